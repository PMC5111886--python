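"""Isoform combinatorics for hypervariable mutually-exclusive exon arrays.

Dscam-like loci carry tandem arrays of alternative exons from which
splicing selects exactly one per array; the isoform repertoire is the
product of the array sizes (e.g. arrays of 13, 20 and 13 alternatives
yield 3,380 ectodomain combinations).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple


class CombinError(ValueError):
    pass


@dataclass(frozen=True)
class ExonArraySpec:
    """Ordered 5'->3' arrays of mutually exclusive alternative exons."""

    locus_id: str
    array_names: Tuple[str, ...]
    array_sizes: Tuple[int, ...]

    def __post_init__(self):
        if len(self.array_names) != len(self.array_sizes):
            raise CombinError("names and sizes differ in length")
        if len(self.array_sizes) == 0:
            raise CombinError("empty exon-array spec")
        if any(n < 1 for n in self.array_sizes):
            raise CombinError("array sizes must be >= 1")

    @classmethod
    def from_sizes(cls, sizes: Sequence[int], locus_id: str = "locus"
                   ) -> "ExonArraySpec":
        names = tuple(f"array{i}" for i in range(len(sizes)))
        return cls(locus_id, names, tuple(int(s) for s in sizes))


def count_combinations(spec) -> int:
    """Number of isoforms: one exon chosen per array."""
    sizes = spec.array_sizes if isinstance(spec, ExonArraySpec) else tuple(spec)
    if len(sizes) == 0:
        raise CombinError("empty exon-array spec")
    if any(int(n) < 1 for n in sizes):
        raise CombinError("array sizes must be >= 1")
    return math.prod(int(n) for n in sizes)


def enumerate_isoforms(spec, cap: int = 1_000_000
                       ) -> List[Tuple[int, ...]]:
    """Exhaustive, lexicographically ordered exon-choice enumeration."""
    sizes = spec.array_sizes if isinstance(spec, ExonArraySpec) else tuple(spec)
    total = count_combinations(sizes)
    if total > cap:
        raise CombinError(f"{total} combinations exceed cap {cap}")
    return list(itertools.product(*(range(n) for n in sizes)))
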