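"""Base-level pileups and the shared heterozygous-site calling rule.

A pileup is a (6, L) count matrix per contig: rows 0-3 are A/C/G/T
support, row 4 counts reads spanning a deletion of the position, row 5
counts insertion events anchored immediately after the position.

The het-site rule used across the package (gene-level calling, fragment
heterozygosity, overlap cross-checks): a site is heterozygous when total
depth >= ``min_depth``, the second allele is seen on >= ``min_reads``
reads, and the minor-allele fraction is >= ``min_maf``. Indel events pass
the same support thresholds and count one site at their leftmost position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np

from .placement import Placement

DEL_ROW, INS_ROW = 4, 5


def build_pileups(placements: Iterable[Placement],
                  contig_lengths: Dict[str, int]) -> Dict[str, np.ndarray]:
    piles = {name: np.zeros((6, ln), dtype=np.int32)
             for name, ln in contig_lengths.items()}
    for p in placements:
        counts = piles[p.contig]
        rp, ro = p.pos, 0
        for op, ln in p.cigar:
            if op == "M":
                np.add.at(counts, (p.codes[ro:ro + ln],
                                   np.arange(rp, rp + ln)), 1)
                rp += ln
                ro += ln
            elif op == "D":
                counts[DEL_ROW, rp:rp + ln] += 1
                rp += ln
            elif op == "I":
                if rp > 0:
                    counts[INS_ROW, rp - 1] += 1
                ro += ln
            elif op == "S":
                ro += ln
            else:
                raise ValueError(f"unsupported cigar op {op!r}")
    return piles


@dataclass
class SiteCalls:
    """Vectorised site-level verdicts over one contig."""

    depth: np.ndarray          # substitution depth + spanning deletions
    assessed: np.ndarray       # bool: depth >= min_depth
    snp_het: np.ndarray        # bool per position
    del_start: np.ndarray      # bool: leftmost position of a het deletion
    ins_het: np.ndarray        # bool: het insertion anchored here
    third_allele: np.ndarray   # bool: >2 read-supported base alleles

    def het_sites(self, include_indels: bool = True) -> np.ndarray:
        out = self.snp_het.copy()
        if include_indels:
            out |= self.del_start | self.ins_het
        return out


def call_sites(counts: np.ndarray, min_depth: int = 10, min_reads: int = 2,
               min_maf: float = 0.2) -> SiteCalls:
    base = counts[:4]
    sub_depth = base.sum(axis=0)
    depth = sub_depth + counts[DEL_ROW]
    assessed = depth >= min_depth
    ordered = np.sort(base, axis=0)
    a2 = ordered[2]            # second-best allele support
    denom = np.maximum(sub_depth, 1)
    snp_het = assessed & (a2 >= min_reads) & (a2 / denom >= min_maf)

    d = counts[DEL_ROW]
    ddenom = np.maximum(depth, 1)
    del_het = assessed & (d >= min_reads) & (d / ddenom >= min_maf) \
        & (d / ddenom <= 1 - min_maf)
    del_start = del_het & ~np.concatenate(([False], del_het[:-1]))

    ins = counts[INS_ROW]
    ins_het = assessed & (ins >= min_reads) & (ins / ddenom >= min_maf)

    third = assessed & ((base >= min_reads).sum(axis=0) >= 3)
    return SiteCalls(depth, assessed, snp_het, del_start, ins_het, third)


def alleles_at(counts: np.ndarray, pos: int, min_reads: int = 2) -> Set[int]:
    """Read-supported base codes at one position."""
    return set(np.flatnonzero(counts[:4, pos] >= min_reads).tolist())
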