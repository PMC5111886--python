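"""Coordinate projection between the two haplotypes of a diploid sequence.

The generator expresses all truth against haplotype A. Indel variants make
the two haplotype coordinate systems diverge; this module represents the
A<->B relation as a list of gapless matched blocks and supports position
mapping, interval projection, and CIGAR construction for a read drawn from
one haplotype and placed on the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class Variant:
    """A planted difference between hapA (reference) and hapB.

    ``pos`` is 0-based on hapA. For a SNP, ``ref``/``alt`` are single bases.
    For a deletion, ``ref`` holds the hapA bases absent from hapB and
    ``alt`` is empty. For an insertion, ``alt`` holds the bases present in
    hapB immediately before hapA position ``pos`` and ``ref`` is empty.
    """

    chrom: str
    pos: int
    kind: str  # "snp" | "ins" | "del"
    ref: str
    alt: str

    @property
    def is_indel(self) -> bool:
        return self.kind != "snp"

    @property
    def length(self) -> int:
        return len(self.ref) if self.kind == "del" else len(self.alt)


def apply_variants(seq: str, variants: Sequence[Variant]) -> str:
    """Apply hapA-coordinate variants to ``seq`` (hapA), producing hapB."""
    pieces: List[str] = []
    cursor = 0
    for v in sorted(variants, key=lambda v: (v.pos, v.kind != "ins")):
        if v.pos < cursor:
            raise ValueError(f"overlapping variants at {v.chrom}:{v.pos}")
        pieces.append(seq[cursor:v.pos])
        if v.kind == "snp":
            if seq[v.pos] != v.ref:
                raise ValueError(f"SNP ref mismatch at {v.chrom}:{v.pos}")
            pieces.append(v.alt)
            cursor = v.pos + 1
        elif v.kind == "del":
            if seq[v.pos:v.pos + len(v.ref)] != v.ref:
                raise ValueError(f"deletion ref mismatch at {v.chrom}:{v.pos}")
            cursor = v.pos + len(v.ref)
        elif v.kind == "ins":
            pieces.append(v.alt)
            cursor = v.pos
        else:
            raise ValueError(f"unknown variant kind {v.kind!r}")
    pieces.append(seq[cursor:])
    return "".join(pieces)


class CoordinateMap:
    """Block-wise mapping between hapA and hapB coordinates.

    Blocks are maximal gapless runs; between consecutive blocks either hapA
    has extra bases (a deletion in hapB) or hapB has extra bases (an
    insertion). Positions inside a gap clamp to the start of the next block.
    """

    def __init__(self, a_starts, b_starts, lengths, a_len: int, b_len: int):
        self.a_starts = np.asarray(a_starts, dtype=np.int64)
        self.b_starts = np.asarray(b_starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.a_len = a_len
        self.b_len = b_len

    @classmethod
    def from_variants(cls, variants: Iterable[Variant], a_len: int) -> "CoordinateMap":
        indels = sorted((v for v in variants if v.is_indel), key=lambda v: v.pos)
        a_starts, b_starts, lengths = [], [], []
        ca = cb = 0
        for v in indels:
            blk = v.pos - ca
            a_starts.append(ca)
            b_starts.append(cb)
            lengths.append(blk)
            ca += blk
            cb += blk
            if v.kind == "del":
                ca += len(v.ref)
            else:
                cb += len(v.alt)
        a_starts.append(ca)
        b_starts.append(cb)
        lengths.append(a_len - ca)
        b_len = cb + (a_len - ca)
        return cls(a_starts, b_starts, lengths, a_len, b_len)

    # -- position mapping ---------------------------------------------------

    def _map(self, starts_from, starts_to, pos: int) -> int:
        i = int(np.searchsorted(starts_from, pos, side="right")) - 1
        i = max(i, 0)
        off = pos - int(starts_from[i])
        off = min(off, int(self.lengths[i]))
        return int(starts_to[i]) + off

    def a_to_b(self, pos: int) -> int:
        return self._map(self.a_starts, self.b_starts, pos)

    def b_to_a(self, pos: int) -> int:
        return self._map(self.b_starts, self.a_starts, pos)

    def interval_a_to_b(self, start: int, end: int) -> Tuple[int, int]:
        return self.a_to_b(start), self.a_to_b(end)

    def interval_b_to_a(self, start: int, end: int) -> Tuple[int, int]:
        return self.b_to_a(start), self.b_to_a(end)

    # -- alignment projection ----------------------------------------------

    def project_cigar(self, start: int, end: int, source: str = "B"
                      ) -> Tuple[int, List[Tuple[str, int]]]:
        """Alignment of source-haplotype interval [start, end) on the other.

        Returns ``(target_start, cigar)`` with ops 'M' (aligned run, may
        contain substitutions), 'I' (bases present only in the source),
        'D' (bases present only in the target) and 'S' (source bases
        falling before the first / after the last aligned block).
        """
        if source == "B":
            s_starts, t_starts = self.b_starts, self.a_starts
        elif source == "A":
            s_starts, t_starts = self.a_starts, self.b_starts
        else:
            raise ValueError("source must be 'A' or 'B'")
        lengths = self.lengths
        n = len(lengths)
        i = max(int(np.searchsorted(s_starts, start, side="right")) - 1, 0)
        pos = start
        ops: List[Tuple[str, int]] = []
        target_start = None
        while pos < end and i < n:
            blk_s = int(s_starts[i])
            blk_t = int(t_starts[i])
            blk_len = int(lengths[i])
            blk_end = blk_s + blk_len
            if pos < blk_end:
                take = min(end, blk_end) - pos
                if take > 0:
                    if target_start is None:
                        target_start = blk_t + (pos - blk_s)
                    ops.append(("M", take))
                    pos += take
            if pos >= end or i + 1 >= n:
                break
            next_s = int(s_starts[i + 1])
            next_t = int(t_starts[i + 1])
            gap_s = next_s - blk_end           # source-only bases
            gap_t = next_t - (blk_t + blk_len)  # target-only bases
            if gap_s and pos < next_s:
                take = min(end, next_s) - pos
                ops.append(("I", take) if target_start is not None else ("S", take))
                pos += take
            if pos >= end:
                break
            if gap_t and target_start is not None:
                ops.append(("D", gap_t))
            i += 1
        if pos < end:  # ran off the block list
            ops.append(("I", end - pos) if target_start is not None else ("S", end - pos))
        # a trailing insertion has nothing to align against: soft-clip it
        while ops and ops[-1][0] in ("I", "D"):
            op, ln = ops.pop()
            if op == "I":
                ops.append(("S", ln))
                break
        if target_start is None:
            raise ValueError("interval maps entirely into a gap")
        return target_start, _merge_ops(ops)


def _merge_ops(ops: List[Tuple[str, int]]) -> List[Tuple[str, int]]:
    merged: List[Tuple[str, int]] = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return merged


def cigar_target_span(cigar: Sequence[Tuple[str, int]]) -> int:
    return sum(ln for op, ln in cigar if op in ("M", "D"))


def cigar_query_span(cigar: Sequence[Tuple[str, int]]) -> int:
    return sum(ln for op, ln in cigar if op in ("M", "I", "S"))
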