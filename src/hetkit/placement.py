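"""Truth-guided placement of simulated reads onto assembly contigs.

The generator knows exactly where every read comes from, so alignments can
be constructed instead of searched for: a read is placed on the contig of
its own haplotype when one covers it, otherwise projected through the
planted-variant coordinate map onto the homologous contig of the other
haplotype (CIGAR included). This emulates an ideal mapper — reads over
split regions go to their own haplotype's contig, reads over merged
regions pile onto the single consensus at twice the depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .coords import CoordinateMap, _merge_ops
from .synth.assembly import AssemblyContig
from .synth.fragments import Fragment
from .synth.genome import DiploidGenome
from .synth.reads import ReadSet

_CIGAR_OP = {"M": 0, "I": 1, "D": 2, "S": 4}


@dataclass
class Placement:
    contig: str
    pos: int                     # 0-based start on the contig
    cigar: List[Tuple[str, int]]
    codes: np.ndarray            # read bases, genome-oriented
    qname: str = ""


def fragment_to_contig(frag: Fragment) -> AssemblyContig:
    return AssemblyContig(frag.name, frag.chrom, frag.hap, frag.start,
                          frag.end, frag.a_start, frag.a_end, frag.seq)


class _ContigIndex:
    def __init__(self, contigs: Sequence[AssemblyContig]):
        self.groups: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, List[AssemblyContig]]] = {}
        by_key: Dict[Tuple[str, str], List[AssemblyContig]] = {}
        for c in contigs:
            by_key.setdefault((c.chrom, c.hap), []).append(c)
        for key, group in by_key.items():
            group.sort(key=lambda c: c.start)
            starts = np.array([c.start for c in group], dtype=np.int64)
            ends = np.array([c.end for c in group], dtype=np.int64)
            self.groups[key] = (starts, ends, group)

    def containing(self, chrom: str, hap: str, s: int, e: int,
                   min_overlap: int = 30) -> Optional[AssemblyContig]:
        """Contig containing [s, e), or overlapping it by >= min_overlap."""
        entry = self.groups.get((chrom, hap))
        if entry is None:
            return None
        starts, ends, group = entry
        i = int(np.searchsorted(starts, s, side="right")) - 1
        for j in (i, i + 1):
            if 0 <= j < len(group):
                ov = min(e, ends[j]) - max(s, int(starts[j]))
                if ov >= min(min_overlap, e - s):
                    return group[j]
        return None


def _clip_cigar(start: int, cigar: List[Tuple[str, int]], lo: int, hi: int
                ) -> Optional[Tuple[int, List[Tuple[str, int]]]]:
    """Restrict an alignment to target interval [lo, hi); clip the rest."""
    ops: List[Tuple[str, int]] = []
    rp = start
    new_start = None
    for op, ln in cigar:
        if op in ("M", "D"):
            seg_lo, seg_hi = rp, rp + ln
            cut_lo, cut_hi = max(seg_lo, lo), min(seg_hi, hi)
            if cut_hi <= cut_lo:       # entirely outside
                if op == "M":
                    ops.append(("S", ln))
            else:
                if op == "M" and cut_lo > seg_lo:
                    ops.append(("S", cut_lo - seg_lo))
                if cut_hi > cut_lo:
                    if new_start is None and op == "M":
                        new_start = cut_lo
                    if op == "M" or new_start is not None:
                        ops.append((op if new_start is not None else "S",
                                    cut_hi - cut_lo))
                if op == "M" and seg_hi > cut_hi:
                    ops.append(("S", seg_hi - cut_hi))
            rp += ln
        else:                          # I / S consume query only
            ops.append(("S", ln) if new_start is None else (op, ln))
    # drop leading/trailing deletions
    merged = list(_merge_ops(ops))
    while merged and merged[0][0] == "D":
        merged.pop(0)
    while merged and merged[-1][0] == "D":
        merged.pop()
    aligned = sum(ln for op, ln in merged if op == "M")
    if new_start is None or aligned < 1:
        return None
    return new_start, merged


def place_readset(rs: ReadSet, contigs: Sequence[AssemblyContig],
                  genome: DiploidGenome) -> List[Placement]:
    """Place every read of ``rs`` on the best-matching contig.

    Reads not fully contained in any contig (after projection) are dropped,
    mirroring a mapper discarding partial boundary alignments.
    """
    index = _ContigIndex(contigs)
    hapc = ("A", "B")
    placements: List[Placement] = []
    for mate, mat in ((1, rs.r1), (2, rs.r2)):
        starts, ends = rs.mate_intervals(mate)
        for i in range(rs.n_pairs):
            chrom = rs.chroms[rs.chrom_id[i]]
            hap = hapc[rs.hap[i]]
            s, e = int(starts[i]), int(ends[i])
            qname = f"sim.{i}/{mate}"
            own = index.containing(chrom, hap, s, e)
            if own is not None:
                # soft-clip read parts hanging over the contig edge
                ov_s, ov_e = max(s, own.start), min(e, own.end)
                cigar = _merge_ops([("S", ov_s - s), ("M", ov_e - ov_s),
                                    ("S", e - ov_e)])
                placements.append(Placement(
                    own.name, ov_s - own.start, cigar, mat[i], qname))
                continue
            other = hapc[1 - rs.hap[i]]
            cmap = genome.coord_maps[chrom]
            if hap == "A":
                ts, te = cmap.interval_a_to_b(s, e)
            else:
                ts, te = cmap.interval_b_to_a(s, e)
            target = index.containing(chrom, other, ts, te)
            if target is None:
                continue
            try:
                # reads falling entirely inside a region deleted on the
                # other haplotype have no alignment there
                tstart, cigar = cmap.project_cigar(s, e, source=hap)
            except ValueError:
                continue
            clipped = _clip_cigar(tstart, cigar, target.start, target.end)
            if clipped is None:
                continue
            tstart, cigar = clipped
            placements.append(Placement(
                target.name, tstart - target.start, cigar, mat[i], qname))
    return placements


def write_sam(placements: Iterable[Placement],
              contig_lengths: Dict[str, int], path) -> None:
    """Emit placements as a plain-text SAM file (via pysam)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": name, "LN": int(ln)}
                     for name, ln in sorted(contig_lengths.items())]}
    tid = {name: j for j, name in enumerate(sorted(contig_lengths))}
    from . import dna
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in placements:
            a = pysam.AlignedSegment(out.header)
            a.query_name = p.qname or "read"
            a.query_sequence = dna.decode(p.codes)
            a.reference_id = tid[p.contig]
            a.reference_start = p.pos
            a.mapping_quality = 60
            a.cigartuples = [(_CIGAR_OP[op], ln) for op, ln in p.cigar]
            a.query_qualities = pysam.qualitystring_to_array(
                "I" * len(p.codes))
            out.write(a)
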