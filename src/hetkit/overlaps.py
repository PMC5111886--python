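"""Contiguous-fragment (BAC-style) polymorphism accounting.

Long fragments cloned from single haplotypes tile a region with declared
overlaps. Where consecutive fragments come from opposite haplotypes, the
overlap is a direct haplotype-to-haplotype comparison: a global affine-gap
alignment yields SNP columns and indel events (including the long,
polynucleotide ones short reads cannot resolve), each SNP is cross-checked
against read pileups on both fragments, and pileup alleles absent from
both fragments are tallied as third alleles — evidence of polymorphism
beyond the two haplotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from . import dna
from .pileup import SiteCalls, alleles_at, call_sites
from .synth.fragments import Fragment, FragmentSet

MIN_OVERLAP_LEN = 100


class OverlapError(ValueError):
    pass


@dataclass(frozen=True)
class IndelEvent:
    pos: int          # coordinate on fragment A of the event start
    length: int
    kind: str         # "ins" = extra bases on B, "del" = extra bases on A


@dataclass
class OverlapReport:
    pair: Tuple[str, str]
    overlap_len: int
    identity: float
    snps_pairwise: int
    snps_read_supported: int
    snps_both_supported: int
    third_allele_sites: int
    indels: List[IndelEvent] = field(default_factory=list)
    large_indel_min: int = 100

    @property
    def n_indels(self) -> int:
        return len(self.indels)

    @property
    def n_indels_large(self) -> int:
        return sum(1 for e in self.indels if e.length >= self.large_indel_min)

    def as_row(self) -> dict:
        return {
            "pair": "|".join(self.pair), "overlap_len": self.overlap_len,
            "identity": round(self.identity, 3),
            "snps_pairwise": self.snps_pairwise,
            "snps_read_supported": self.snps_read_supported,
            "snps_both_supported": self.snps_both_supported,
            "third_allele_sites": self.third_allele_sites,
            "n_indels": self.n_indels,
            "n_indels_ge_100": self.n_indels_large,
        }


@dataclass
class FragmentHetRecord:
    fragment: str
    length: int
    het_percent: float
    popvar_percent: float
    mean_depth: float
    low_confidence: bool


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2
    al.mismatch_score = -3
    al.open_gap_score = -10
    al.extend_gap_score = -1
    return al


# ---------------------------------------------------------------------------
# overlap detection


def find_overlaps(fragments, genome=None, min_seed_matches: int = 20,
                  seed_k: int = 21
                  ) -> List[Tuple[str, str, int, int, int, int]]:
    """Overlap coordinates per fragment pair.

    For a :class:`FragmentSet` (with its source genome) the declared truth
    coordinates are used directly; for a plain mapping name -> sequence,
    overlaps are detected by shared-k-mer seeding and diagonal estimation.
    Returns tuples ``(name_a, name_b, a_lo, a_hi, b_lo, b_hi)`` in
    fragment-local coordinates.
    """
    if isinstance(fragments, FragmentSet):
        if genome is None:
            raise OverlapError("declared-truth overlap coordinates need the "
                               "source genome")
        return find_overlaps_genome(fragments, genome)
    # sequence-only path: seed-based detection
    from .collapse import _contig_kmers
    names = sorted(fragments)
    tables = {n: _contig_kmers(fragments[n], seed_k) for n in names}
    out = []
    for na, nb in itertools.combinations(names, 2):
        ka, pa = tables[na]
        kb, pb = tables[nb]
        common, ia, ib = np.intersect1d(ka, kb, assume_unique=True,
                                        return_indices=True)
        qa, qb = pa[ia], pb[ib]
        anchors = (qa >= 0) & (qb >= 0)
        if anchors.sum() < min_seed_matches:
            continue
        offset = int(np.median(qa[anchors] - qb[anchors]))
        a_lo = max(0, offset)
        a_hi = min(len(fragments[na]), offset + len(fragments[nb]))
        b_lo = max(0, -offset)
        b_hi = min(len(fragments[nb]), len(fragments[na]) - offset)
        if a_hi - a_lo >= MIN_OVERLAP_LEN:
            out.append((na, nb, a_lo, a_hi, b_lo, b_hi))
    return out


def find_overlaps_genome(fragset: FragmentSet, genome
                         ) -> List[Tuple[str, str, int, int, int, int]]:
    """Declared-truth overlap coordinates using the genome coordinate map."""
    out = []
    frag_by_name = {f.name: f for f in fragset.fragments}
    for ov in fragset.overlaps:
        coords = []
        for name in (ov.name_a, ov.name_b):
            fr = frag_by_name[name]
            if fr.hap == "A":
                coords.append((ov.a_lo - fr.start, ov.a_hi - fr.start))
            else:
                cmap = genome.coord_maps[fr.chrom]
                b_lo, b_hi = cmap.interval_a_to_b(ov.a_lo, ov.a_hi)
                coords.append((b_lo - fr.start, b_hi - fr.start))
        (a_lo, a_hi), (b_lo, b_hi) = coords
        out.append((ov.name_a, ov.name_b, a_lo, a_hi, b_lo, b_hi))
    return out


# ---------------------------------------------------------------------------
# overlap analysis


def analyze_overlap(name_a: str, name_b: str, seq_a: str, seq_b: str,
                    coords: Tuple[int, int, int, int],
                    pileup_a: Optional[np.ndarray] = None,
                    pileup_b: Optional[np.ndarray] = None,
                    min_depth: int = 10, min_reads: int = 2,
                    min_maf: float = 0.2, large_indel_min: int = 100
                    ) -> OverlapReport:
    """Pairwise SNP/indel accounting over one overlap, with read support."""
    a_lo, a_hi, b_lo, b_hi = coords
    if a_hi - a_lo < MIN_OVERLAP_LEN:
        raise OverlapError(
            f"overlap of {a_hi - a_lo} bp is uninformative (<{MIN_OVERLAP_LEN})")
    wa = seq_a[a_lo:a_hi]
    wb = seq_b[b_lo:b_hi]
    aln = _aligner().align(wa, wb)[0]
    blocks_a, blocks_b = aln.aligned
    snp_cols: List[Tuple[int, int]] = []        # (posA, posB), local coords
    match_cols = 0
    total_cols = 0
    indels: List[IndelEvent] = []
    prev_a = prev_b = None
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            ga, gb = as_ - prev_a, bs - prev_b
            if ga > 0:
                indels.append(IndelEvent(a_lo + prev_a, ga, "del"))
                total_cols += ga
            if gb > 0:
                indels.append(IndelEvent(a_lo + prev_a, gb, "ins"))
                total_cols += gb
        sub_a = np.frombuffer(wa[as_:ae].encode(), dtype=np.uint8)
        sub_b = np.frombuffer(wb[bs:be].encode(), dtype=np.uint8)
        diff = np.flatnonzero(sub_a != sub_b)
        for d in diff:
            snp_cols.append((as_ + int(d), bs + int(d)))
        match_cols += (ae - as_) - diff.size
        total_cols += ae - as_
        prev_a, prev_b = ae, be
    identity = 100.0 * match_cols / total_cols if total_cols else 0.0

    snps_read_supported = snps_both = third = 0
    if pileup_a is not None:
        calls_a = call_sites(pileup_a[:, a_lo:a_hi], min_depth, min_reads,
                             min_maf)
        snps_read_supported = int(calls_a.snp_het.sum())
        for pa, pb in snp_cols:
            base_a = dna.BASES.index(wa[pa])
            base_b = dna.BASES.index(wb[pb])
            support_a = alleles_at(pileup_a, a_lo + pa, min_reads)
            ok = {base_a, base_b} <= support_a
            if not ok and pileup_b is not None:
                support_b = alleles_at(pileup_b, b_lo + pb, min_reads)
                ok = {base_a, base_b} <= support_b
            snps_both += bool(ok)
        # third alleles: columns where fragment bases plus read-supported
        # bases exceed two alleles — polymorphism beyond the individual's
        # two haplotypes; a frequency floor keeps sequencing errors out
        depth = pileup_a[:4].sum(axis=0)
        for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
            for j in range(ae - as_):
                pa = a_lo + as_ + j
                d = depth[pa]
                if d < min_depth:
                    continue
                floor = max(min_reads, int(np.ceil(0.1 * d)))
                support = alleles_at(pileup_a, pa, floor)
                frag_alleles = {dna.BASES.index(wa[as_ + j]),
                                dna.BASES.index(wb[bs + j])}
                if len(support | frag_alleles) > 2:
                    third += 1
    return OverlapReport(
        (name_a, name_b), a_hi - a_lo, identity, len(snp_cols),
        snps_read_supported, snps_both, third, indels, large_indel_min)


def fragment_het(fragment_name: str, length: int, pileup: np.ndarray,
                 min_depth: int = 10, min_reads: int = 2,
                 min_maf: float = 0.2, include_indels: bool = False
                 ) -> FragmentHetRecord:
    """Per-fragment heterozygosity and population variance from reads alone.

    Heterozygosity counts pileup het sites over the fragment length
    (SNP sites only by default); population variance counts sites where
    reads support more than two alleles.
    """
    calls = call_sites(pileup, min_depth, min_reads, min_maf)
    het_sites = int(calls.het_sites(include_indels).sum())
    third = int(calls.third_allele.sum())
    mean_depth = float(calls.depth.mean())
    return FragmentHetRecord(
        fragment_name, length,
        100.0 * het_sites / length,
        100.0 * third / length,
        mean_depth,
        mean_depth < min_depth)


def analyze_fragment_set(fragset: FragmentSet, genome, readset,
                         min_depth: int = 10, min_reads: int = 2,
                         min_maf: float = 0.2
                         ) -> Tuple[List[OverlapReport],
                                    List[FragmentHetRecord]]:
    """Full fragment pipeline: per-fragment pileups, overlaps, het records."""
    from .placement import fragment_to_contig, place_readset
    from .pileup import build_pileups

    piles: Dict[str, np.ndarray] = {}
    chrom_index = {c: i for i, c in enumerate(readset.chroms)}
    for fr in fragset.fragments:
        contig = fragment_to_contig(fr)
        # cheap prefilter: only read pairs near the fragment's ancestral
        # interval can place on it (coordinate drift << margin)
        margin = 5_000
        near = ((readset.chrom_id == chrom_index[fr.chrom])
                & (readset.frag_start + readset.frag_len
                   >= fr.a_start - margin)
                & (readset.frag_start <= fr.a_end + margin))
        placements = place_readset(readset.take(near), [contig], genome)
        piles[fr.name] = build_pileups(placements,
                                       {fr.name: len(fr.seq)})[fr.name]
    seqs = {f.name: f.seq for f in fragset.fragments}
    reports = []
    for name_a, name_b, a_lo, a_hi, b_lo, b_hi in \
            find_overlaps_genome(fragset, genome):
        reports.append(analyze_overlap(
            name_a, name_b, seqs[name_a], seqs[name_b],
            (a_lo, a_hi, b_lo, b_hi), piles[name_a], piles[name_b],
            min_depth, min_reads, min_maf))
    het_records = [fragment_het(f.name, len(f.seq), piles[f.name],
                                min_depth, min_reads, min_maf)
                   for f in fragset.fragments]
    return reports, het_records
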