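"""Per-gene heterozygosity and population-variance calling.

The procedure mirrors transcript-guided two-locus analysis of a diploid
assembly:

1. transcripts are aligned to the assembly; alignments under 30 bp are
   discarded, transcripts hitting more than five loci are dropped as
   repeats/conserved domains, and the two loci with fewest mismatches are
   retained;
2. read coverage over each gene's transcribed region splits genes into a
   low-coverage group (haplotypes assembled separately, ~1x per-haplotype
   depth) and a high-coverage group (haplotypes merged, ~2x);
3. heterozygosity of merged genes comes from the read pileup; for split
   genes the two genomic loci are aligned and each differing site must be
   supported by reads on its own contig;
4. alleles observed in transcripts that match neither haplotype allele are
   population variance — polymorphism segregating in the wider laboratory
   population beyond the sequenced individual;
5. coding differences are classified codon-by-codon into synonymous and
   non-synonymous substitutions, frame-disrupting indels counted apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import edlib
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import dna
from .pileup import SiteCalls, alleles_at, call_sites

SEED_K = 21
MAX_INTRON = 5_000
_DIAG_TOL = 40


class HetcallError(ValueError):
    pass


# ---------------------------------------------------------------------------
# transcript mapping


@dataclass
class LocusBlock:
    """One gap-free-ish matched block (roughly an exon) of a locus."""

    t_lo: int
    t_hi: int
    c_lo: int
    c_hi: int


@dataclass
class Locus:
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    aln_len: int
    blocks: List[LocusBlock] = field(default_factory=list)


@dataclass
class TranscriptHit:
    tx_id: str
    loci: List[Locus]               # top two, fewest mismatches first
    n_loci_observed: int
    oriented_seq: str               # transcript in genome orientation
    dropped: bool = False           # > max_loci rule
    unplaced: bool = False


def _kmer_table(seq: str, k: int = SEED_K) -> Tuple[np.ndarray, np.ndarray]:
    """Unique canonical k-mers of ``seq`` with their (unique) positions."""
    if len(seq) < k:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    codes = dna.encode(seq)[None, :]
    w = len(seq) - k + 1
    fwd = np.zeros((1, w), dtype=np.uint64)
    rev = np.zeros((1, w), dtype=np.uint64)
    for j in range(k):
        col = codes[:, j:j + w].astype(np.uint64)
        fwd = (fwd << np.uint64(2)) | col
        rev |= (np.uint64(3) - col) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev).ravel()
    order = np.argsort(canon, kind="stable")
    cs = canon[order]
    first = np.concatenate(([True], cs[1:] != cs[:-1]))
    starts = np.flatnonzero(first)
    run_len = np.diff(np.append(starts, cs.size))
    keep = run_len == 1
    return cs[starts][keep], order[starts][keep]


def _anchors(tx_table, contig_table) -> Tuple[np.ndarray, np.ndarray]:
    tk, tp = tx_table
    ck, cp = contig_table
    common, it, ic = np.intersect1d(tk, ck, assume_unique=True,
                                    return_indices=True)
    return tp[it], cp[ic]


def _mismatch_count(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _refine_blocks(blocks: List[LocusBlock], tx: str, cseq: str,
                   max_mismatch_frac: float = 0.35) -> None:
    """Extend anchored blocks over seed deserts.

    Exact-seed anchoring cannot start within k bases of an exon junction,
    a planted variant cluster, or the transcript ends, which erodes block
    edges exactly where variant sites concentrate. Outer edges are
    extended to the transcript ends when the extension still matches the
    contig; interior junction gaps are split between the flanking blocks
    at the position minimising total mismatches.
    """
    if not blocks:
        return
    b0 = blocks[0]
    ext = min(b0.t_lo, b0.c_lo)
    if ext > 0:
        tseg = tx[b0.t_lo - ext:b0.t_lo]
        cseg = cseq[b0.c_lo - ext:b0.c_lo]
        if _mismatch_count(tseg, cseg) <= max_mismatch_frac * ext:
            b0.t_lo -= ext
            b0.c_lo -= ext
    bl = blocks[-1]
    ext = min(len(tx) - bl.t_hi, len(cseq) - bl.c_hi)
    if ext > 0:
        tseg = tx[bl.t_hi:bl.t_hi + ext]
        cseg = cseq[bl.c_hi:bl.c_hi + ext]
        if _mismatch_count(tseg, cseg) <= max_mismatch_frac * ext:
            bl.t_hi += ext
            bl.c_hi += ext
    for left, right in zip(blocks, blocks[1:]):
        g = right.t_lo - left.t_hi
        room = right.c_lo - left.c_hi
        if g <= 0 or room < g:
            continue
        tgap = tx[left.t_hi:right.t_lo]
        cl = cseq[left.c_hi:left.c_hi + g]
        cr = cseq[right.c_lo - g:right.c_lo]
        pref = np.zeros(g + 1, dtype=np.int64)
        suf = np.zeros(g + 1, dtype=np.int64)
        for i in range(g):
            pref[i + 1] = pref[i] + (tgap[i] != cl[i])
            suf[i + 1] = suf[i] + (tgap[g - 1 - i] != cr[g - 1 - i])
        cost = pref[np.arange(g + 1)] + suf[g - np.arange(g + 1)]
        s = int(np.argmin(cost))
        if cost[s] <= max_mismatch_frac * g:
            left.t_hi += s
            left.c_hi += s
            right.t_lo -= g - s
            right.c_lo -= g - s


def _build_loci(tpos: np.ndarray, cpos: np.ndarray, contig: str,
                strand: str, tx: str, contig_seq: str, k: int = SEED_K
                ) -> List[Locus]:
    order = np.argsort(cpos)
    tpos, cpos = tpos[order], cpos[order]
    breaks = np.flatnonzero(np.diff(cpos) > MAX_INTRON) + 1
    loci: List[Locus] = []
    for lo, hi in zip(np.concatenate(([0], breaks)),
                      np.concatenate((breaks, [cpos.size]))):
        tt, cc = tpos[lo:hi], cpos[lo:hi]
        o2 = np.argsort(tt)
        tt, cc = tt[o2], cc[o2]
        # keep a monotone anchor chain (spurious seed matches would
        # otherwise produce inverted, empty blocks)
        keep = [0]
        for i in range(1, tt.size):
            if cc[i] >= cc[keep[-1]] and tt[i] >= tt[keep[-1]]:
                keep.append(i)
        tt, cc = tt[keep], cc[keep]
        # split into blocks on diagonal jumps (introns / long indels)
        diag = cc - tt
        blocks: List[LocusBlock] = []
        start = 0
        for i in range(1, tt.size):
            if abs(int(diag[i]) - int(diag[i - 1])) > _DIAG_TOL:
                blocks.append(LocusBlock(int(tt[start]), int(tt[i - 1]) + k,
                                         int(cc[start]), int(cc[i - 1]) + k))
                start = i
        blocks.append(LocusBlock(int(tt[start]), int(tt[-1]) + k,
                                 int(cc[start]), int(cc[-1]) + k))
        _refine_blocks(blocks, tx, contig_seq)
        mism = 0
        aln = 0
        for b in blocks:
            aln += b.t_hi - b.t_lo
            res = edlib.align(tx[b.t_lo:b.t_hi], contig_seq[b.c_lo:b.c_hi],
                              mode="NW")
            mism += max(res["editDistance"], 0)
        loci.append(Locus(contig, min(b.c_lo for b in blocks),
                          max(b.c_hi for b in blocks), strand,
                          mism, aln, blocks))
    return loci


def map_transcripts_and_filter(transcripts: Dict[str, str],
                               contigs: Dict[str, str],
                               min_aln: int = 30, max_loci: int = 5,
                               seed_k: int = SEED_K
                               ) -> Dict[str, TranscriptHit]:
    """Map every transcript, apply the length/multi-locus filters.

    Loci are sorted by ascending mismatch count (ties: longer alignment,
    then contig name) and the top two are retained.
    """
    ctables = {name: _kmer_table(seq, seed_k) for name, seq in contigs.items()}
    hits: Dict[str, TranscriptHit] = {}
    for tx_id, seq in transcripts.items():
        best: Optional[Tuple[int, str, List[Locus]]] = None
        for strand, oriented in (("+", seq), ("-", dna.revcomp(seq))):
            ttable = _kmer_table(oriented, seed_k)
            loci: List[Locus] = []
            for cname, ctable in ctables.items():
                tp, cp = _anchors(ttable, ctable)
                if tp.size == 0:
                    continue
                loci.extend(_build_loci(tp, cp, cname, strand, oriented,
                                        contigs[cname], seed_k))
            # canonical k-mers match either strand; the true orientation is
            # the one whose collinear chains cover more of the transcript
            score = sum(l.aln_len for l in loci)
            if best is None or score > best[0]:
                best = (score, oriented, loci)
        assert best is not None
        _, oriented, loci = best
        loci = [l for l in loci if l.aln_len >= min_aln]
        if not loci:
            hits[tx_id] = TranscriptHit(tx_id, [], 0, oriented,
                                        unplaced=True)
            continue
        if len(loci) > max_loci:
            hits[tx_id] = TranscriptHit(tx_id, [], len(loci), oriented,
                                        dropped=True)
            continue
        loci.sort(key=lambda l: (l.mismatches, -l.aln_len, l.contig))
        hits[tx_id] = TranscriptHit(tx_id, loci[:2], len(loci), oriented)
    return hits


# ---------------------------------------------------------------------------
# coverage groups


@dataclass
class CoverageGroups:
    boundary: float
    upper: float
    low_mode: Optional[float]
    high_mode: Optional[float]
    assignment: Dict[str, str]      # gene -> "split" | "merged" | "unassigned"
    unimodal: bool = False


def region_coverage(pileups: Dict[str, np.ndarray],
                    hits: Dict[str, TranscriptHit],
                    gene_of: Dict[str, str]) -> pd.DataFrame:
    """Mean read depth over the transcribed region of each gene."""
    rows = []
    for tx_id, hit in hits.items():
        if not hit.loci:
            continue
        top = hit.loci[0]
        counts = pileups[top.contig]
        depth = counts[:5].sum(axis=0)
        cols = np.concatenate([np.arange(b.c_lo, b.c_hi) for b in top.blocks])
        cols = cols[(cols >= 0) & (cols < depth.size)]
        mean = float(depth[cols].mean()) if cols.size else 0.0
        rows.append({"gene_id": gene_of[tx_id], "tx_id": tx_id,
                     "depth": mean, "flagged_zero": cols.size == 0})
    return pd.DataFrame(rows)


def coverage_histogram(depths: Sequence[float], bin_width: int = 1
                       ) -> np.ndarray:
    edges = (np.asarray(depths) / bin_width).astype(int)
    hist = np.bincount(edges[edges >= 0])
    return hist


def classify_coverage_groups(depths: pd.DataFrame,
                             boundary: Optional[float] = None,
                             upper_factor: float = 5.0 / 3.0,
                             smooth_window: int = 3) -> CoverageGroups:
    """Split genes into coverage groups around the histogram modes.

    The boundary defaults to the geometric mean of the two detected depth
    modes (~105x for modes at 75x and 150x); genes at or above it are
    "merged", below it "split", above ``upper_factor`` x high mode
    "unassigned" (repeat-like). With an explicit ``boundary`` no mode
    detection is attempted.
    """
    d = depths["depth"].to_numpy(float)
    low_mode = high_mode = None
    unimodal = False
    if boundary is None:
        bw = max(1, int(round(d.max() / 60))) if d.size else 1
        hist = coverage_histogram(d, bw)
        try:
            from .kspec import KmerSpectrum, detect_peaks
            pk = detect_peaks(KmerSpectrum(31, hist.astype(np.int64)),
                              smooth_window=smooth_window)
            if pk.het_peak is None:
                raise HetcallError("unimodal coverage histogram")
            low_mode = pk.het_peak * bw
            high_mode = pk.hom_peak * bw
            boundary = math.sqrt(low_mode * high_mode)
        except Exception:
            unimodal = True
            boundary = float("inf")
            high_mode = float(np.median(d)) if d.size else 0.0
    upper = (high_mode or boundary) * upper_factor \
        if not math.isinf(boundary) else float("inf")
    assignment = {}
    for _, row in depths.iterrows():
        if unimodal:
            assignment[row["gene_id"]] = "split"
        elif row["depth"] >= boundary and row["depth"] <= upper:
            assignment[row["gene_id"]] = "merged"
        elif row["depth"] < boundary:
            assignment[row["gene_id"]] = "split"
        else:
            assignment[row["gene_id"]] = "unassigned"
    return CoverageGroups(float(boundary), float(upper), low_mode, high_mode,
                          assignment, unimodal)


# ---------------------------------------------------------------------------
# heterozygosity


@dataclass
class GeneHetRecord:
    gene_id: str
    group: str
    depth: float
    het_percent: float
    het_sites: int
    assessed: int
    popvar_percent: Optional[float] = None
    popvar_sites: int = 0
    popvar_assessed: int = 0
    syn: int = 0
    nonsyn: int = 0
    indel_events: int = 0
    low_confidence: bool = False


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _align_split_loci(l1: Locus, l2: Locus, seq1: str, seq2: str,
                      calls1: SiteCalls, calls2: SiteCalls,
                      counts1: np.ndarray, counts2: np.ndarray,
                      min_reads: int = 2
                      ) -> Tuple[int, int, Dict[int, str]]:
    """Align the full genomic spans of two loci; count supported het sites.

    The spans cover the transcribed region including introns, which are
    homologous between the two haplotype loci and carry variants at the
    same regional rate. A substitution column counts when each allele is
    read-supported on its own contig; an indel gap run counts once when
    both flanks are adequately covered. Returns (het_sites,
    aligned_columns, map locus1 position -> locus2 base).
    """
    w1 = seq1[l1.start:l1.end]
    w2 = seq2[l2.start:l2.end]
    sites = 0
    columns = 0
    partner: Dict[int, str] = {}
    if not w1 or not w2:
        return 0, 0, partner
    res = edlib.align(w2, w1, mode="NW", task="path")
    p1, p2 = l1.start, l2.start
    in_gap = False
    for ln, op in _iter_cigar(res["cigar"]):
        if op == "=":
            for j in range(ln):
                partner[p1 + j] = seq2[p2 + j]
            p1 += ln
            p2 += ln
            in_gap = False
        elif op == "X":
            for j in range(ln):
                partner[p1 + j] = seq2[p2 + j]
                a1 = dna.BASES.index(seq1[p1 + j])
                a2 = dna.BASES.index(seq2[p2 + j])
                if counts1[a1, p1 + j] >= min_reads \
                        and counts2[a2, p2 + j] >= min_reads:
                    sites += 1
            p1 += ln
            p2 += ln
            in_gap = False
        else:  # I/D: one indel event per gap run, requires covered flanks
            if not in_gap \
                    and calls1.assessed[min(p1, calls1.depth.size - 1)] \
                    and calls2.assessed[min(p2, calls2.depth.size - 1)]:
                sites += 1
            in_gap = True
            if op == "I":
                p2 += ln
            else:
                p1 += ln
        columns += ln
    return sites, columns, partner


def call_heterozygosity(hit: TranscriptHit,
                        contig_seqs: Dict[str, str],
                        pileups: Dict[str, np.ndarray],
                        site_calls: Dict[str, SiteCalls],
                        group: str,
                        min_depth: int = 10, min_reads: int = 2
                        ) -> Tuple[float, int, int, bool, Dict[int, str]]:
    """Heterozygosity of one gene.

    Merged genes (one locus): heterozygous sites from the pileup over the
    transcribed positions, denominated by positions at adequate depth.
    Split genes (two loci): differing columns of the locus-locus alignment,
    each requiring read support on its own contig.

    Returns (het_percent, sites, assessed_length, low_confidence,
    partner-base map for split genes).
    """
    if not hit.loci:
        raise HetcallError(f"{hit.tx_id}: no mapped locus")
    top = hit.loci[0]
    partner: Dict[int, str] = {}
    if group == "merged" or len(hit.loci) == 1:
        calls = site_calls[top.contig]
        cols = np.arange(max(top.start, 0),
                         min(top.end, calls.depth.size))
        het = calls.het_sites(include_indels=True)[cols]
        assessed = calls.assessed[cols]
        sites = int(het[assessed].sum())
        n_assessed = int(assessed.sum())
        low_conf = n_assessed < 0.5 * cols.size
    else:
        l1, l2 = hit.loci[0], hit.loci[1]
        sites, n_assessed, partner = _align_split_loci(
            l1, l2, contig_seqs[l1.contig], contig_seqs[l2.contig],
            site_calls[l1.contig], site_calls[l2.contig],
            pileups[l1.contig], pileups[l2.contig], min_reads)
        low_conf = n_assessed == 0
    het_pct = 100.0 * sites / n_assessed if n_assessed else 0.0
    return het_pct, sites, n_assessed, low_conf, partner


def population_variance(hit: TranscriptHit,
                        contig_seqs: Dict[str, str],
                        pileups: Dict[str, np.ndarray],
                        site_calls: Dict[str, SiteCalls],
                        partner: Dict[int, str],
                        min_reads: int = 2) -> Tuple[Optional[float], int, int]:
    """Transcript alleles matching neither haplotype allele, per base.

    Alleles of the genome at a position are the contig base, any
    read-supported base (covers the second haplotype of merged genes), and
    the homologous base of the second locus for split genes. Only
    adequately covered columns count toward the denominator.
    """
    if not hit.loci:
        return None, 0, 0
    top = hit.loci[0]
    seq = contig_seqs[top.contig]
    counts = pileups[top.contig]
    calls = site_calls[top.contig]
    tx = hit.oriented_seq
    sites = 0
    assessed = 0
    for b in top.blocks:
        if b.t_hi <= b.t_lo or b.c_hi <= b.c_lo:
            continue
        res = edlib.align(tx[b.t_lo:b.t_hi], seq[b.c_lo:b.c_hi], mode="NW",
                          task="path")
        tp, cp = b.t_lo, b.c_lo
        for ln, op in _iter_cigar(res["cigar"]):
            if op in ("=", "X"):
                for j in range(ln):
                    p = cp + j
                    if p >= calls.depth.size or not calls.assessed[p]:
                        continue
                    assessed += 1
                    t_base = tx[tp + j]
                    alleles: Set[str] = {seq[p]}
                    alleles |= {dna.BASES[c] for c in
                                alleles_at(counts, p, min_reads)}
                    if p in partner:
                        alleles.add(partner[p])
                    if t_base not in alleles:
                        sites += 1
                tp += ln
                cp += ln
            elif op == "I":
                tp += ln
            else:
                cp += ln
    if assessed == 0:
        return None, 0, 0
    return 100.0 * sites / assessed, sites, assessed


# ---------------------------------------------------------------------------
# synonymous / non-synonymous classification


_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_AA.update({c: "*" for c in _TABLE.stop_codons})


def classify_substitutions(coding_a: str, coding_b: str
                           ) -> Tuple[int, int, int]:
    """Codon-wise comparison of two aligned in-frame coding sequences.

    Inputs may contain ``-`` gap characters from a pairwise alignment; gap
    runs are counted as frame-disrupting indel events and the codons they
    interrupt are skipped. Returns (synonymous, non_synonymous,
    indel_events).
    """
    if len(coding_a) != len(coding_b):
        raise HetcallError("aligned sequences must have equal length")
    a_clean = coding_a.replace("-", "")
    if len(a_clean) % 3 != 0:
        raise HetcallError("coding length not divisible by 3 after "
                           "indel decomposition")
    syn = nonsyn = indels = 0
    in_gap = False
    codon_a: List[str] = []
    codon_b: List[str] = []
    dirty = False
    for ca, cb in zip(coding_a.upper(), coding_b.upper()):
        if ca == "-" or cb == "-":
            if not in_gap:
                indels += 1
            in_gap = True
            dirty = True
            if ca == "-":
                continue            # insertion in b: no frame advance on a
        else:
            in_gap = False
            codon_b.append(cb)
        codon_a.append(ca)
        if len(codon_a) == 3:
            if not dirty and len(codon_b) == 3:
                ka, kb = "".join(codon_a), "".join(codon_b)
                if ka != kb:
                    if _AA[ka] == _AA[kb]:
                        syn += 1
                    else:
                        nonsyn += 1
            codon_a, codon_b, dirty = [], [], False
    return syn, nonsyn, indels


# ---------------------------------------------------------------------------
# top-level per-gene table


def analyze_genes(transcripts: Dict[str, str], gene_of: Dict[str, str],
                  contig_seqs: Dict[str, str],
                  pileups: Dict[str, np.ndarray],
                  min_depth: int = 10, min_reads: int = 2,
                  min_maf: float = 0.2,
                  boundary: Optional[float] = None
                  ) -> Tuple[pd.DataFrame, CoverageGroups,
                             Dict[str, TranscriptHit]]:
    """Run the full per-gene pipeline and return the gene table."""
    hits = map_transcripts_and_filter(transcripts, contig_seqs)
    site_calls = {name: call_sites(counts, min_depth, min_reads, min_maf)
                  for name, counts in pileups.items()}
    cov = region_coverage(pileups, hits, gene_of)
    if cov.empty:
        return pd.DataFrame(), CoverageGroups(
            float("inf"), float("inf"), None, None, {}, True), hits
    groups = classify_coverage_groups(cov, boundary=boundary)
    depth_of = dict(zip(cov["gene_id"], cov["depth"]))
    records: List[GeneHetRecord] = []
    for tx_id, hit in hits.items():
        if not hit.loci:
            continue
        gene = gene_of[tx_id]
        group = groups.assignment.get(gene, "unassigned")
        het_pct, sites, assessed, low_conf, partner = call_heterozygosity(
            hit, contig_seqs, pileups, site_calls, group,
            min_depth, min_reads)
        pv_pct, pv_sites, pv_assessed = population_variance(
            hit, contig_seqs, pileups, site_calls, partner, min_reads)
        records.append(GeneHetRecord(
            gene, group, depth_of.get(gene, 0.0), het_pct, sites, assessed,
            pv_pct, pv_sites, pv_assessed, low_confidence=low_conf))
    table = pd.DataFrame([r.__dict__ for r in records])
    return table, groups, hits
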