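"""Synthetic diploid genome generator with exhaustive ground truth.

The generator builds haplotype A from random sequence, overwrites part of
it with divergent copies of interspersed repeat families, places intron-
containing gene models in the repeat-free remainder, and then derives
haplotype B by planting SNPs, small indels and rare long (>= 100 bp)
indels. Every planted feature is recorded, so downstream estimators can be
scored against complete truth.

Repeats are placed before variants are drawn, which puts each repeat copy
at homologous positions on both haplotypes (diverging only by the planted
heterozygosity) — repeat content then inflates k-mer multiplicities
without biasing heterozygosity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..config import ConfigError, SimConfig
from ..coords import CoordinateMap, Variant, apply_variants
from .. import dna


@dataclass(frozen=True)
class RepeatCopy:
    chrom: str
    start: int
    end: int
    family: str


@dataclass(frozen=True)
class GeneModel:
    """A gene on hapA: ordered exon intervals (0-based, half-open)."""

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    frame: int = 0

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class DiploidGenome:
    hapA: Dict[str, str]
    hapB: Dict[str, str]
    variants: Dict[str, List[Variant]]
    repeats: List[RepeatCopy]
    genes: List[GeneModel]
    coord_maps: Dict[str, CoordinateMap]
    config: SimConfig

    def all_variants(self) -> List[Variant]:
        out: List[Variant] = []
        for chrom in sorted(self.variants):
            out.extend(self.variants[chrom])
        return out

    def hap(self, which: str) -> Dict[str, str]:
        if which == "A":
            return self.hapA
        if which == "B":
            return self.hapB
        raise ValueError("haplotype must be 'A' or 'B'")


# ---------------------------------------------------------------------------
# repeats


def _scatter_nonoverlapping(lo: int, hi: int, unit: int, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Uniform non-overlapping placement of ``n`` unit-length blocks."""
    free = (hi - lo) - n * unit
    starts = np.sort(rng.integers(0, free + 1, size=n))
    return lo + starts + np.arange(n) * unit


def _plant_repeats(codes: np.ndarray, chrom: str, cfg: SimConfig,
                   families: List[str], rng: np.random.Generator,
                   reserved: Sequence[Tuple[int, int]]) -> List[RepeatCopy]:
    """Fill repeat copies into the space left between reserved gene loci."""
    L = len(codes)
    unit = cfg.repeat_unit_len
    n_copies = int(round(cfg.repeat_fraction * L)) // unit
    if n_copies == 0:
        return []
    free = _free_intervals(L, reserved)
    capacity = np.array([(e - s) // unit for s, e in free])
    if capacity.sum() < n_copies:
        raise ConfigError(
            "repeat_fraction infeasible after reserving gene loci")
    # proportional allocation of copies across free intervals
    alloc = np.floor(capacity * n_copies / capacity.sum()).astype(int)
    short = n_copies - alloc.sum()
    for i in np.argsort(capacity - alloc)[::-1][:short]:
        alloc[i] += 1
    copies: List[RepeatCopy] = []
    for (s, e), k in zip(free, alloc):
        if k == 0:
            continue
        starts = _scatter_nonoverlapping(s, e, unit, int(k), rng)
        fam_idx = rng.integers(0, len(families), size=int(k))
        for st, fi in zip(starts, fam_idx):
            copy = dna.mutate(families[fi], rng, cfg.repeat_divergence)
            codes[st:st + unit] = dna.encode(copy)
            copies.append(RepeatCopy(chrom, int(st), int(st) + unit,
                                     f"fam{fi}"))
    return copies


# ---------------------------------------------------------------------------
# gene models


def _free_intervals(L: int, occupied: Sequence[Tuple[int, int]]
                    ) -> List[Tuple[int, int]]:
    out = []
    cursor = 0
    for s, e in sorted(occupied):
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < L:
        out.append((cursor, L))
    return out


def _draft_gene_structure(cfg: SimConfig, rng: np.random.Generator
                          ) -> Tuple[List[int], List[int]]:
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    ex = [int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
          for _ in range(n_ex)]
    intr = [int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
            for _ in range(n_ex - 1)]
    # keep the spliced product in frame
    ex[-1] += (3 - sum(ex) % 3) % 3
    return ex, intr


def _place_genes(chrom_lens: Dict[str, int], cfg: SimConfig,
                 rng: np.random.Generator) -> List[GeneModel]:
    """Reserve repeat-free gene loci, spread over the chromosomes."""
    if cfg.n_genes == 0:
        return []
    chroms = sorted(chrom_lens)
    per_chrom = np.full(len(chroms), cfg.n_genes // len(chroms))
    per_chrom[:cfg.n_genes % len(chroms)] += 1
    genes: List[GeneModel] = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        L = chrom_lens[chrom]
        drafts = [_draft_gene_structure(cfg, rng) for _ in range(n)]
        spans = np.array([sum(ex) + sum(intr) for ex, intr in drafts])
        total = int(spans.sum())
        if total > L:
            raise ConfigError(
                f"{n} genes spanning {total} bp cannot fit in {L} bp")
        # uniform non-overlapping placement of the variable-length spans
        slack = L - total
        gaps = np.sort(rng.integers(0, slack + 1, size=n))
        starts = gaps + np.concatenate(([0], np.cumsum(spans[:-1])))
        for (ex, intr), start in zip(drafts, starts):
            exons = []
            pos = int(start)
            for j, el in enumerate(ex):
                exons.append((pos, pos + el))
                pos += el
                if j < len(intr):
                    pos += intr[j]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gid:04d}", chrom, strand,
                                   tuple(exons)))
            gid += 1
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# variants


def _truncated_geometric(rng: np.random.Generator, p: float, lo: int,
                         hi: Optional[int], size: int) -> np.ndarray:
    ln = lo - 1 + rng.geometric(p, size=size)
    if hi is not None:
        ln = np.minimum(ln, hi)
    return ln


def left_normalize(codes: np.ndarray, pos: int, kind: str, allele: np.ndarray
                   ) -> Tuple[int, np.ndarray]:
    """Shift an indel to its leftmost equivalent representation.

    For a deletion of ``codes[pos:pos+n]`` the window slides left while the
    base preceding it equals the last base of the window; an insertion
    rotates analogously against the reference.
    """
    n = len(allele)
    if kind == "del":
        while pos > 0 and codes[pos - 1] == codes[pos + n - 1]:
            pos -= 1
        return pos, codes[pos:pos + n].copy()
    if kind == "ins":
        allele = allele.copy()
        while pos > 0 and codes[pos - 1] == allele[-1]:
            allele = np.concatenate(([codes[pos - 1]], allele[:-1]))
            pos -= 1
        return pos, allele
    return pos, allele


def _plant_variants(codes: np.ndarray, chrom: str, cfg: SimConfig,
                    rng: np.random.Generator) -> List[Variant]:
    L = len(codes)
    # draw indels first; SNPs colliding with an indel footprint are dropped
    raw: List[Tuple[int, str, np.ndarray]] = []
    if cfg.small_indel_rate > 0:
        pos = np.flatnonzero(rng.random(L) < cfg.small_indel_rate)
        lens = _truncated_geometric(rng, cfg.small_indel_geom_p, 1,
                                    cfg.small_indel_max_len, pos.size)
        kinds = rng.random(pos.size) < 0.5
        for p, ln, is_ins in zip(pos, lens, kinds):
            if is_ins:
                raw.append((int(p), "ins", dna.random_codes(rng, int(ln))))
            else:
                raw.append((int(p), "del", codes[p:p + ln].copy()))
    if cfg.large_indel_rate > 0:
        pos = np.flatnonzero(rng.random(L) < cfg.large_indel_rate)
        lens = _truncated_geometric(rng, cfg.large_indel_geom_p,
                                    cfg.large_indel_min_len, None, pos.size)
        kinds = rng.random(pos.size) < 0.5
        for p, ln, is_ins in zip(pos, lens, kinds):
            if is_ins:
                raw.append((int(p), "ins", dna.random_codes(rng, int(ln))))
            else:
                raw.append((int(p), "del", codes[p:p + ln].copy()))

    indels: List[Tuple[int, str, np.ndarray]] = []
    # wide exclusion keeps indel events apart; the SNP zone additionally
    # bans SNPs close enough to an indel for an aligner to absorb them
    # into a slid gap (truth must stay alignment-identifiable)
    snp_guard = 8
    wide = np.zeros(L, dtype=bool)
    occupied = np.zeros(L, dtype=bool)
    spacing = cfg.indel_spacing
    for p, kind, allele in sorted(raw, key=lambda t: t[0]):
        n = len(allele)
        if kind == "del" and p + n > L:
            continue
        p, allele = left_normalize(codes, p, kind, allele)
        end = (p + n) if kind == "del" else p
        if wide[max(p - spacing, 0):min(end + spacing, L)].any():
            continue
        wide[max(p - spacing, 0):min(end + spacing, L)] = True
        occupied[max(p - snp_guard, 0):min(end + snp_guard, L)] = True
        indels.append((p, kind, allele))

    variants: List[Variant] = []
    if cfg.snp_rate > 0:
        # regional heterozygosity: mean-normalised lognormal factor per
        # window keeps the genome-wide rate at snp_rate while individual
        # regions range realistically around it
        if cfg.het_lognormal_sigma > 0 and cfg.het_window < L:
            n_win = -(-L // cfg.het_window)
            factors = rng.lognormal(0.0, cfg.het_lognormal_sigma, n_win)
            factors /= factors.mean()
            rate = np.minimum(
                cfg.snp_rate * factors[np.arange(L) // cfg.het_window], 0.75)
        else:
            rate = np.full(L, cfg.snp_rate)
        # compensate for the indel exclusion zones so the realised
        # genome-wide SNP rate stays calibrated to snp_rate
        free = L - int(occupied.sum())
        if 0 < free < L:
            rate = np.minimum(rate * (L / free), 0.75)
        snp_pos = np.flatnonzero(rng.random(L) < rate)
        snp_pos = snp_pos[~occupied[snp_pos]]
        shift = rng.integers(1, 4, size=snp_pos.size)
        for p, sh in zip(snp_pos, shift):
            ref = dna.BASES[codes[p]]
            alt = dna.BASES[(codes[p] + sh) % 4]
            variants.append(Variant(chrom, int(p), "snp", ref, alt))
    for p, kind, allele in indels:
        s = dna.decode(allele)
        if kind == "del":
            variants.append(Variant(chrom, p, "del", s, ""))
        else:
            variants.append(Variant(chrom, p, "ins", "", s))
    variants.sort(key=lambda v: (v.pos, v.kind != "ins"))
    return variants


# ---------------------------------------------------------------------------
# top level


def simulate_diploid(cfg: SimConfig) -> DiploidGenome:
    """Generate a diploid genome under ``cfg`` with full truth tables."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    per = cfg.haploid_length // cfg.n_sequences
    if per < max(cfg.repeat_unit_len, cfg.read_len):
        raise ConfigError("sequences too short for configured features")
    chrom_lens = {f"chr{i}": per for i in range(cfg.n_sequences)}

    families = [dna.random_seq(rng, cfg.repeat_unit_len)
                for _ in range(cfg.n_repeat_families)]
    genes = _place_genes(chrom_lens, cfg, rng)
    hapA: Dict[str, str] = {}
    hapB: Dict[str, str] = {}
    variants: Dict[str, List[Variant]] = {}
    coord_maps: Dict[str, CoordinateMap] = {}
    repeats: List[RepeatCopy] = []
    for chrom, L in chrom_lens.items():
        codes = dna.random_codes(rng, L)
        if cfg.repeat_fraction > 0 and cfg.n_repeat_families > 0:
            reserved = [(g.start, g.end) for g in genes if g.chrom == chrom]
            repeats.extend(_plant_repeats(codes, chrom, cfg, families, rng,
                                          reserved))
        seq = dna.decode(codes)
        vs = _plant_variants(codes, chrom, cfg, rng)
        hapA[chrom] = seq
        hapB[chrom] = apply_variants(seq, vs)
        variants[chrom] = vs
        coord_maps[chrom] = CoordinateMap.from_variants(vs, L)

    return DiploidGenome(hapA, hapB, variants, repeats, genes,
                         coord_maps, cfg)
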