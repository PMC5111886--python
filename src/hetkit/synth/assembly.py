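"""Emulated contig assemblies cut from the two haplotypes.

Real assemblies of highly heterozygous genomes assemble many regions twice
(once per haplotype) and merge others into a single consensus. Two
emulations are provided:

* :func:`fragment_haplotypes` — cut BOTH haplotypes independently into
  pieces; every region is represented twice. This is the input for testing
  allelic-contig discovery and collapse.
* :func:`paired_assembly` — cut hapA into pieces whose boundaries avoid
  gene models; each piece contributes its hapA contig and, with probability
  ``split_prob``, the homologous hapB contig as well. Genes inside pieces
  with both contigs are truly "split" (haplotypes assembled separately),
  the rest are "merged" — ground truth for the coverage-group classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np

from .genome import DiploidGenome


@dataclass(frozen=True)
class AssemblyContig:
    name: str
    chrom: str
    hap: str          # "A" | "B"
    start: int        # own-haplotype coordinates, half-open
    end: int
    a_start: int      # ancestral (hapA) projection
    a_end: int
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def _cut_points(L: int, min_len: int, max_len: int,
                rng: np.random.Generator) -> List[Tuple[int, int]]:
    pieces = []
    pos = 0
    while pos < L:
        ln = int(rng.integers(min_len, max_len + 1))
        end = min(pos + ln, L)
        if L - end < min_len:
            end = L
        pieces.append((pos, end))
        pos = end
    return pieces


def fragment_haplotypes(genome: DiploidGenome, seed: int,
                        min_len: int = 5_000, max_len: int = 20_000
                        ) -> List[AssemblyContig]:
    """Cut both haplotypes independently into 5–20 kb style pieces."""
    rng = np.random.default_rng([seed, 10])
    contigs: List[AssemblyContig] = []
    for chrom in sorted(genome.hapA):
        cmap = genome.coord_maps[chrom]
        for hap in "AB":
            seq = genome.hap(hap)[chrom]
            for i, (s, e) in enumerate(_cut_points(len(seq), min_len,
                                                   max_len, rng)):
                if hap == "A":
                    a0, a1 = s, e
                else:
                    a0, a1 = cmap.interval_b_to_a(s, e)
                contigs.append(AssemblyContig(
                    f"{chrom}.{hap}.{i:04d}", chrom, hap, s, e, a0, a1,
                    seq[s:e]))
    return contigs


def true_allelic_pairs(contigs: List[AssemblyContig],
                       min_mutual_overlap: float = 0.95
                       ) -> Set[FrozenSet[str]]:
    """Pairs of opposite-haplotype contigs with high mutual ancestral overlap."""
    pairs: Set[FrozenSet[str]] = set()
    by_chrom: Dict[str, List[AssemblyContig]] = {}
    for c in contigs:
        by_chrom.setdefault(c.chrom, []).append(c)
    for group in by_chrom.values():
        a_side = [c for c in group if c.hap == "A"]
        b_side = [c for c in group if c.hap == "B"]
        for ca in a_side:
            for cb in b_side:
                lo = max(ca.a_start, cb.a_start)
                hi = min(ca.a_end, cb.a_end)
                if hi <= lo:
                    continue
                shorter = min(ca.a_end - ca.a_start, cb.a_end - cb.a_start)
                if (hi - lo) / shorter >= min_mutual_overlap:
                    pairs.add(frozenset((ca.name, cb.name)))
    return pairs


def paired_assembly(genome: DiploidGenome, seed: int,
                    min_len: int = 10_000, max_len: int = 30_000,
                    split_rule: str = "density", split_prob: float = 0.5,
                    margin: int = 200
                    ) -> Tuple[List[AssemblyContig], Dict[str, str]]:
    """Gene-aware assembly emulation with known merged/split truth.

    With ``split_rule="density"`` a piece keeps both haplotype contigs
    exactly when its planted-variant density exceeds the chromosome-wide
    mean — the mechanism by which heterozygosity defeats haplotype
    merging in real assemblies, and the reason the split-haplotype gene
    group is the more heterozygous one. ``split_rule="random"`` splits
    with probability ``split_prob`` instead.

    Returns the contig list and a mapping gene_id -> "split" | "merged".
    """
    rng = np.random.default_rng([seed, 11])
    contigs: List[AssemblyContig] = []
    status: Dict[str, str] = {}
    for chrom in sorted(genome.hapA):
        cmap = genome.coord_maps[chrom]
        seqA = genome.hapA[chrom]
        seqB = genome.hapB[chrom]
        L = len(seqA)
        genes = [g for g in genome.genes if g.chrom == chrom]
        spans = sorted((g.start - margin, g.end + margin) for g in genes)
        pieces: List[Tuple[int, int]] = []
        pos = 0
        while pos < L:
            end = min(pos + int(rng.integers(min_len, max_len + 1)), L)
            for s, e in spans:       # never cut through a gene body
                if s < end < e:
                    end = min(e, L)
            if L - end < min_len:
                end = L
            pieces.append((pos, end))
            pos = end
        var_pos = np.array([v.pos for v in genome.variants[chrom]],
                           dtype=np.int64)
        mean_density = var_pos.size / L if L else 0.0
        for i, (s, e) in enumerate(pieces):
            if split_rule == "density":
                n_var = int(np.searchsorted(var_pos, e)
                            - np.searchsorted(var_pos, s))
                split = n_var / max(e - s, 1) > mean_density
            else:
                split = rng.random() < split_prob
            contigs.append(AssemblyContig(
                f"{chrom}.A.{i:04d}", chrom, "A", s, e, s, e, seqA[s:e]))
            if split:
                bs, be = cmap.interval_a_to_b(s, e)
                contigs.append(AssemblyContig(
                    f"{chrom}.B.{i:04d}", chrom, "B", bs, be, s, e,
                    seqB[bs:be]))
            for g in genes:
                if s <= g.start and g.end <= e:
                    status[g.gene_id] = "split" if split else "merged"
    return contigs, status
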