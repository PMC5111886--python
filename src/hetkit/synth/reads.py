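"""Paired-end shotgun read simulation over both haplotypes.

Each haplotype is sampled independently at ``coverage_per_haplotype`` fold,
so homozygous regions of a collapsed assembly see twice that depth — the
coverage-bimodality signal the downstream classifiers rely on. Errors are
substitutions only; read bases are stored genome-oriented (the second mate
is reverse-complemented on FASTQ export only), which keeps truth-guided
placement and pileups straightforward.

Optionally, reads can carry extra "population" alleles at sites drawn once
per chromosome, emulating libraries pooled from several individuals whose
chromosomes segregate a third allele at a modest frequency.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..config import ConfigError, SimConfig
from .. import dna
from .genome import DiploidGenome

_POP_ALLELE_FREQ = 0.5   # carrier frequency of a population allele in reads


@dataclass
class ReadPopSite:
    chrom: str
    pos_a: int          # hapA coordinate
    alt: str


@dataclass
class ReadSet:
    """Paired reads with per-pair truth of origin.

    ``r1``/``r2`` are (n_pairs, read_len) uint8 code matrices in genome
    orientation. ``frag_start``/``frag_len`` are on the source haplotype of
    each pair (``hap``: 0 = A, 1 = B), ``chrom_id`` indexes ``chroms``.
    """

    chroms: List[str]
    read_len: int
    r1: np.ndarray
    r2: np.ndarray
    chrom_id: np.ndarray
    hap: np.ndarray
    frag_start: np.ndarray
    frag_len: np.ndarray
    pop_sites: List[ReadPopSite] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def all_codes(self) -> np.ndarray:
        """All reads (both mates) as one (2n, read_len) code matrix."""
        return np.concatenate([self.r1, self.r2], axis=0)

    def take(self, mask: np.ndarray) -> "ReadSet":
        """Subset of read pairs selected by boolean mask or index array."""
        return ReadSet(self.chroms, self.read_len,
                       self.r1[mask], self.r2[mask],
                       self.chrom_id[mask], self.hap[mask],
                       self.frag_start[mask], self.frag_len[mask],
                       self.pop_sites)

    def mate_intervals(self, mate: int) -> Tuple[np.ndarray, np.ndarray]:
        """Source-haplotype [start, end) of mate 1 or 2 for every pair."""
        if mate == 1:
            start = self.frag_start
        elif mate == 2:
            start = self.frag_start + self.frag_len - self.read_len
        else:
            raise ValueError("mate must be 1 or 2")
        return start, start + self.read_len

    # -- FASTQ --------------------------------------------------------------

    def write_fastq(self, path1, path2) -> None:
        qual = "I" * self.read_len
        hapc = np.array(["A", "B"])
        with _opener(path1) as f1, _opener(path2) as f2:
            for i in range(self.n_pairs):
                name = (f"sim.{i}:{self.chroms[self.chrom_id[i]]}"
                        f":{hapc[self.hap[i]]}:{self.frag_start[i]}"
                        f":{self.frag_len[i]}")
                f1.write(f"@{name}/1\n{dna.decode(self.r1[i])}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n"
                         f"{dna.revcomp(dna.decode(self.r2[i]))}\n+\n{qual}\n")


def _opener(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def simulate_reads(genome: DiploidGenome, cfg: SimConfig) -> ReadSet:
    """Simulate paired reads from both haplotypes at configured coverage."""
    if cfg.coverage_per_haplotype <= 0:
        raise ConfigError("coverage_per_haplotype must be positive")
    rl = cfg.read_len
    rng = np.random.default_rng([cfg.seed, 1])
    chroms = sorted(genome.hapA)
    for chrom in chroms:
        if rl > len(genome.hapA[chrom]) or rl > len(genome.hapB[chrom]):
            raise ConfigError("read_len exceeds shortest sequence")

    parts: Dict[str, List[np.ndarray]] = {k: [] for k in
                                          ("r1", "r2", "cid", "hap", "fs", "fl")}
    for ci, chrom in enumerate(chroms):
        for hap_idx, seq in enumerate((genome.hapA[chrom], genome.hapB[chrom])):
            codes = dna.encode(seq)
            L = len(codes)
            n_pairs = int(round(cfg.coverage_per_haplotype * L / (2 * rl)))
            flen = rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=n_pairs)
            flen = np.clip(np.rint(flen), rl, L).astype(np.int64)
            start = (rng.random(n_pairs) * (L - flen + 1)).astype(np.int64)
            offs = np.arange(rl)
            r1 = codes[start[:, None] + offs]
            r2 = codes[(start + flen - rl)[:, None] + offs]
            parts["r1"].append(r1)
            parts["r2"].append(r2)
            parts["cid"].append(np.full(n_pairs, ci, dtype=np.int32))
            parts["hap"].append(np.full(n_pairs, hap_idx, dtype=np.uint8))
            parts["fs"].append(start)
            parts["fl"].append(flen)

    rs = ReadSet(
        chroms=chroms,
        read_len=rl,
        r1=np.concatenate(parts["r1"]),
        r2=np.concatenate(parts["r2"]),
        chrom_id=np.concatenate(parts["cid"]),
        hap=np.concatenate(parts["hap"]),
        frag_start=np.concatenate(parts["fs"]),
        frag_len=np.concatenate(parts["fl"]),
    )
    if cfg.read_population_variant_rate > 0:
        rs.pop_sites = _plant_population_alleles(rs, genome, cfg, rng)
    if cfg.seq_error_rate > 0:
        for mat in (rs.r1, rs.r2):
            err = rng.random(mat.shape) < cfg.seq_error_rate
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4
    return rs


def _plant_population_alleles(rs: ReadSet, genome: DiploidGenome,
                              cfg: SimConfig, rng: np.random.Generator
                              ) -> List[ReadPopSite]:
    """Overwrite read bases with a third allele at a subset of SNP sites.

    Population third alleles segregate at sites that are already
    polymorphic in the individual ("more than 2 alleles" at a site): each
    planted SNP site carries a third allele in the wider pool with
    probability ``read_population_variant_rate``, and a fraction of the
    reads of one haplotype background are rewritten as carriers.
    """
    sites: List[ReadPopSite] = []
    for ci, chrom in enumerate(rs.chroms):
        seqB = genome.hapB[chrom]
        cmap = genome.coord_maps[chrom]
        snps = [v for v in genome.variants[chrom] if v.kind == "snp"]
        chosen = rng.random(len(snps)) < cfg.read_population_variant_rate
        for v, hit in zip(snps, chosen):
            if not hit:
                continue
            p = v.pos
            pb = cmap.a_to_b(p)
            taken = {v.ref, v.alt}
            if pb < len(seqB):
                taken.add(seqB[pb])
            options = [b for b in dna.BASES if b not in taken]
            alt = options[int(rng.integers(0, len(options)))]
            alt_code = dna.BASES.index(alt)
            hap_idx = int(rng.integers(0, 2))      # carrier background
            hp = p if hap_idx == 0 else pb
            sel = (rs.chrom_id == ci) & (rs.hap == hap_idx)
            for mate, mat in ((1, rs.r1), (2, rs.r2)):
                s, e = rs.mate_intervals(mate)
                cover = np.flatnonzero(sel & (s <= hp) & (hp < e))
                if cover.size == 0:
                    continue
                carrier = cover[rng.random(cover.size) < _POP_ALLELE_FREQ]
                mat[carrier, hp - s[carrier]] = alt_code
            sites.append(ReadPopSite(chrom, int(p), alt))
    return sites
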