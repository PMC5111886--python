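"""Transcript simulation: spliced haplotype products plus population alleles.

Each gene yields one transcript: the spliced exons of one randomly chosen
haplotype (minus strand genes are reverse-complemented). On top of the
haplotype sequence, extra variants are planted at ``population_variant_rate``
per transcribed base, emulating transcriptomes assembled from pooled
laboratory populations that segregate alleles absent from the single
sequenced individual. Planted alleles always differ from BOTH haplotype
alleles at the site, so they are unambiguous third alleles in the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from ..config import ConfigError, SimConfig
from .. import dna
from .genome import DiploidGenome

_TRUTH_COLS = ["tx_id", "gene_id", "tx_pos", "chrom", "pos_a",
               "ref_a", "ref_b", "alt", "origin_hap"]


@dataclass
class TranscriptSet:
    seqs: Dict[str, str]
    gene_of: Dict[str, str]
    origin: Dict[str, str]            # tx_id -> "A" | "B"
    truth: pd.DataFrame               # planted population variants

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for tx in sorted(self.seqs):
                fh.write(f">{tx} gene={self.gene_of[tx]} hap={self.origin[tx]}\n")
                seq = self.seqs[tx]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    def write_truth_tsv(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_truth_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t",
                           dtype={c: str for c in
                                  ("tx_id", "gene_id", "chrom", "ref_a",
                                   "ref_b", "alt", "origin_hap")})


def simulate_transcripts(genome: DiploidGenome, cfg: SimConfig
                         ) -> TranscriptSet:
    """One transcript per gene from a random haplotype, plus extra alleles."""
    if not genome.genes:
        raise ConfigError("genome has no gene models")
    rng = np.random.default_rng([cfg.seed, 2])
    seqs: Dict[str, str] = {}
    gene_of: Dict[str, str] = {}
    origin: Dict[str, str] = {}
    rows: List[list] = []
    for gene in genome.genes:
        tx_id = f"{gene.gene_id}.t1"
        hap = "A" if rng.random() < 0.5 else "B"
        cmap = genome.coord_maps[gene.chrom]
        seqA = genome.hapA[gene.chrom]
        seqB = genome.hapB[gene.chrom]
        bases: List[str] = []
        pos_a: List[int] = []          # hapA position per transcript base, -1 if none
        for (s, e) in gene.exons:
            if hap == "A":
                bases.append(seqA[s:e])
                pos_a.extend(range(s, e))
            else:
                bs, be = cmap.interval_a_to_b(s, e)
                bases.append(seqB[bs:be])
                for b in range(bs, be):
                    a = cmap.b_to_a(b)
                    # positions inside hapB insertions have no hapA partner
                    pos_a.append(a if cmap.a_to_b(a) == b else -1)
        tx = "".join(bases)
        pa = np.array(pos_a, dtype=np.int64)
        if gene.strand == "-":
            tx = dna.revcomp(tx)
            pa = pa[::-1]
        tx_codes = dna.encode(tx)

        if cfg.population_variant_rate > 0:
            hits = np.flatnonzero(
                rng.random(len(tx_codes)) < cfg.population_variant_rate)
            for t in hits:
                a = int(pa[t])
                taken = {tx[t]}
                ref_a = ref_b = "."
                if a >= 0:
                    ref_a = seqA[a]
                    b = cmap.a_to_b(a)
                    if cmap.b_to_a(b) == a:
                        ref_b = seqB[b]
                    if gene.strand == "-":
                        taken |= {dna.revcomp(ref_a), dna.revcomp(ref_b)}
                    else:
                        taken |= {ref_a, ref_b}
                taken.discard(".")
                options = [x for x in dna.BASES if x not in taken]
                alt = options[int(rng.integers(0, len(options)))]
                tx_codes[t] = dna.BASES.index(alt)
                # record the alt genome-oriented so it is comparable with
                # the ref_a/ref_b columns
                genome_alt = dna.revcomp(alt) if gene.strand == "-" else alt
                rows.append([tx_id, gene.gene_id, int(t), gene.chrom, a,
                             ref_a, ref_b, genome_alt, hap])
        seqs[tx_id] = dna.decode(tx_codes)
        gene_of[tx_id] = gene.gene_id
        origin[tx_id] = hap
    truth = pd.DataFrame(rows, columns=_TRUTH_COLS)
    return TranscriptSet(seqs, gene_of, origin, truth)
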