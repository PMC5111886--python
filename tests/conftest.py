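"""Shared synthetic bundles, generated once per session.

Two regimes: `bundle` has sequencing errors and population variants (the
realistic het-calling regime); `clean_bundle` is error-free (exact-truth
comparisons for overlap accounting).
"""

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pytest

from hetkit import SimConfig
from hetkit.pileup import build_pileups
from hetkit.placement import place_readset
from hetkit.synth import (paired_assembly, simulate_diploid,
                          simulate_fragments, simulate_reads,
                          simulate_transcripts)


@dataclass
class Bundle:
    cfg: SimConfig
    genome: object
    reads: object
    transcripts: object
    fragments: object
    contigs: list
    status: Dict[str, str]
    pileups: Dict[str, np.ndarray]

    @property
    def contig_seqs(self):
        return {c.name: c.seq for c in self.contigs}


def _make_bundle(cfg: SimConfig) -> Bundle:
    genome = simulate_diploid(cfg)
    reads = simulate_reads(genome, cfg)
    transcripts = simulate_transcripts(genome, cfg)
    fragments = simulate_fragments(genome, cfg)
    contigs, status = paired_assembly(genome, cfg.seed)
    placements = place_readset(reads, contigs, genome)
    pileups = build_pileups(placements, {c.name: len(c.seq) for c in contigs})
    return Bundle(cfg, genome, reads, transcripts, fragments, contigs,
                  status, pileups)


@pytest.fixture(scope="session")
def bundle() -> Bundle:
    cfg = SimConfig(haploid_length=150_000, coverage_per_haplotype=30,
                    n_genes=16, seq_error_rate=0.005,
                    population_variant_rate=0.008,
                    fragment_len=20_000, fragment_overlap=4_000,
                    seed=42)
    return _make_bundle(cfg)


@pytest.fixture(scope="session")
def clean_bundle() -> Bundle:
    cfg = SimConfig(haploid_length=150_000, coverage_per_haplotype=30,
                    n_genes=8, seq_error_rate=0.0,
                    fragment_len=20_000, fragment_overlap=4_000,
                    seed=7)
    return _make_bundle(cfg)
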