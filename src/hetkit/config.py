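"""Simulation configuration for the synthetic diploid generator.

The defaults encode the regime the generator is meant to emulate: a highly
heterozygous diploid (per-base SNP heterozygosity in the low percents, small
indels plus rare polynucleotide events of 100 bp and more), a repeat-rich
genome (repeat families covering over half the sequence), ~75-fold shotgun
coverage per haplotype, and transcripts sampled from a wider laboratory
population that carries extra alleles at just under 1% of transcribed bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml


@dataclass
class SimConfig:
    """Parameters of one synthetic diploid experiment.

    All rates are per-base probabilities in [0, 1]; lengths are in bases;
    ``coverage_per_haplotype`` is fold coverage contributed by each of the
    two haplotypes (so homozygous regions see twice that depth). The same
    ``seed`` always reproduces bit-identical outputs.
    """

    # genome
    haploid_length: int = 1_000_000
    n_sequences: int = 1
    # variants between the two haplotypes; the SNP rate is modulated along
    # each chromosome by mean-normalised lognormal window factors so that
    # per-region heterozygosity spans a realistic range around snp_rate
    snp_rate: float = 0.025
    het_window: int = 20_000
    het_lognormal_sigma: float = 0.5
    small_indel_rate: float = 0.002
    small_indel_geom_p: float = 0.35     # truncated-geometric body, 1..max
    small_indel_max_len: int = 20
    large_indel_rate: float = 2e-5
    large_indel_min_len: int = 100
    large_indel_geom_p: float = 0.02     # tail above the minimum length
    # minimum bases between planted indel events: close indel pairs have
    # ambiguous optimal alignments, which would make truth unidentifiable
    indel_spacing: int = 12
    # repeats
    repeat_fraction: float = 0.57
    repeat_unit_len: int = 400
    n_repeat_families: int = 5
    repeat_divergence: float = 0.03
    # gene models
    n_genes: int = 20
    exon_len_range: Tuple[int, int] = (120, 300)
    intron_len_range: Tuple[int, int] = (60, 400)
    exons_per_gene: Tuple[int, int] = (3, 8)
    # shotgun reads
    read_len: int = 150
    fragment_mean: int = 450
    fragment_sd: int = 50
    coverage_per_haplotype: float = 75.0
    seq_error_rate: float = 0.0
    read_population_variant_rate: float = 0.0
    # transcripts
    population_variant_rate: float = 0.008
    # long contiguous fragments (BAC-like)
    n_fragments: int = 6
    fragment_len: int = 30_000
    fragment_overlap: int = 5_000
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "snp_rate": self.snp_rate,
            "small_indel_rate": self.small_indel_rate,
            "large_indel_rate": self.large_indel_rate,
            "seq_error_rate": self.seq_error_rate,
            "population_variant_rate": self.population_variant_rate,
            "read_population_variant_rate": self.read_population_variant_rate,
            "repeat_divergence": self.repeat_divergence,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ConfigError("repeat_fraction must be in [0, 1)")
        if self.fragment_overlap >= self.fragment_len:
            raise ConfigError("fragment_overlap must be smaller than fragment_len")
        if self.haploid_length < 1 or self.n_sequences < 1:
            raise ConfigError("haploid_length and n_sequences must be positive")
        if self.read_len < 1:
            raise ConfigError("read_len must be positive")
        if not 1 <= self.small_indel_max_len:
            raise ConfigError("small_indel_max_len must be >= 1")
        if self.large_indel_min_len <= self.small_indel_max_len:
            raise ConfigError(
                "large_indel_min_len must exceed small_indel_max_len"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("exon_len_range", "intron_len_range", "exons_per_gene"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


class ConfigError(ValueError):
    """Raised for infeasible or out-of-range simulation settings."""
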