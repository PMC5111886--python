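"""K-mer spectrum construction, peaks, genome size, and branch rates."""

import math

import numpy as np
import pytest

from hetkit import SimConfig, dna, kspec
from hetkit.synth import simulate_diploid, simulate_reads


def brute_force_spectrum(reads, k):
    """Independent oracle: dict-based canonical k-mer counting on strings."""
    counts = {}
    for r in reads:
        for i in range(len(r) - k + 1):
            km = r[i:i + k]
            canon = min(km, dna.revcomp(km))
            counts[canon] = counts.get(canon, 0) + 1
    hist = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    return hist


def test_spectrum_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    reads = [dna.random_seq(rng, 60) for _ in range(200)]
    # force some duplicates and palindromic structure
    reads += reads[:50]
    spec = kspec.build_spectrum(reads, 21)
    assert spec.as_dict() == brute_force_spectrum(reads, 21)


def test_small_read_hand_counted():
    """'ACGTACGT' at k=5: 4 k-mers forming 2 canonical pairs."""
    spec = kspec.build_spectrum(["ACGTACGT"], 5)
    assert spec.total_kmers == 4
    assert spec.as_dict() == brute_force_spectrum(["ACGTACGT"], 5)


def test_canonicalization_invariant():
    rng = np.random.default_rng(1)
    reads = [dna.random_seq(rng, 80) for _ in range(300)]
    rc = [dna.revcomp(r) for r in reads]
    a = kspec.build_spectrum(reads, 31)
    b = kspec.build_spectrum(rc, 31)
    assert a.as_dict() == b.as_dict()


def test_k_validation():
    with pytest.raises(kspec.SpectrumError):
        kspec.build_spectrum(["ACGTACGTACGTACGTACGT"], 16)
    with pytest.raises(kspec.SpectrumError):
        kspec.build_spectrum(["ACGTACGTACGTACGTACGT"], 65)


def test_homozygous_mode_matches_coverage_formula(clean_bundle):
    """Error-free reads: spectrum mode ~= C * (L - k + 1) / L per copy."""
    cfg = SimConfig(haploid_length=100_000, coverage_per_haplotype=25,
                    snp_rate=0, small_indel_rate=0, large_indel_rate=0,
                    repeat_fraction=0.0, n_genes=2, seed=11)
    g = simulate_diploid(cfg)
    rs = simulate_reads(g, cfg)
    spec = kspec.build_spectrum(rs, 31)
    # both haplotypes identical: every k-mer at ~2x the per-hap k-mer depth
    expect = 2 * 25 * (150 - 31 + 1) / 150
    hist = spec.hist.copy()
    hist[:5] = 0
    mode = int(np.argmax(hist))
    assert abs(mode - expect) <= max(2, 0.06 * expect)
    peaks = kspec.detect_peaks(spec)
    assert peaks.het_peak is None          # no heterozygous peak
    size = kspec.estimate_genome_size(spec, peaks)
    assert abs(size - 100_000) <= 10_000


def test_diploid_peaks_and_genome_size():
    cfg = SimConfig(haploid_length=200_000, coverage_per_haplotype=40,
                    seq_error_rate=0.005, n_genes=5, seed=12)
    g = simulate_diploid(cfg)
    rs = simulate_reads(g, cfg)
    spec = kspec.build_spectrum(rs, 31)
    peaks = kspec.detect_peaks(spec)
    assert peaks.het_peak is not None
    assert peaks.error_cutoff < peaks.het_peak < peaks.hom_peak
    assert 0.4 <= peaks.peak_ratio <= 0.6
    size = kspec.estimate_genome_size(spec, peaks)
    assert abs(size - 200_000) <= 20_000


def test_genome_size_coverage_invariance():
    """Doubling coverage leaves the size estimate within 5%."""
    sizes = []
    for cov in (20, 40):
        cfg = SimConfig(haploid_length=100_000, coverage_per_haplotype=cov,
                        n_genes=3, seed=13)
        g = simulate_diploid(cfg)
        rs = simulate_reads(g, cfg)
        spec = kspec.build_spectrum(rs, 31)
        sizes.append(kspec.estimate_genome_size(spec, kspec.detect_peaks(spec)))
    assert abs(sizes[1] - sizes[0]) <= 0.05 * sizes[0]


def test_noise_spectrum_has_no_fabricated_peaks():
    hist = np.array([0] + [int(1e6 * 0.5 ** m) for m in range(1, 30)])
    with pytest.raises(kspec.SpectrumError):
        kspec.detect_peaks(kspec.KmerSpectrum(31, hist))


def test_intersection_identical_and_disjoint():
    rng = np.random.default_rng(2)
    reads = [dna.random_seq(rng, 100) for _ in range(500)]
    assert kspec.intersect_kmers(reads, list(reads), 31,
                                 error_cutoff=0) == 1.0
    other = [dna.random_seq(rng, 100) for _ in range(500)]
    assert kspec.intersect_kmers(reads, other, 31, error_cutoff=0) < 0.01
    with pytest.raises(kspec.SpectrumError):
        kspec.intersect_kmers([], reads, 31)


def test_independent_libraries_intersect_high():
    """Two independent 30x read sets of one genome share >=90% of k-mers."""
    cfg = SimConfig(haploid_length=100_000, coverage_per_haplotype=30,
                    n_genes=3, seed=14)
    g = simulate_diploid(cfg)
    cfg2 = SimConfig(**{**cfg.to_dict(), "seed": 15})
    rs1 = simulate_reads(g, cfg)
    rs2 = simulate_reads(g, cfg2)
    assert kspec.intersect_kmers(rs1, rs2, 31) >= 0.9


def test_branch_rates():
    """No branching without het/repeats; monotone in het; repeats add."""
    base = dict(haploid_length=100_000, coverage_per_haplotype=25,
                small_indel_rate=0, large_indel_rate=0, n_genes=3,
                het_lognormal_sigma=0.0)
    rates = {}
    for snp in (0.0, 0.005, 0.025):
        cfg = SimConfig(**base, snp_rate=snp, repeat_fraction=0.0, seed=16)
        g = simulate_diploid(cfg)
        rs = simulate_reads(g, cfg)
        spec = kspec.build_spectrum(rs, 31)
        peaks = kspec.detect_peaks(spec)
        stats = kspec.classify_branches(rs, 31, peaks, max_sample=20_000,
                                        seed=1)
        rates[snp] = stats
    assert rates[0.0].variant_branch_rate < 1e-3
    assert rates[0.0].repeat_branch_rate < 1e-3
    assert rates[0.0].variant_branch_rate <= rates[0.005].variant_branch_rate \
        <= rates[0.025].variant_branch_rate
    assert rates[0.025].variant_branch_rate > 5 * max(
        rates[0.0].variant_branch_rate, 1e-4)
    # adding a dense repeat family boosts the repeat branch rate >= 5x
    cfg = SimConfig(**base, snp_rate=0.0, repeat_fraction=0.5, seed=16)
    g = simulate_diploid(cfg)
    rs = simulate_reads(g, cfg)
    spec = kspec.build_spectrum(rs, 31)
    peaks = kspec.detect_peaks(spec)
    rep = kspec.classify_branches(rs, 31, peaks, max_sample=20_000, seed=1)
    assert rep.repeat_branch_rate >= 5 * max(rates[0.0].repeat_branch_rate,
                                             1e-4)


def test_spectrum_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    reads = [dna.random_seq(rng, 64) for _ in range(100)]
    spec = kspec.build_spectrum(reads, 21)
    spec.write_tsv(tmp_path / "spec.tsv")
    back = kspec.KmerSpectrum.read_tsv(tmp_path / "spec.tsv", 21)
    assert back.as_dict() == spec.as_dict()
    assert back.total_kmers == spec.total_kmers
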