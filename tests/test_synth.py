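"""Generator truth: rates, determinism, serialization, fragment truth."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from hetkit import SimConfig
from hetkit.config import ConfigError
from hetkit.coords import apply_variants
from hetkit.synth import (io as synth_io, simulate_diploid,
                          simulate_fragments, simulate_reads,
                          simulate_transcripts)
from hetkit.synth.transcripts import TranscriptSet


def test_zero_rates_yield_identical_haplotypes():
    cfg = SimConfig(haploid_length=30_000, snp_rate=0, small_indel_rate=0,
                    large_indel_rate=0, n_genes=2, seed=1)
    g = simulate_diploid(cfg)
    assert g.hapA == g.hapB
    assert g.all_variants() == []


def test_snp_count_within_binomial_bound():
    """Realized SNP count within 3 binomial SDs of the configured rate."""
    cfg = SimConfig(haploid_length=1_000_000, snp_rate=0.025,
                    small_indel_rate=0, large_indel_rate=0,
                    het_lognormal_sigma=0.0, n_genes=5, seed=1)
    g = simulate_diploid(cfg)
    n = sum(1 for v in g.all_variants() if v.kind == "snp")
    expect = 1_000_000 * 0.025
    bound = 3 * math.sqrt(1_000_000 * 0.025 * 0.975)
    assert abs(n - expect) <= bound


def test_large_indels_planted():
    """Poisson bound: with >=5 expected events, at least one >=100 bp."""
    cfg = SimConfig(haploid_length=500_000, large_indel_rate=4e-5,
                    n_genes=5, seed=2)
    assert 500_000 * 4e-5 >= 5
    g = simulate_diploid(cfg)
    big = [v for v in g.all_variants() if v.is_indel and v.length >= 100]
    assert len(big) >= 1


def test_reconstruction_and_repeat_fraction():
    cfg = SimConfig(haploid_length=100_000, n_genes=8, seed=3)
    g = simulate_diploid(cfg)
    for chrom in g.hapA:
        assert apply_variants(g.hapA[chrom], g.variants[chrom]) \
            == g.hapB[chrom]
    rep = sum(r.end - r.start for r in g.repeats)
    assert abs(rep / 100_000 - cfg.repeat_fraction) <= 0.1 * cfg.repeat_fraction


def test_variants_left_normalized_and_ordered():
    cfg = SimConfig(haploid_length=200_000, n_genes=5, seed=4)
    g = simulate_diploid(cfg)
    for chrom, vs in g.variants.items():
        seq = g.hapA[chrom]
        assert [v.pos for v in vs] == sorted(v.pos for v in vs)
        for v in vs:
            if v.kind == "del" and v.pos > 0:
                assert seq[v.pos - 1] != v.ref[-1]
            elif v.kind == "ins" and v.pos > 0:
                assert seq[v.pos - 1] != v.alt[-1]


def test_gene_models_valid():
    cfg = SimConfig(haploid_length=120_000, n_genes=10, seed=5)
    g = simulate_diploid(cfg)
    assert len(g.genes) == 10
    for gene in g.genes:
        assert gene.strand in "+-"
        assert gene.spliced_length % 3 == 0
        prev_end = 0
        for s, e in gene.exons:
            assert prev_end <= s < e <= len(g.hapA[gene.chrom])
            prev_end = e
        # exons placed outside repeat copies
        for r in g.repeats:
            if r.chrom != gene.chrom:
                continue
            for s, e in gene.exons:
                assert e <= r.start or s >= r.end


def test_infeasible_config_raises():
    with pytest.raises(ConfigError):
        SimConfig.from_dict({"snp_rate": 1.5})
    with pytest.raises(ConfigError):
        SimConfig.from_dict({"fragment_overlap": 500, "fragment_len": 400})
    cfg = SimConfig(haploid_length=20_000, n_genes=40, seed=1)
    with pytest.raises(ConfigError):
        simulate_diploid(cfg)


# ---------------------------------------------------------------------------
# reads


def test_error_free_reads_are_exact_substrings():
    cfg = SimConfig(haploid_length=50_000, coverage_per_haplotype=10,
                    seq_error_rate=0.0, n_genes=3, seed=6)
    g = simulate_diploid(cfg)
    rs = simulate_reads(g, cfg)
    from hetkit import dna
    haps = (g.hapA, g.hapB)
    for i in range(0, rs.n_pairs, 97):
        chrom = rs.chroms[rs.chrom_id[i]]
        src = haps[rs.hap[i]][chrom]
        s1, e1 = (int(a[i]) for a in rs.mate_intervals(1))
        assert dna.decode(rs.r1[i]) == src[s1:e1]
        s2, e2 = (int(a[i]) for a in rs.mate_intervals(2))
        assert dna.decode(rs.r2[i]) == src[s2:e2]


def test_read_depth_matches_configured_coverage(clean_bundle):
    rs = clean_bundle.reads
    cfg = clean_bundle.cfg
    total_bases = 2 * rs.n_pairs * cfg.read_len
    genome_bases = sum(len(s) for s in clean_bundle.genome.hapA.values()) \
        + sum(len(s) for s in clean_bundle.genome.hapB.values())
    depth = total_bases / genome_bases
    assert abs(depth - cfg.coverage_per_haplotype) \
        <= 0.05 * cfg.coverage_per_haplotype


def test_fastq_deterministic(tmp_path):
    cfg = SimConfig(haploid_length=20_000, coverage_per_haplotype=5,
                    n_genes=2, seed=7)
    g = simulate_diploid(cfg)
    outs = []
    for run in (1, 2):
        rs = simulate_reads(g, cfg)
        p1 = tmp_path / f"r1_{run}.fq"
        p2 = tmp_path / f"r2_{run}.fq"
        rs.write_fastq(p1, p2)
        outs.append((p1.read_bytes(), p2.read_bytes()))
    assert outs[0] == outs[1]


def test_read_len_error():
    cfg = SimConfig(haploid_length=2_000, read_len=5_000, n_genes=0, seed=1)
    with pytest.raises(ConfigError):
        g = simulate_diploid(cfg)
        simulate_reads(g, cfg)


# ---------------------------------------------------------------------------
# transcripts


def test_transcripts_match_haplotype_when_rate_zero():
    from hetkit import dna
    cfg = SimConfig(haploid_length=80_000, population_variant_rate=0.0,
                    n_genes=6, seed=8)
    g = simulate_diploid(cfg)
    ts = simulate_transcripts(g, cfg)
    assert ts.truth.empty
    genes = {x.gene_id: x for x in g.genes}
    for tx_id, seq in ts.seqs.items():
        gene = genes[ts.gene_of[tx_id]]
        hap = ts.origin[tx_id]
        cmap = g.coord_maps[gene.chrom]
        pieces = []
        for s, e in gene.exons:
            if hap == "A":
                pieces.append(g.hapA[gene.chrom][s:e])
            else:
                bs, be = cmap.interval_a_to_b(s, e)
                pieces.append(g.hapB[gene.chrom][bs:be])
        expect = "".join(pieces)
        if gene.strand == "-":
            expect = dna.revcomp(expect)
        assert seq == expect


def test_population_variant_rate_calibrated():
    cfg = SimConfig(haploid_length=400_000, population_variant_rate=0.008,
                    n_genes=40, seed=9)
    g = simulate_diploid(cfg)
    ts = simulate_transcripts(g, cfg)
    total = sum(len(s) for s in ts.seqs.values())
    n = len(ts.truth)
    bound = 3 * math.sqrt(total * 0.008 * 0.992)
    assert abs(n - total * 0.008) <= bound
    # planted alleles never coincide with either haplotype allele
    for _, row in ts.truth.head(200).iterrows():
        assert row.alt not in (row.ref_a, row.ref_b) or row.ref_a == "."


def test_transcript_truth_tsv_roundtrip(tmp_path, bundle):
    ts = bundle.transcripts
    path = tmp_path / "truth.tsv"
    ts.write_truth_tsv(path)
    back = TranscriptSet.read_truth_tsv(path)
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True),
        ts.truth.reset_index(drop=True),
        check_dtype=False)


# ---------------------------------------------------------------------------
# fragments


def test_fragment_truth(clean_bundle):
    fs = clean_bundle.fragments
    cfg = clean_bundle.cfg
    genome = clean_bundle.genome
    assert len(fs.fragments) == cfg.n_fragments
    frag = {f.name: f for f in fs.fragments}
    for ov in fs.overlaps:
        fa, fb = frag[ov.name_a], frag[ov.name_b]
        assert ov.a_hi - ov.a_lo >= cfg.fragment_overlap
        if fa.hap == fb.hap:
            assert ov.n_snps == 0 and ov.n_indels == 0
        else:
            expect = [v for v in genome.variants[fa.chrom]
                      if ov.a_lo <= v.pos < ov.a_hi]
            assert ov.n_snps == sum(1 for v in expect if v.kind == "snp")
            assert ov.n_indels == sum(1 for v in expect if v.is_indel)


def test_fragment_overlap_must_fit():
    cfg = SimConfig(haploid_length=30_000, fragment_len=20_000,
                    fragment_overlap=2_000, n_fragments=4, n_genes=2, seed=1)
    g = simulate_diploid(cfg)
    with pytest.raises(ConfigError):
        simulate_fragments(g, cfg)


# ---------------------------------------------------------------------------
# serialization


def test_vcf_parses_and_reconstructs(tmp_path, clean_bundle):
    """The emitted VCF is valid (pysam-parseable) and complete."""
    import pysam
    g = clean_bundle.genome
    path = tmp_path / "truth.vcf"
    synth_io.write_vcf(g, path)
    with pysam.VariantFile(str(path)) as vf:
        records = list(vf)
    assert len(records) == len(g.all_variants())
    for rec in records[:50]:
        ref_slice = g.hapA[rec.chrom][rec.start:rec.start + len(rec.ref)]
        assert ref_slice == rec.ref


def test_gff3_and_bed_outputs(tmp_path, clean_bundle):
    g = clean_bundle.genome
    synth_io.write_gff3(g.genes, tmp_path / "genes.gff3")
    lines = (tmp_path / "genes.gff3").read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    exon_lines = [l for l in lines if "\texon\t" in l]
    assert len(exon_lines) == sum(len(x.exons) for x in g.genes)
    first_exon = exon_lines[0].split("\t")
    assert int(first_exon[3]) >= 1  # 1-based output
    synth_io.write_repeats_bed(g, tmp_path / "repeats.bed")
    n = len((tmp_path / "repeats.bed").read_text().splitlines())
    assert n == len(g.repeats)


def test_fasta_roundtrip(tmp_path, clean_bundle):
    g = clean_bundle.genome
    synth_io.write_fasta(g.hapA, tmp_path / "hapA.fa")
    back = synth_io.read_fasta(tmp_path / "hapA.fa")
    assert back == g.hapA
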