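"""Transcript mapping, coverage groups, het/popvar calling, syn/nonsyn."""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from hetkit import SimConfig, dna
from hetkit.hetcall import (HetcallError, analyze_genes,
                            classify_coverage_groups,
                            classify_substitutions,
                            map_transcripts_and_filter, region_coverage)
from hetkit.synth.io import gene_truth_table


# ---------------------------------------------------------------------------
# transcript mapping filters


def test_allelic_transcript_maps_to_two_loci(bundle):
    hits = map_transcripts_and_filter(bundle.transcripts.seqs,
                                      bundle.contig_seqs)
    split_genes = {g for g, s in bundle.status.items() if s == "split"}
    two_locus = {bundle.transcripts.gene_of[t]
                 for t, h in hits.items() if len(h.loci) == 2}
    # every split gene has both haplotype loci discovered
    assert split_genes <= two_locus
    for h in hits.values():
        assert all(l.aln_len >= 30 for l in h.loci)
        if len(h.loci) == 2:
            assert h.loci[0].mismatches <= h.loci[1].mismatches


def test_repetitive_transcript_dropped():
    rng = np.random.default_rng(0)
    unit = dna.random_seq(rng, 600)
    contigs = {f"copy{i}": dna.random_seq(rng, 200) + unit
               + dna.random_seq(rng, 200) for i in range(6)}
    hits = map_transcripts_and_filter({"tx": unit}, contigs)
    assert hits["tx"].dropped
    assert hits["tx"].n_loci_observed == 6
    assert hits["tx"].loci == []


def test_short_and_unmappable_transcripts():
    rng = np.random.default_rng(1)
    contigs = {"c": dna.random_seq(rng, 5_000)}
    hits = map_transcripts_and_filter(
        {"short": contigs["c"][100:125],          # < 30 bp alignment
         "alien": dna.random_seq(rng, 500)}, contigs)
    assert hits["short"].unplaced
    assert hits["alien"].unplaced


def test_minus_strand_transcripts_map(bundle):
    hits = map_transcripts_and_filter(bundle.transcripts.seqs,
                                      bundle.contig_seqs)
    minus = [g for g in bundle.genome.genes if g.strand == "-"]
    assert minus
    for gene in minus:
        hit = hits[f"{gene.gene_id}.t1"]
        assert hit.loci, f"{gene.gene_id} unplaced"
        assert hit.loci[0].strand == "-"


# ---------------------------------------------------------------------------
# coverage groups


def test_boundary_from_75_150_modes():
    rng = np.random.default_rng(2)
    depths = np.concatenate([rng.normal(75, 6, 120),
                             rng.normal(150, 9, 120)])
    table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(240)],
                          "depth": depths})
    groups = classify_coverage_groups(table)
    assert groups.boundary == pytest.approx(math.sqrt(75 * 150), rel=0.08)
    assert not groups.unimodal


def test_boundary_tie_goes_to_merged():
    table = pd.DataFrame({"gene_id": ["g"], "depth": [100.0]})
    groups = classify_coverage_groups(table, boundary=100.0)
    assert groups.assignment["g"] == "merged"
    low = classify_coverage_groups(
        pd.DataFrame({"gene_id": ["g"], "depth": [99.0]}), boundary=100.0)
    assert low.assignment["g"] == "split"


def test_unimodal_fallback():
    rng = np.random.default_rng(3)
    table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(60)],
                          "depth": rng.normal(80, 5, 60)})
    groups = classify_coverage_groups(table)
    assert groups.unimodal
    assert set(groups.assignment.values()) == {"split"}


def test_group_assignment_recovers_truth(bundle):
    table, groups, hits = analyze_genes(
        bundle.transcripts.seqs, bundle.transcripts.gene_of,
        bundle.contig_seqs, bundle.pileups)
    merged = table[table.group == "merged"]
    split = table[table.group == "split"]
    assert len(table) == len(bundle.genome.genes)
    truth = pd.Series(bundle.status)
    match = (table.set_index("gene_id")["group"] == truth).mean()
    assert match >= 0.9
    # coverage regime: split loci near 1x per-hap, merged near 2x
    cov = bundle.cfg.coverage_per_haplotype
    assert split["depth"].mean() == pytest.approx(cov, rel=0.15)
    assert merged["depth"].mean() == pytest.approx(2 * cov, rel=0.15)


# ---------------------------------------------------------------------------
# heterozygosity + population variance


def test_het_zero_without_variants():
    cfg = SimConfig(haploid_length=60_000, snp_rate=0, small_indel_rate=0,
                    large_indel_rate=0, population_variant_rate=0,
                    coverage_per_haplotype=30, n_genes=6,
                    fragment_len=10_000, fragment_overlap=2_000,
                    seq_error_rate=0.0, seed=31)
    from tests.conftest import _make_bundle
    b = _make_bundle(cfg)
    table, _, _ = analyze_genes(b.transcripts.seqs, b.transcripts.gene_of,
                                b.contig_seqs, b.pileups)
    assert (table["het_percent"] == 0).all()
    assert (table["popvar_percent"].fillna(0) == 0).all()


def test_het_recovers_planted_rates(bundle):
    table, _, _ = analyze_genes(
        bundle.transcripts.seqs, bundle.transcripts.gene_of,
        bundle.contig_seqs, bundle.pileups)
    truth = gene_truth_table(bundle.genome).set_index("gene_id")
    t = table.set_index("gene_id")
    est = t["het_percent"].mean()
    true = truth["true_het_span_pct"].mean()
    assert est == pytest.approx(true, rel=0.2)
    # split group is the more heterozygous one by construction
    gm = t.groupby("group")["het_percent"].mean()
    assert gm["split"] > gm["merged"]


def test_popvar_recovers_planted_sites(bundle):
    table, _, _ = analyze_genes(
        bundle.transcripts.seqs, bundle.transcripts.gene_of,
        bundle.contig_seqs, bundle.pileups)
    planted = len(bundle.transcripts.truth)
    recovered = table["popvar_sites"].sum()
    assert planted > 50
    assert recovered == pytest.approx(planted, rel=0.15)


# ---------------------------------------------------------------------------
# synonymous / non-synonymous


def oracle_classify(a: str, b: str):
    """Brute force via Biopython whole-sequence translation."""
    pa, pb = Seq(a).translate(), Seq(b).translate()
    syn = nonsyn = 0
    for i in range(0, len(a), 3):
        if a[i:i + 3] != b[i:i + 3]:
            if pa[i // 3] == pb[i // 3]:
                syn += 1
            else:
                nonsyn += 1
    return syn, nonsyn


def test_silent_and_missense_codons():
    assert classify_substitutions("GCT", "GCC") == (1, 0, 0)
    assert classify_substitutions("GCT", "GAT") == (0, 1, 0)


def test_indel_events_counted_separately():
    # one 3-bp gap: single event; the interrupted codon is skipped and the
    # flanking silent change (TTT->TTC, Phe) still counts as synonymous
    a = "ATGGCTAAATTT"
    b = "ATG---AAATTC"
    assert classify_substitutions(a, b) == (1, 0, 1)


def test_frame_error():
    with pytest.raises(HetcallError):
        classify_substitutions("ATGC", "ATGC")
    with pytest.raises(HetcallError):
        classify_substitutions("ATG", "AT")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 100_000))
def test_classifier_matches_translation_oracle(seed):
    rng = np.random.default_rng(seed)
    n_codons = 100
    a = dna.random_seq(rng, 3 * n_codons)
    codes = dna.encode(a).copy()
    subs = rng.choice(len(codes), size=20, replace=False)
    codes[subs] = (codes[subs] + rng.integers(1, 4, size=20)) % 4
    b = dna.decode(codes)
    assert classify_substitutions(a, b)[:2] == oracle_classify(a, b)
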