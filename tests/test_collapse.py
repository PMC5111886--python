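"""Allelic-pair discovery, cluster resolution, collapse, reintegration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetkit import SimConfig, dna
from hetkit.collapse import (CandidatePair, CollapseError, collapse,
                             pairwise_similarity, reintegrate,
                             select_allelic_pairs)
from hetkit.stats import assembly_stats, nx
from hetkit.synth import (fragment_haplotypes, simulate_diploid,
                          true_allelic_pairs)


def test_identical_contigs_full_identity():
    rng = np.random.default_rng(0)
    seq = dna.random_seq(rng, 10_000)
    cands = pairwise_similarity({"a": seq, "b": seq})
    assert len(cands) == 1
    c = cands[0]
    assert c.identity == 100.0
    assert c.overlap_frac == pytest.approx(1.0, abs=1e-9)


def test_five_percent_divergence_measured():
    rng = np.random.default_rng(1)
    seq = dna.random_seq(rng, 10_000)
    mutant = dna.mutate(seq, rng, 0.05)
    cands = pairwise_similarity({"a": seq, "b": mutant})
    assert len(cands) == 1
    assert cands[0].identity == pytest.approx(95.0, abs=0.5)


def test_unrelated_contigs_no_candidate():
    rng = np.random.default_rng(2)
    contigs = {f"c{i}": dna.random_seq(rng, 8_000) for i in range(3)}
    assert pairwise_similarity(contigs) == []


def test_duplicate_or_single_input_rejected():
    with pytest.raises(CollapseError):
        pairwise_similarity({"only": "ACGT" * 100})


def _pair(a, b, ident=99.0, frac=1.0):
    return CandidatePair(a, b, ident, 1000, frac)


def test_threshold_is_strict_and_clusters_resolve():
    lengths = {"A": 12_000, "B": 10_000, "C": 9_000, "D": 5_000}
    cands = [_pair("A", "B"), _pair("B", "C"), _pair("C", "D", ident=94.0)]
    mapping = select_allelic_pairs(cands, lengths)
    # chain A~B~C: both secondary to the longest; D excluded at 94%
    assert mapping == {"B": "A", "C": "A"}
    # inclusive override admits an exactly-95 candidate
    cands95 = [_pair("A", "B", ident=95.0)]
    assert select_allelic_pairs(cands95, lengths) == {}
    assert select_allelic_pairs(cands95, lengths, inclusive=True) \
        == {"B": "A"}


def test_equal_length_tie_lexicographic():
    lengths = {"x": 1000, "w": 1000}
    assert select_allelic_pairs([_pair("x", "w")], lengths) == {"x": "w"}


def test_threshold_monotonicity():
    rng = np.random.default_rng(3)
    lengths = {f"c{i}": int(rng.integers(1_000, 20_000)) for i in range(12)}
    names = sorted(lengths)
    cands = [
        CandidatePair(a, b, float(rng.uniform(80, 100)), 1000,
                      float(rng.uniform(0.9, 1.0)))
        for a, b in itertools.combinations(names, 2)
        if rng.random() < 0.3
    ]
    prev = None
    for min_id in (99, 97, 95, 90, 85, 80):
        n_secondary = len(select_allelic_pairs(cands, lengths, min_id, 0.95))
        if prev is not None:
            assert n_secondary >= prev
        prev = n_secondary


def _exhaustive_primary_oracle(cands, lengths):
    """Connected components; best single primary per component by length."""
    names = set()
    for c in cands:
        names |= {c.a, c.b}
    adj = {n: set() for n in names}
    for c in cands:
        adj[c.a].add(c.b)
        adj[c.b].add(c.a)
    seen, components = set(), []
    for n in names:
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        components.append(comp)
    mapping = {}
    for comp in components:
        best = None
        for primary in comp:  # enumerate every possible primary choice
            total = lengths[primary]
            if best is None or total > best[0] \
                    or (total == best[0] and primary < best[1]):
                best = (total, primary)
        for member in comp:
            if member != best[1]:
                mapping[member] = best[1]
    return mapping


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_cluster_resolution_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 13))
    lengths = {f"c{i:02d}": int(rng.integers(1_000, 30_000))
               for i in range(n)}
    cands = [
        CandidatePair(a, b, 99.0, 1000, 1.0)
        for a, b in itertools.combinations(sorted(lengths), 2)
        if rng.random() < 0.25
    ]
    assert select_allelic_pairs(cands, lengths) \
        == _exhaustive_primary_oracle(cands, lengths)


def test_collapse_partition_and_conservation():
    rng = np.random.default_rng(4)
    contigs = {f"c{i}": dna.random_seq(rng, int(rng.integers(500, 2_000)))
               for i in range(6)}
    assert collapse(contigs, {}).secondary == {}
    lengths = {n: len(s) for n, s in contigs.items()}
    sec, pri = sorted(lengths, key=lambda n: lengths[n])[:2][0], \
        max(lengths, key=lambda n: lengths[n])
    result = collapse(contigs, {sec: pri})
    assert set(result.primary) | set(result.secondary) == set(contigs)
    assert not set(result.primary) & set(result.secondary)
    total = sum(map(len, result.primary.values())) \
        + sum(map(len, result.secondary.values()))
    assert total == sum(map(len, contigs.values()))
    with pytest.raises(CollapseError):
        collapse(contigs, {"nope": pri})


def test_recovery_on_fragmented_haplotypes():
    """Allelic pairs recovered from a two-haplotype fragmentation."""
    cfg = SimConfig(haploid_length=150_000, n_genes=5, seed=21,
                    het_lognormal_sigma=0.0)
    g = simulate_diploid(cfg)
    contigs = fragment_haplotypes(g, cfg.seed, min_len=5_000,
                                  max_len=15_000)
    seqs = {c.name: c.seq for c in contigs}
    cands = pairwise_similarity(seqs)
    mapping = select_allelic_pairs(cands, {n: len(s)
                                           for n, s in seqs.items()})
    truth = true_allelic_pairs(contigs, 0.95)
    found = {frozenset((s, p)) for s, p in mapping.items()}
    assert truth, "fixture must contain true allelic pairs"
    tp = len(found & truth)
    assert tp / max(len(found), 1) >= 0.9
    assert tp / len(truth) >= 0.9


# ---------------------------------------------------------------------------
# stats and reintegration


def brute_force_nx(lengths, x):
    total = sum(lengths)
    run = 0
    for ln in sorted(lengths, reverse=True):
        run += ln
        if run >= total * x / 100:
            return ln
    return 0


def test_n50_matches_brute_force():
    assert nx([100, 200, 300, 400], 50) == 300
    rng = np.random.default_rng(5)
    for _ in range(25):
        lens = rng.integers(1, 10_000, size=int(rng.integers(1, 40))).tolist()
        for x in (10, 50, 90):
            assert nx(lens, x) == brute_force_nx(lens, x)


def test_reintegrate_classes_and_schema():
    contigs = {"p1": "A" * 400, "p2": "C" * 300, "s1": "G" * 200}
    result = collapse(contigs, {"s1": "p1"})
    stats = reintegrate({"scaf1": ["p1"]}, {"scaf1": "A" * 400}, result)
    assert set(stats) == {"scaffolds", "unplaced_contigs",
                          "heterozygous_contigs"}
    for cls in stats.values():
        assert set(cls) == {"n_sequences", "N90", "N50", "N10",
                            "sum_length", "max_length"}
    assert stats["scaffolds"]["n_sequences"] == 1
    assert stats["unplaced_contigs"]["n_sequences"] == 1  # p2
    assert stats["heterozygous_contigs"]["n_sequences"] == 1
    # identity scaffolding: every primary its own scaffold
    ident = reintegrate({n: [n] for n in result.primary},
                        dict(result.primary), result)
    assert ident["scaffolds"]["n_sequences"] == len(result.primary)
    assert ident["unplaced_contigs"]["n_sequences"] == 0
    with pytest.raises(CollapseError):
        reintegrate({"scaf1": ["unknown"]}, {}, result)
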