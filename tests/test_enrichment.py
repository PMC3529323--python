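"""Overlap expectation, hypergeometric tails, category scanning."""

import itertools
import math

import numpy as np
import pytest

import retromap as rm
from retromap.enrichment import (
    category_scan,
    enrichment_test,
    expected_overlap,
    hypergeom_pvalue,
    permutation_null,
)


def _universe(n):
    return [f"p{i}" for i in range(n)]


def _sets_with_overlap(n_a, n_b, overlap, n_universe):
    ids = _universe(n_universe)
    a = set(ids[:n_a])
    b = set(ids[n_a - overlap: n_a - overlap + n_b])
    assert len(a & b) == overlap
    return a, b, set(ids)


def test_expected_overlap_values_and_edges():
    assert expected_overlap(720, 606, 22810) == pytest.approx(19.1284, abs=1e-4)
    assert round(expected_overlap(720, 606, 22810)) == 19
    assert expected_overlap(0, 500, 1000) == 0.0
    assert expected_overlap(100, 100, 100) == 100.0
    assert expected_overlap(3, 7, 50) == expected_overlap(7, 3, 50)  # symmetric
    with pytest.raises(ValueError):
        expected_overlap(1, 1, 0)


def test_hypergeom_enumeration_example():
    # N=10, K=5, n=5, all 5 drawn from the category: C(5,5)C(5,0)/C(10,5)
    assert hypergeom_pvalue(5, 5, 5, 10, "over") == pytest.approx(1 / 252, rel=1e-12)
    assert hypergeom_pvalue(0, 5, 5, 10, "over") == pytest.approx(1.0)


def _enum_tail(obs, K, n, N, tail):
    """Exhaustive hypergeometric tail by direct enumeration of draw counts."""
    total = math.comb(N, n)
    ks = range(obs, min(K, n) + 1) if tail == "over" else range(0, obs + 1)
    return sum(math.comb(K, k) * math.comb(N - K, n - k) for k in ks) / total


def test_hypergeom_matches_enumeration_for_all_small_instances():
    """Full oracle sweep: every (N <= 12, K, n, observed) agrees with the
    combinatorial enumeration."""
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                lo, hi = max(0, K + n - N), min(K, n)
                for obs in range(lo, hi + 1):
                    for tail in ("over", "under"):
                        got = hypergeom_pvalue(obs, K, n, N, tail)
                        assert got == pytest.approx(
                            _enum_tail(obs, K, n, N, tail), rel=1e-9), (N, K, n, obs)


def test_tail_identity():
    # over + under = 1 + P(X = observed)
    K, n, N = 5, 6, 12
    for obs in range(0, 6):
        over = hypergeom_pvalue(obs, K, n, N, "over")
        under = hypergeom_pvalue(obs, K, n, N, "under")
        pmf = math.comb(K, obs) * math.comb(N - K, n - obs) / math.comb(N, n)
        assert over + under == pytest.approx(1 + pmf, rel=1e-9)


def test_impossible_observed_rejected():
    with pytest.raises(ValueError, match="impossible"):
        hypergeom_pvalue(6, 5, 10, 20)


def test_enrichment_test_published_rows():
    """The chloroplast-category row: 606 foreground, 2198 category, 22810
    universe, 177 observed -> expected ~58 and ratio ~3.03 on the
    unrounded expected; the mitochondrial row gives ratio ~0.99."""
    fg, cat, uni = _sets_with_overlap(606, 2198, 177, 22810)
    res = enrichment_test(fg, cat, uni)
    assert round(res.expected) == 58
    assert res.ratio == pytest.approx(3.03, abs=0.005)
    assert res.p_over < 0.001

    fg, cat, uni = _sets_with_overlap(606, 1178, 31, 22810)
    res = enrichment_test(fg, cat, uni)
    assert res.ratio == pytest.approx(0.99, abs=0.005)
    assert res.p_over > 0.05


def test_enrichment_category_equals_universe():
    uni = set(_universe(100))
    fg = set(_universe(30))
    res = enrichment_test(fg, uni, uni)
    assert res.observed == 30 and res.ratio == pytest.approx(1.0)


def test_enrichment_ratio_symmetric_in_foreground_and_category():
    rng = np.random.default_rng(3)
    uni = set(_universe(300))
    fg = set(rng.choice(sorted(uni), 60, replace=False))
    cat = set(rng.choice(sorted(uni), 90, replace=False))
    a, b = enrichment_test(fg, cat, uni), enrichment_test(cat, fg, uni)
    assert a.observed == b.observed
    assert a.ratio == pytest.approx(b.ratio, rel=1e-12)


def test_foreground_outside_universe_rejected():
    with pytest.raises(ValueError, match="universe"):
        enrichment_test({"x"}, set(), set(_universe(10)))


def test_permutation_null_agrees_with_hypergeometric():
    """Monte-Carlo null within 3 binomial standard errors of the analytic
    tail at 10,000 permutations, on random small instances."""
    rng = np.random.default_rng(6)
    for seed in (1, 2, 3):
        n_uni = int(rng.integers(60, 150))
        uni = set(_universe(n_uni))
        cat = set(rng.choice(sorted(uni), int(rng.integers(10, 30)), replace=False))
        fg_size = int(rng.integers(10, 30))
        obs = int(rng.integers(1, min(fg_size, len(cat)) // 2 + 2))
        exact = hypergeom_pvalue(obs, fg_size, len(cat), n_uni, "over")
        emp = permutation_null(fg_size, cat, uni, obs, n_perm=10000, seed=seed)
        se = math.sqrt(exact * (1 - exact) / 10000)
        assert abs(emp["p_over"] - exact) <= 3 * se + 2 / 10001


def test_permutation_null_category_equals_universe_and_determinism():
    uni = set(_universe(40))
    out = permutation_null(8, uni, uni, 8, n_perm=200, seed=9)
    assert out["null_mean"] == 8.0 and out["null_sd"] == 0.0
    out2 = permutation_null(8, uni, uni, 8, n_perm=200, seed=9)
    assert out == out2


def test_category_scan_retention_rules():
    uni = set(_universe(400))
    fg = set(_universe(40))
    cats = {
        "self": fg,                              # maximal over-representation
        "avoided": set(_universe(400)[40:140]),  # fully avoided by fg
        "everything": uni,
    }
    out = category_scan(fg, cats, uni)
    assert out.loc["self", "ratio"] == pytest.approx(400 / 40)
    assert out.loc["self", "retained"]
    avoided = out.loc["avoided"]
    assert avoided["observed"] == 0 and avoided["ratio"] < 1
    assert avoided["p_under"] < 0.05
    assert out.loc["everything", "ratio"] == pytest.approx(1.0)
    assert not out.loc["everything", "retained"]


def test_category_scan_null_calibration():
    """A uniform random foreground passes p < 0.05 in about 5% of random
    categories before the ratio filter."""
    rng = np.random.default_rng(12)
    uni = _universe(1000)
    fg = set(rng.choice(uni, 200, replace=False))
    cats = {
        f"c{i}": set(rng.choice(uni, 50, replace=False)) for i in range(200)
    }
    out = category_scan(fg, cats, set(uni))
    frac = (np.minimum(out["p_over"], out["p_under"]) < 0.05).mean()
    assert frac <= 0.12  # ~5% expected; generous binomial headroom


def test_compartment_structure_recovered_from_planted_truth(
        benchmark_compendium, benchmark_counts):
    """On the benchmark compendium the responsive set of each class is
    over-represented for its own organelle's proteins and not for the
    other's — the published cross-compartment asymmetry."""
    comp = benchmark_compendium
    _, _, _, counts = benchmark_counts
    uni = set(counts.index)
    cats = comp.truth.compartment_sets()
    for cls, own, other in (("mito", "mitochondrion", "chloroplast"),
                            ("chloro", "chloroplast", "mitochondrion")):
        fg = rm.responsive_set(counts, cls, 4)
        own_res = enrichment_test(fg, cats[own] & uni, uni)
        other_res = enrichment_test(fg, cats[other] & uni, uni)
        assert own_res.ratio > 1 and own_res.p_over < 0.05
        assert other_res.p_over > 0.05
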