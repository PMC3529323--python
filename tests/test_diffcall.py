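"""Regularized t statistic, beta-uniform mixture, and the calling rule."""

import numpy as np
import pytest
from scipy import stats

import retromap as rm
from retromap.diffcall import (
    BetaUniformMixture,
    call_significant,
    fit_ppde,
    reg_t_test,
    regularized_variance,
)


# --- regularized variance --------------------------------------------------


def test_prior_df_zero_returns_sample_variance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(50, 4))
    out = regularized_variance(x, window=11, prior_df=0)
    assert np.allclose(out, x.var(axis=1, ddof=1))


def test_identical_variances_are_a_fixed_point():
    # every gene has replicate variance exactly 2 (values m-1, m+1)
    means = np.linspace(0, 10, 40)
    x = np.stack([means - 1, means + 1], axis=1)
    for prior_df in (0, 1, 10, 100):
        out = regularized_variance(x, window=5, prior_df=prior_df)
        assert np.allclose(out, 2.0)


def test_hand_arithmetic_14_over_11():
    """n=2 replicates, sample variance 4, background 1, prior_df 10
    -> (10*1 + 1*4) / 11."""
    n_genes = 101
    # neighbors chosen so the window-101 mean variance is exactly 1:
    # (100 * 0.97 + 4) / 101 = 1
    means = np.linspace(0, 10, n_genes)
    half = np.full(n_genes, np.sqrt(0.97 / 2))
    half[50] = np.sqrt(4 / 2)
    x = np.stack([means - half, means + half], axis=1)
    out = regularized_variance(x, window=101, prior_df=10)
    assert out[50] == pytest.approx(14 / 11, rel=1e-12)


def test_window_validation():
    x = np.zeros((10, 3))
    with pytest.raises(ValueError, match="odd"):
        regularized_variance(x, window=4)
    with pytest.raises(ValueError, match="exceeds"):
        regularized_variance(x, window=11)


# --- regularized t ---------------------------------------------------------


def test_equal_means_give_t0_p1():
    c = np.array([[1.0, 2.0, 3.0]])
    t = np.array([[3.0, 2.0, 1.0]])
    v = np.array([1.0])
    reg_t, p = reg_t_test(c, t, v, v, prior_df=0)
    assert reg_t[0] == 0.0 and p[0] == pytest.approx(1.0)


def test_ordinary_pooled_t_closed_form():
    """prior_df=0, {1,2,3} vs {4,5,6}: t = 3 / sqrt(1/3 + 1/3)."""
    c = np.array([[1.0, 2.0, 3.0]])
    t = np.array([[4.0, 5.0, 6.0]])
    reg_t, p = reg_t_test(c, t, c.var(axis=1, ddof=1), t.var(axis=1, ddof=1), prior_df=0)
    assert reg_t[0] == pytest.approx(3 / np.sqrt(2 / 3), rel=1e-12)
    oracle = stats.ttest_ind([4, 5, 6], [1, 2, 3])
    assert reg_t[0] == pytest.approx(oracle.statistic, rel=1e-12)
    assert p[0] == pytest.approx(oracle.pvalue, rel=1e-12)


def test_prior_df_zero_matches_pooled_t_oracle_randomized():
    """Equal group sizes: the regularized t with prior weight 0 is the
    ordinary two-sample pooled t, to 1e-10 on random inputs."""
    rng = np.random.default_rng(42)
    c = rng.normal(5, 1, size=(200, 3))
    t = rng.normal(5.5, 1.2, size=(200, 3))
    reg_t, p = reg_t_test(c, t, c.var(axis=1, ddof=1), t.var(axis=1, ddof=1), prior_df=0)
    oracle = stats.ttest_ind(t, c, axis=1)
    assert np.allclose(reg_t, oracle.statistic, atol=1e-10)
    assert np.allclose(p, oracle.pvalue, atol=1e-10)


def test_swapping_groups_flips_sign_only():
    rng = np.random.default_rng(1)
    c = rng.normal(size=(30, 3))
    t = rng.normal(0.5, 1, size=(30, 3))
    vc, vt = c.var(axis=1, ddof=1), t.var(axis=1, ddof=1)
    t1, p1 = reg_t_test(c, t, vc, vt, prior_df=5)
    t2, p2 = reg_t_test(t, c, vt, vc, prior_df=5)
    assert np.allclose(t1, -t2) and np.allclose(p1, p2)


def test_zero_variance_unequal_means_flagged_tiny_p():
    c = np.array([[1.0, 1.0]])
    t = np.array([[2.0, 2.0]])
    reg_t, p = reg_t_test(c, t, np.zeros(1), np.zeros(1), prior_df=0)
    assert p[0] > 0 and p[0] < 1e-300


# --- beta-uniform mixture --------------------------------------------------


def test_uniform_pvalues_fit_pi0_near_one():
    rng = np.random.default_rng(7)
    p = rng.uniform(1e-12, 1, size=5000)
    model = BetaUniformMixture().fit(p)
    assert model.pi0_ >= 0.95
    assert np.max(model.ppde(p)) < 0.5


def test_mixture_recovers_pi0_half():
    rng = np.random.default_rng(8)
    p = np.concatenate([rng.uniform(1e-12, 1, 2500), rng.beta(0.1, 1, 2500)])
    p = np.clip(p, 1e-12, 1.0)
    model = BetaUniformMixture().fit(p)
    assert model.pi0_ == pytest.approx(0.5, abs=0.05)


def test_ppde_boundary_identity_and_monotonicity():
    rng = np.random.default_rng(9)
    p = np.clip(np.concatenate([rng.uniform(0, 1, 500), rng.beta(0.2, 1, 500)]), 1e-12, 1)
    model = BetaUniformMixture().fit(p)
    assert model.ppde(np.array([1.0]))[0] == pytest.approx(1 - model.pi0_, abs=1e-9)
    grid = np.linspace(1e-6, 1, 300)
    ppde = model.ppde(grid)
    assert np.all(np.diff(ppde) <= 1e-12)


def test_fit_requires_enough_valid_pvalues():
    with pytest.raises(ValueError, match=">= 50"):
        fit_ppde(np.full(10, 0.5))
    with pytest.raises(ValueError, match="0, 1"):
        fit_ppde(np.linspace(0, 1, 100))  # p=0 is invalid


# --- calling rule ----------------------------------------------------------


@pytest.mark.parametrize(
    "log2_fc,ppde,expected",
    [
        (1.0, 0.99, False),     # FC exactly 2: strict "more than twofold"
        (np.log2(0.4), 0.99, True),   # 2.5-fold down
        (1.5, 0.95, False),     # PPDE exactly at threshold: strict >
        (1.5, 0.951, True),
        (-1.001, 0.96, True),
        (0.5, 0.999, False),
    ],
)
def test_call_significant_strict_thresholds(log2_fc, ppde, expected):
    assert call_significant(log2_fc, ppde) is expected


def test_direction_recorded_with_sign(small_compendium):
    comp = small_compendium
    de = rm.call_experiment(comp.expression, comp.presence, comp.experiments[0])
    sig = de[de["significant"]]
    assert len(sig) > 0
    assert (np.sign(sig["log2_fc"]) == sig["direction"]).all()
    assert (de.loc[~de["significant"], "direction"] == 0).all()


def test_null_compendium_type_one_error_below_one_percent():
    """No planted effects, noise sd 0.5, 3 replicates: the twofold + PPDE
    thresholds must call <= 1% of genes per experiment."""
    cfg = rm.SyntheticConfig(
        n_genes=2000, n_mito_experiments=2, n_chloro_experiments=2,
        frac_shared=0, frac_mito_specific=0, frac_chloro_specific=0,
        noise_sd_log2=0.5, absent_prob=0.0, seed=13)
    comp = rm.generate_compendium(cfg)
    for exp in comp.experiments:
        de = rm.call_experiment(comp.expression, comp.presence, exp)
        assert de["significant"].mean() <= 0.01


def test_planted_effects_recovered_with_high_power(small_compendium):
    """Effect 2 log2-units over noise 0.25: >= 90% of planted responsive
    gene-experiment pairs are called significant."""
    comp = small_compendium
    de = rm.call_compendium(comp.expression, comp.presence)
    planted = comp.truth.effects != 0
    hits = total = 0
    for exp in comp.experiments:
        genes = planted.index[planted[exp]]
        calls = de.xs(exp, level="experiment").loc[genes, "significant"]
        hits += int(calls.sum())
        total += len(genes)
    assert total > 0 and hits / total >= 0.90
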