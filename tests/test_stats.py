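"""Moderated tests, BH adjustment, binder calling, condition contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import chipdecode as cd


def brute_force_bh(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} m p_(j)/j, clipped."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    q_sorted = [min(min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)]
    out = np.empty(m)
    out[order] = q_sorted
    return out


def null_panel(rng, n_factors=400, n_reps=6, sd=1.0):
    return pd.DataFrame(rng.normal(0, sd, size=(n_factors, n_reps)),
                        index=[f"g{i}" for i in range(n_factors)])


# -- prior estimation --------------------------------------------------------

def test_prior_equal_variances_gives_infinite_d0():
    from scipy.special import psi
    prior = cd.estimate_prior(np.full(5000, 2.5), df=5)
    assert math.isinf(prior.d0)
    # zero spread implies no excess variance; the scale keeps the unbiasing
    # correction for log-chi-square sampling, exp(log s2 - psi(d/2) + log(d/2))
    expected = 2.5 * np.exp(np.log(2.5) - psi(2.5))
    assert abs(prior.s0_sq - expected) < 1e-9


def test_prior_homoskedastic_sampling_recovers_common_variance():
    """With true common variance and real chi-square noise, d0 is huge and
    s0^2 lands on the common value."""
    rng = np.random.default_rng(8)
    d = 50
    s2 = 2.5 * rng.chisquare(d, 5000) / d
    prior = cd.estimate_prior(s2, df=d)
    assert prior.d0 > d
    assert abs(prior.s0_sq - 2.5) / 2.5 < 0.05


def test_prior_recovery_from_scaled_inv_chi2():
    rng = np.random.default_rng(77)
    d0, s0_sq, d, G = 4.0, 1.0, 5, 5000
    sigma2 = d0 * s0_sq / rng.chisquare(d0, G)
    s2 = sigma2 * rng.chisquare(d, G) / d
    prior = cd.estimate_prior(s2, df=d)
    assert abs(prior.d0 - d0) / d0 < 0.2
    assert abs(prior.s0_sq - s0_sq) / s0_sq < 0.1


def test_prior_requires_enough_factors():
    with pytest.raises(ValueError):
        cd.estimate_prior([1.0, 2.0], df=3)


def test_prior_all_zero_variances_fail():
    with pytest.raises(ValueError, match="zero"):
        cd.estimate_prior(np.zeros(100), df=5)


# -- moderated one-sample test -----------------------------------------------

def test_no_shrinkage_limit_equals_ordinary_t():
    rng = np.random.default_rng(3)
    panel = null_panel(rng, 50, 5)
    prior = cd.ModeratedPrior(d0=0.0, s0_sq=1.0)
    tab = cd.moderated_one_sample_test(panel, prior)
    t_ref, p_ref = sps.ttest_1samp(panel.to_numpy(), 0.0, axis=1)
    np.testing.assert_allclose(tab["t"], t_ref, rtol=1e-10)
    np.testing.assert_allclose(tab["p"], p_ref, rtol=1e-10)


def test_symmetric_scores_give_null_result():
    panel = pd.DataFrame([[1.0, -1, 1, -1, 1, -1]], index=["sym"])
    tab = cd.moderated_one_sample_test(panel,
                                       cd.ModeratedPrior(4.0, 1.0))
    assert tab.loc["sym", "logFC"] == 0
    assert tab.loc["sym", "t"] == 0
    assert tab.loc["sym", "p"] == 1


def test_shrinkage_interpolates_between_sample_and_prior():
    rng = np.random.default_rng(9)
    panel = null_panel(rng, 200, 4)
    prior = cd.ModeratedPrior(d0=4.0, s0_sq=1.0)
    tab = cd.moderated_one_sample_test(panel, prior)
    s2 = tab["s2"].to_numpy()
    d = tab["df"].to_numpy()
    s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
    lo = np.minimum(s2, prior.s0_sq)
    hi = np.maximum(s2, prior.s0_sq)
    differ = np.abs(s2 - prior.s0_sq) > 1e-12
    assert ((s2_post > lo) & (s2_post < hi))[differ].all()


def test_t_monotone_in_mean_and_n():
    prior = cd.ModeratedPrior(4.0, 1.0)

    def t_of(mean, n):
        panel = pd.DataFrame([np.r_[np.full(n - 1, mean), mean + 1e-9]])
        return abs(cd.moderated_one_sample_test(panel, prior)["t"].iloc[0])

    assert t_of(2.0, 4) > t_of(1.0, 4)
    assert t_of(1.0, 8) > t_of(1.0, 4)


def test_null_p_values_approximately_uniform():
    rng = np.random.default_rng(123)
    tab = cd.moderated_one_sample_test(null_panel(rng, 4000, 6))
    ks = sps.kstest(tab["p"], "uniform")
    assert ks.pvalue > 0.01


def test_drops_factors_with_single_observation():
    panel = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, 3.0]},
                         index=["lonely", "ok"])
    tab = cd.moderated_one_sample_test(panel, cd.ModeratedPrior(4.0, 1.0))
    assert list(tab.index) == ["ok"]


# -- BH adjustment -----------------------------------------------------------

def test_bh_single_p_is_itself():
    np.testing.assert_allclose(cd.bh_adjust([0.37]), [0.37])


def test_bh_hand_example():
    np.testing.assert_allclose(cd.bh_adjust([0.01, 0.02, 0.03, 1.0]),
                               [0.04, 0.04, 0.04, 1.0])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        cd.bh_adjust([0.5, 1.5])


def test_bh_matches_brute_force(rng):
    for _ in range(50):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(cd.bh_adjust(p), brute_force_bh(p),
                                   atol=1e-12)


def test_bh_permutation_equivariant(rng):
    p = rng.random(25)
    perm = rng.permutation(25)
    np.testing.assert_allclose(cd.bh_adjust(p)[perm], cd.bh_adjust(p[perm]))


# -- binder calling ----------------------------------------------------------

def test_binder_requires_positive_fold_change():
    tab = pd.DataFrame({"logFC": [-2.0, 0.0, 1.0, 1.0],
                        "fdr": [1e-9, 1e-9, 0.005, 0.02]})
    out = cd.call_binders(tab, fdr_cut=0.01)
    assert list(out["binder"]) == [False, False, True, False]


def test_binder_simulation_power_and_fdr():
    rng = np.random.default_rng(55)
    n, k = 2000, 200
    panel = null_panel(rng, n, 6, sd=0.5)
    true = set(panel.index[:k])
    panel.iloc[:k] += 1.0
    out = cd.call_binders(cd.moderated_one_sample_test(panel), 0.01)
    called = set(out.index[out["binder"]])
    assert len(called & true) / k >= 0.8
    assert len(called - true) / max(1, len(called)) <= 0.05


# -- differential binding ----------------------------------------------------

def test_identical_panels_yield_no_changes():
    rng = np.random.default_rng(31)
    panel = null_panel(rng, 300, 3) + 2.0  # everything binds
    out = cd.differential_binding(panel, panel.copy())
    assert len(out) > 0
    assert not out["significant"].any()
    assert (out["logFC"] == 0).all()


def test_nonbinders_absent_from_contrast():
    rng = np.random.default_rng(37)
    panel_a = null_panel(rng, 100, 3)
    panel_b = null_panel(rng, 100, 3)
    binders = panel_a.index[:30]
    panel_a.loc[binders] += 3.0
    panel_b.loc[binders] += 3.0
    out = cd.differential_binding(panel_a, panel_b)
    assert set(out.index) <= set(binders)


def test_empty_binder_union_warns():
    rng = np.random.default_rng(41)
    with pytest.warns(UserWarning, match="no binders"):
        out = cd.differential_binding(null_panel(rng, 50, 3),
                                      null_panel(rng, 50, 3))
    assert out.empty


def test_differential_simulation_power_and_fdr():
    """50 of 500 binders shifted by -1.5 log2 units, 3 vs 3 replicates."""
    rng = np.random.default_rng(43)
    base = rng.normal(1.5, 0.5, size=500)
    panel_a = pd.DataFrame(base[:, None] + rng.normal(0, 0.4, (500, 3)),
                           index=[f"g{i}" for i in range(500)])
    panel_b = pd.DataFrame(base[:, None] + rng.normal(0, 0.4, (500, 3)),
                           index=panel_a.index)
    shifted = set(panel_b.index[:50])
    panel_b.iloc[:50] -= 1.5
    out = cd.differential_binding(panel_a, panel_b)
    called = set(out.index[out["significant"]])
    assert len(called & shifted) / 50 >= 0.6
    assert len(called - shifted) / max(1, len(called)) <= 0.10


def test_type_one_error_control_over_null_runs():
    """Mean binder-call fraction at FDR<0.01 stays below 0.01 on nulls."""
    rates = []
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        out = cd.call_binders(
            cd.moderated_one_sample_test(null_panel(rng, 1000, 6)), 0.01)
        rates.append(out["binder"].mean())
    assert np.mean(rates) < 0.01
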