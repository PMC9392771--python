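"""NB-GLM engine: likelihoods, size factors, fits, dispersion, inference."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from diffstab import (
    adjust_bh,
    estimate_dispersion,
    estimate_size_factors,
    fit_genes,
    nb_log_likelihood,
    wald_test,
)
from diffstab.data import StackedCounts
from diffstab.glm import median_of_ratios


# ---------------------------------------------------------------------------
# size factors

def test_size_factors_identity_and_scaling(rng):
    base = rng.poisson(50, size=(40, 1)).repeat(8, axis=1)
    np.testing.assert_allclose(median_of_ratios(base), np.ones(8))

    doubled = base.copy().astype(float)
    doubled[:, 2] *= 2
    s = median_of_ratios(doubled)
    np.testing.assert_allclose(s[2] / s[0], 2.0, rtol=1e-12)


def test_size_factors_match_brute_force_oracle(rng):
    m = rng.poisson(30, size=(5, 6)) + 1
    # independent brute-force median-of-ratios on the 5 x 6 table
    ref = np.array([np.exp(np.mean(np.log(m[g]))) for g in range(5)])
    expected = np.array([np.median(m[:, j] / ref) for j in range(6)])
    np.testing.assert_allclose(median_of_ratios(m), expected, rtol=1e-12)


def test_size_factor_blocks_have_geometric_mean_one(rng):
    mat = rng.poisson(40, size=(60, 12)) + 1
    st_ = StackedCounts(matrix=mat, gene_ids=[f"g{i}" for i in range(60)],
                        sample_ids=[f"s{j}" for j in range(6)])
    s = estimate_size_factors(st_)
    assert np.exp(np.mean(np.log(s[:6]))) == pytest.approx(1.0)
    assert np.exp(np.mean(np.log(s[6:]))) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# likelihood

def test_poisson_limit_matches_closed_form():
    val = nb_log_likelihood(np.array([3.0]), np.array([3.0]), 0.0)
    assert val == pytest.approx(np.log(3.0**3 * np.exp(-3) / 6.0))


def test_nb_pmf_matches_direct_gamma_form():
    y, mu, alpha = 3.0, 3.0, 0.5
    k = 1 / alpha
    direct = (gammaln(y + k) - gammaln(k) - gammaln(y + 1)
              + k * np.log(k / (k + mu)) + y * np.log(mu / (k + mu)))
    assert nb_log_likelihood(np.array([y]), np.array([mu]), alpha) == pytest.approx(direct)
    # and against scipy's NB pmf in its (n, p) parameterization
    sp = stats.nbinom.logpmf(int(y), k, k / (k + mu))
    assert nb_log_likelihood(np.array([y]), np.array([mu]), alpha) == pytest.approx(sp)


def test_single_observation_argmax_at_mu_equals_y():
    y = np.array([7.0])
    mus = np.linspace(1, 20, 400)
    lls = [nb_log_likelihood(y, np.array([m]), 0.4) for m in mus]
    assert abs(mus[int(np.argmax(lls))] - 7.0) < 0.1


# ---------------------------------------------------------------------------
# fitting

def test_intercept_only_closed_form(rng):
    y = rng.poisson(20, size=12).astype(float)
    fit = fit_genes(y[None, :], np.ones((12, 1)), alpha=0.0)
    assert fit.coefficients[0, 0] == pytest.approx(np.log(y.mean()), abs=1e-8)


def test_saturated_design_reproduces_counts():
    y = np.array([[3.0, 9.0, 27.0]])
    fit = fit_genes(y, np.eye(3), alpha=0.3)
    np.testing.assert_allclose(fit.fitted_means[0], y[0], rtol=1e-6)


def test_loglik_consistent_and_beats_grid(rng):
    """Fitted coefficients reach the maximum of a brute-force grid search."""
    design = np.column_stack([np.ones(10), np.repeat([0.0, 1.0], 5)])
    y = rng.negative_binomial(5, 5 / (5 + 20.0), size=10).astype(float)
    fit = fit_genes(y[None, :], design, alpha=0.2)
    ll_fit = fit.log_likelihood[0]
    assert ll_fit == pytest.approx(
        nb_log_likelihood(y, fit.fitted_means[0], 0.2), abs=1e-9
    )
    b0 = np.linspace(fit.coefficients[0, 0] - 1, fit.coefficients[0, 0] + 1, 160)
    b1 = np.linspace(fit.coefficients[0, 1] - 1, fit.coefficients[0, 1] + 1, 160)
    grid_ll = np.array([
        [nb_log_likelihood(y, np.exp(design @ np.array([a, b])), 0.2) for b in b1]
        for a in b0
    ])
    assert ll_fit >= grid_ll.max() - 1e-4


def test_fit_beats_random_coefficient_vectors(rng):
    design = np.column_stack([np.ones(12), np.tile([0.0, 1.0], 6)])
    for _ in range(20):
        y = rng.poisson(rng.uniform(5, 60), size=12).astype(float)
        fit = fit_genes(y[None, :], design, alpha=0.1)
        cand = fit.coefficients[0] + rng.normal(0, 0.8, size=(1000, 2))
        lls = nb_log_likelihood(y, np.exp(cand @ design.T), 0.1)
        assert fit.log_likelihood[0] >= lls.max() - 1e-6


def test_matches_statsmodels_nb_glm(rng):
    """Independent cross-check against statsmodels' NB GLM (fixed alpha)."""
    design = np.column_stack([np.ones(16), rng.normal(size=16)])
    offset = rng.normal(0, 0.2, size=16)
    y = rng.poisson(30, size=16).astype(float)
    alpha = 0.15
    ours = fit_genes(y[None, :], design, offset=offset, alpha=alpha)
    ref = sm.GLM(y, design, family=sm.families.NegativeBinomial(alpha=alpha),
                 offset=offset).fit()
    np.testing.assert_allclose(ours.coefficients[0], ref.params, rtol=1e-4)


def test_poisson_alpha_zero_matches_poisson_glm(rng):
    design = np.column_stack([np.ones(14), np.repeat([0.0, 1.0], 7)])
    y = rng.poisson(25, size=14).astype(float)
    ours = fit_genes(y[None, :], design, alpha=0.0)
    ref = sm.GLM(y, design, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(ours.coefficients[0], ref.params, atol=1e-6)
    np.testing.assert_allclose(ours.standard_errors[0], ref.bse, rtol=1e-5)


def test_offset_equivariance(rng):
    """Scaling one pseudo-library and its size factor leaves coefficients put."""
    design = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
    y = rng.poisson(40, size=8).astype(float)
    s = np.ones(8)
    f1 = fit_genes(y[None, :], design, offset=np.log(s), alpha=0.1)
    y2, s2 = y.copy(), s.copy()
    y2[3] *= 4
    s2[3] *= 4
    f2 = fit_genes(y2[None, :], design, offset=np.log(s2), alpha=0.1)
    np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=2e-2)


def test_rank_deficient_design_fatal():
    bad = np.ones((6, 2))
    with pytest.raises(ValueError, match="rank"):
        fit_genes(np.ones((1, 6)), bad)


# ---------------------------------------------------------------------------
# dispersion

def test_dispersion_poisson_gene_hits_lower_clamp(rng):
    design = np.ones((200, 1))
    y = rng.poisson(100, size=(3, 200)).astype(float)
    a = estimate_dispersion(y, design)
    assert np.all(a < 5e-3)


def test_dispersion_recovery_alpha_half(rng):
    design = np.ones((200, 1))
    k = 1 / 0.5
    mu = 50.0
    y = rng.negative_binomial(k, k / (k + mu), size=(5, 200)).astype(float)
    a = estimate_dispersion(y, design)
    assert np.all((a > 0.3) & (a < 0.8))


def test_dispersion_saturated_design_errors():
    with pytest.raises(ValueError):
        estimate_dispersion(np.ones((1, 3)), np.eye(3))


# ---------------------------------------------------------------------------
# Wald and BH

def test_wald_null_point_and_quantile():
    stat, p = wald_test(np.array([0.0]), np.array([1.0]))
    assert stat[0] == 0 and p[0] == 1
    _, p2 = wald_test(np.array([1.959964]), np.array([1.0]))
    assert p2[0] == pytest.approx(0.05, abs=1e-6)
    s_pos, p_pos = wald_test(np.array([0.7]), np.array([0.2]))
    s_neg, p_neg = wald_test(np.array([-0.7]), np.array([0.2]))
    assert p_pos[0] == pytest.approx(p_neg[0])


def test_bh_hand_computation_and_properties():
    np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(adjust_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    p = np.array([0.001, np.nan, 0.04, 0.9])
    q = adjust_bh(p)
    assert np.isnan(q[1]) and np.isfinite(q[[0, 2, 3]]).all()
    # missing values excluded from m: computed over the 3 finite ones
    np.testing.assert_allclose(q[0], 0.003)
    srt = np.sort(q[np.isfinite(q)])
    assert np.all(np.diff(srt) >= -1e-15)


def test_bh_null_fdr_control(rng):
    """BH at 0.05 on uniform p-values keeps average FDP at or below 0.05."""
    fdp = []
    for _ in range(20):
        p = rng.uniform(size=5000)
        q = adjust_bh(p)
        fdp.append(np.mean(q <= 0.05))
    assert np.mean(fdp) <= 0.05
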