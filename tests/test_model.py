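"""Likelihood correctness, design matrices, fitting and prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from multiscale_occupancy import (
    CovariateTable,
    ModelSpec,
    SimDesign,
    brute_force_site_likelihood,
    build_design_matrices,
    combined_daily_detection,
    fit_model,
    predict_probabilities,
    simulate_covariates,
    simulate_method_level,
    site_likelihood,
    total_negative_loglik,
)
from multiscale_occupancy.detection import MISSING, PooledHistory

WORKED_Y = np.array([[0, 1, 1, 0, 0], [0, 0, 0, 0, 0]])
WORKED_L = 0.0040283203125  # psi=theta=p=0.5: 0.5 * 0.5*0.5^5 * (0.5 + 0.5*0.5^5)


def _pooled_from_y(y):
    """One-site PooledHistory from a (T, S) slice."""
    T, S = y.shape
    return PooledHistory(["s1"], [f"m{j+1}" for j in range(S)], [T],
                         np.asarray(y, dtype=np.int8).T[None, :, :])


# ---------------------------------------------------------------------------
# site likelihood
# ---------------------------------------------------------------------------

def test_site_likelihood_two_day_worked_example():
    assert site_likelihood(0.5, 0.5, 0.5, WORKED_Y) == pytest.approx(
        WORKED_L, abs=1e-15)
    assert brute_force_site_likelihood(
        0.5, [0.5, 0.5], np.full((2, 5), 0.5), WORKED_Y
    ) == pytest.approx(WORKED_L, abs=1e-15)


def test_detected_day_factors_as_known_availability():
    # a day with >= 1 detection contributes theta * prod of Bernoulli terms
    psi, th = 0.8, 0.3
    p = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    y = np.array([[0, 1, 1, 0, 0]])
    expect = psi * th * (1 - p[0]) * p[1] * p[2] * (1 - p[3]) * (1 - p[4])
    assert site_likelihood(psi, th, p[None, :], y) == pytest.approx(expect, abs=1e-15)


def test_unoccupied_site_explains_all_zeros():
    y = np.zeros((3, 5), dtype=int)
    assert site_likelihood(0.0, 0.4, 0.3, y) == 1.0
    y[1, 2] = 1
    assert site_likelihood(0.0, 0.4, 0.3, y) == 0.0


def test_degenerate_latent_states_leave_detection_terms():
    y = np.array([[1, 0], [0, 1]])
    p = np.array([[0.7, 0.2], [0.4, 0.9]])
    expect = 0.7 * (1 - 0.2) * (1 - 0.4) * 0.9
    assert site_likelihood(1.0, 1.0, p, y) == pytest.approx(expect, abs=1e-15)
    assert brute_force_site_likelihood(1.0, [1.0, 1.0], p, y) == pytest.approx(
        expect, abs=1e-15)


def test_single_season_reduction_closed_form():
    # theta = 1, one method: L = psi * prod p^y (1-p)^(1-y) + (1-psi) 1{all 0}
    psi, p = 0.62, 0.35
    y = np.array([[1], [0], [0], [1], [0]])
    expect = psi * p**2 * (1 - p) ** 3
    assert site_likelihood(psi, 1.0, p, y) == pytest.approx(expect, abs=1e-15)
    y0 = np.zeros((5, 1), dtype=int)
    expect0 = psi * (1 - p) ** 5 + (1 - psi)
    assert site_likelihood(psi, 1.0, p, y0) == pytest.approx(expect0, abs=1e-15)


def test_probability_bounds_are_enforced():
    with pytest.raises(ValueError, match="psi"):
        site_likelihood(1.2, 0.5, 0.5, WORKED_Y)
    with pytest.raises(ValueError, match="p"):
        site_likelihood(0.5, 0.5, -0.1, WORKED_Y)
    with pytest.raises(ValueError, match="too large"):
        brute_force_site_likelihood(0.5, 0.5, 0.5, np.zeros((13, 2), dtype=int))


@given(st.data())
@settings(max_examples=150)
def test_fast_likelihood_matches_exhaustive_enumeration(data):
    """The closed-form site likelihood equals the sum over all latent
    occupancy/availability configurations, missing entries included."""
    T = data.draw(st.integers(1, 6))
    S = data.draw(st.integers(1, 5))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    y = rng.choice([-1, 0, 1], size=(T, S))
    psi = rng.random()
    theta = rng.random(T)
    p = rng.random((T, S))
    assert site_likelihood(psi, theta, p, y) == pytest.approx(
        brute_force_site_likelihood(psi, theta, p, y), abs=1e-10)


def test_likelihood_invariant_to_occasion_order():
    rng = np.random.default_rng(1)
    y = rng.choice([-1, 0, 1], size=(6, 5))
    perm = rng.permutation(6)
    assert site_likelihood(0.7, 0.3, 0.4, y) == pytest.approx(
        site_likelihood(0.7, 0.3, 0.4, y[perm]), abs=1e-14)


# ---------------------------------------------------------------------------
# total negative log-likelihood
# ---------------------------------------------------------------------------

def test_total_nll_matches_site_likelihood(cov_factory):
    pooled = _pooled_from_y(WORKED_Y)
    spec = ModelSpec.from_formula("psi(.) theta(.) p(.)")
    nll = total_negative_loglik(np.zeros(3), spec, cov_factory(["s1"]), pooled)
    assert nll == pytest.approx(-np.log(WORKED_L), abs=1e-12)


def test_total_nll_additive_over_sites(cov_factory):
    one = _pooled_from_y(WORKED_Y)
    two = PooledHistory(["s1", "s2"], one.method_ids, [2, 2],
                        np.repeat(one.obs, 2, axis=0))
    spec = ModelSpec.from_formula("psi(.) theta(.) p(.)")
    n1 = total_negative_loglik(np.zeros(3), spec, cov_factory(["s1"]), one)
    n2 = total_negative_loglik(np.zeros(3), spec, cov_factory(["s1", "s2"]), two)
    assert n2 == pytest.approx(2 * n1, rel=1e-12)


def test_total_nll_rejects_zero_sites(cov_factory):
    pooled = _pooled_from_y(WORKED_Y)
    empty = PooledHistory([], pooled.method_ids, np.zeros(0, dtype=int),
                          np.zeros((0, 5, 2), dtype=np.int8))
    spec = ModelSpec.from_formula("psi(.) theta(.) p(.)")
    with pytest.raises(ValueError, match="no sites"):
        total_negative_loglik(np.zeros(3), spec, cov_factory([]), empty)


def test_total_nll_invariant_to_site_order(cov_factory, mmap):
    design = SimDesign(n_sites=12, occasions=8, seed=5)
    pooled, _ = simulate_method_level(design, mmap)
    spec = ModelSpec.from_formula("psi(.) theta(.) p(Method)")
    beta = np.linspace(-1, 1, 7)
    base = total_negative_loglik(beta, spec, cov_factory(pooled.site_ids), pooled)
    perm = np.random.default_rng(0).permutation(12)
    shuffled = PooledHistory([pooled.site_ids[i] for i in perm],
                             pooled.method_ids, pooled.occasions[perm],
                             pooled.obs[perm])
    assert total_negative_loglik(
        beta, spec, cov_factory(shuffled.site_ids), shuffled
    ) == pytest.approx(base, rel=1e-12)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def test_design_matrix_column_counts(sim_covariates, mmap):
    design = SimDesign(n_sites=48, occasions=5, seed=2)
    pooled, _ = simulate_method_level(design, mmap)
    dm = build_design_matrices(ModelSpec.from_formula("psi(.) theta(.) p(Method)"),
                               sim_covariates, pooled)
    assert dm.X_psi.shape[1] == 1 and dm.X_p.shape[2] == 5  # intercept + 4
    dm2 = build_design_matrices(
        ModelSpec.from_formula("psi(.) theta(.) p(Method+Access+DistAve)"),
        sim_covariates, pooled)
    assert dm2.X_p.shape[2] == 7  # 5 + Access indicator + DistAve
    assert dm2.K == 1 + 1 + 7


def test_design_matrix_rejects_bad_terms(sim_covariates, mmap):
    pooled, _ = simulate_method_level(SimDesign(n_sites=48, occasions=5, seed=2),
                                      mmap)
    with pytest.raises(KeyError):
        build_design_matrices(ModelSpec.from_formula("psi(Bogus) theta(.) p(.)"),
                              sim_covariates, pooled)
    with pytest.raises(ValueError, match="site, method"):
        build_design_matrices(ModelSpec.from_formula("psi(DistAve) theta(.) p(.)"),
                              sim_covariates, pooled)
    with pytest.raises(ValueError, match="detection-only"):
        ModelSpec.from_formula("psi(Method) theta(.) p(.)")


def test_shared_psi_theta_has_fewer_parameters(sim_covariates, mmap):
    pooled, _ = simulate_method_level(SimDesign(n_sites=48, occasions=5, seed=2),
                                      mmap)
    separate = build_design_matrices(
        ModelSpec.from_formula("psi(Area) theta(Area) p(Method)"),
        sim_covariates, pooled)
    shared = build_design_matrices(
        ModelSpec.from_formula("psi=theta(Area) p(Method)"),
        sim_covariates, pooled)
    assert shared.K < separate.K
    assert shared.K == separate.K - 2  # two Area slopes collapse onto one pair


def test_formula_roundtrip():
    for f in ["psi(.) theta(.) p(Method)",
              "psi(Loss1k) theta(.) p(Method+Access)",
              "psi=theta(Area) p(Method+Access+DistAve)"]:
        assert ModelSpec.from_formula(f).formula == f


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------

def test_fit_all_zero_data_flags_boundary(cov_factory):
    obs = np.zeros((10, 2, 6), dtype=np.int8)
    pooled = PooledHistory([f"s{i}" for i in range(10)], ["m1", "m2"],
                           [6] * 10, obs)
    fit = fit_model(ModelSpec.from_formula("psi(.) theta(.) p(.)"),
                    cov_factory(pooled.site_ids), pooled, n_starts=3, seed=0)
    assert fit.converged
    assert any("boundary" in w for w in fit.warnings)
    assert predict_probabilities(fit).psi < 0.05


def test_fit_saturated_data_flags_boundary(cov_factory):
    obs = np.ones((10, 2, 6), dtype=np.int8)
    pooled = PooledHistory([f"s{i}" for i in range(10)], ["m1", "m2"],
                           [6] * 10, obs)
    fit = fit_model(ModelSpec.from_formula("psi(.) theta(.) p(.)"),
                    cov_factory(pooled.site_ids), pooled, n_starts=3, seed=0)
    assert any("boundary" in w for w in fit.warnings)
    pred = predict_probabilities(fit)
    assert pred.psi > 0.95 and pred.theta > 0.95


def test_refit_from_solution_does_not_improve(cov_factory, mmap):
    design = SimDesign(n_sites=150, occasions=12, psi_true=0.7, theta_true=0.4,
                       p_true=(0.3, 0.5, 0.6, 0.45, 0.55), seed=8)
    pooled, _ = simulate_method_level(design, mmap)
    cov = cov_factory(pooled.site_ids)
    spec = ModelSpec.from_formula("psi(.) theta(.) p(Method)")
    fit = fit_model(spec, cov, pooled, n_starts=2, seed=1)
    nll_at_fit = total_negative_loglik(fit.betas, spec, cov, pooled)
    assert nll_at_fit == pytest.approx(-fit.loglik, abs=1e-8)
    refit = fit_model(spec, cov, pooled, n_starts=1, seed=99)
    assert -refit.loglik <= nll_at_fit + 1e-6


def test_parameter_recovery_bias_shrinks_with_sites(cov_factory, mmap):
    truth_vec = np.array([0.7, 0.4, 0.3, 0.5, 0.6, 0.45, 0.55])

    def mean_abs_error(n):
        design = SimDesign(n_sites=n, occasions=20, psi_true=0.7, theta_true=0.4,
                           p_true=(0.3, 0.5, 0.6, 0.45, 0.55), seed=21)
        pooled, _ = simulate_method_level(design, mmap)
        fit = fit_model(ModelSpec.from_formula("psi(.) theta(.) p(Method)"),
                        cov_factory(pooled.site_ids), pooled, n_starts=2, seed=1)
        pred = predict_probabilities(fit)
        est = np.array([pred.psi, pred.theta, *pred.p["estimate"]])
        return np.abs(est - truth_vec).mean()

    err_small, err_large = mean_abs_error(100), mean_abs_error(1000)
    assert err_large < err_small
    assert err_large < 0.02


def test_predict_probabilities_identities(cov_factory, mmap):
    design = SimDesign(n_sites=300, occasions=15, psi_true=0.6, theta_true=0.5,
                       p_true=(0.3, 0.5, 0.6, 0.45, 0.55), seed=3)
    pooled, _ = simulate_method_level(design, mmap)
    fit = fit_model(ModelSpec.from_formula("psi(.) theta(.) p(Method)"),
                    cov_factory(pooled.site_ids), pooled, n_starts=2, seed=0)
    pred = predict_probabilities(fit)
    # inverse-logit of the intercept and the delta-method identity
    b_psi = fit.betas[fit.design.idx_psi][0]
    assert pred.psi == pytest.approx(expit(b_psi), abs=1e-12)
    se_link = np.sqrt(fit.vcov[0, 0])
    assert pred.psi_se == pytest.approx(
        expit(b_psi) * (1 - expit(b_psi)) * se_link, rel=1e-9)
    # the method factor produces five distinct detection estimates
    assert len(set(pred.p["estimate"].round(6))) == 5


def test_predict_rejects_unseen_category(sim_covariates, mmap):
    pooled, _ = simulate_method_level(SimDesign(n_sites=48, occasions=10, seed=2),
                                      mmap)
    fit = fit_model(ModelSpec.from_formula("psi(Area) theta(.) p(.)"),
                    sim_covariates, pooled, n_starts=2, seed=0)
    with pytest.raises(ValueError, match="training categories"):
        predict_probabilities(fit, {"Area": "XX"})


def test_covariate_effect_recovery(mmap):
    """A logit-scale occupancy covariate effect is recovered by the fit."""
    cov = simulate_covariates(600, mmap, seed=14)
    site = cov.site.copy()
    site["x"] = np.random.default_rng(2).normal(size=600)
    cov = CovariateTable(site, cov.site_method)
    design = SimDesign(n_sites=600, occasions=12, psi_true=0.6, theta_true=0.45,
                       p_true=(0.4,) * 5, psi_coefs={"x": 0.9}, seed=6)
    pooled, _ = simulate_method_level(design, mmap, cov)
    fit = fit_model(ModelSpec.from_formula("psi(x) theta(.) p(.)"),
                    cov, pooled, n_starts=2, seed=0)
    slope = fit.betas[fit.design.idx_psi][1]
    assert slope == pytest.approx(0.9, abs=0.25)


def test_theta_fixed_collapses_to_single_season(cov_factory):
    # with theta pinned at 1 the availability layer vanishes: K drops by 1
    obs = np.array([[[1, 0, 0, 1, 0]], [[0, 0, 0, 0, 0]]], dtype=np.int8)
    pooled = PooledHistory(["s1", "s2"], ["m1"], [5, 5], obs)
    cov = cov_factory(pooled.site_ids)
    spec = ModelSpec.from_formula("psi(.) theta(.) p(.)")
    full = fit_model(spec, cov, pooled, n_starts=2, seed=0)
    reduced = fit_model(spec, cov, pooled, n_starts=2, seed=0, theta_fixed=1.0)
    assert reduced.K == full.K - 1
    assert predict_probabilities(reduced).theta == 1.0


# ---------------------------------------------------------------------------
# derived daily detection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("theta,p,expected", [
    (0.07, 0.13, 0.009),
    (0.24, 0.79, 0.190),
    (0.33, 0.77, 0.254),
    (0.5, 0.0, 0.0),
])
def test_combined_daily_detection(theta, p, expected):
    assert combined_daily_detection(theta, p) == pytest.approx(expected, abs=1e-12)


def test_combined_daily_detection_rejects_bad_probability():
    with pytest.raises(ValueError):
        combined_daily_detection(1.3, 0.5)
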