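"""Latent growth model: ML fit, fit indices, factor scores."""

import numpy as np
import pytest
from scipy import optimize

from adtraj import fit_indices, fit_independence_baseline, fit_lgm, factor_scores
from adtraj.growth import (
    DEFAULT_LOADINGS,
    GrowthModelFit,
    _moments,
    _objective,
    _start_values,
    fml_discrepancy,
)

WEEKS = np.array([0.0, 2.0, 8.0])


def _simulate_lgm(rng, n, mu=(5.0, 0.3), psi=((1.0, 0.0), (0.0, 0.04)), theta=0.25):
    eta = rng.multivariate_normal(mu, psi, size=n)
    return eta @ DEFAULT_LOADINGS.T + rng.normal(0, np.sqrt(theta), (n, 3)), eta


def test_noise_free_growth_recovers_sample_moments(rng):
    """With y = a + b*t exactly, the fit returns the sample moments of (a, b)."""
    eta = rng.multivariate_normal([4.0, 0.2], [[0.8, 0.1], [0.1, 0.05]], size=400)
    Y = eta @ DEFAULT_LOADINGS.T
    fit = fit_lgm(Y)
    assert fit.mu == pytest.approx(eta.mean(axis=0), abs=1e-5)
    assert fit.psi == pytest.approx(np.cov(eta, rowvar=False, ddof=1), abs=1e-4)
    assert fit.theta.max() < 1e-4


def test_parameter_recovery_single_seed(rng):
    Y, _ = _simulate_lgm(rng, 4000)
    fit = fit_lgm(Y)
    assert fit.mu == pytest.approx([5.0, 0.3], abs=0.05)
    assert fit.psi[0, 0] == pytest.approx(1.0, abs=0.12)
    assert fit.psi[1, 1] == pytest.approx(0.04, abs=0.01)
    # theta at week 8 has the largest sampling variance (leverage of t=8)
    assert fit.theta == pytest.approx([0.25] * 3, abs=0.2)
    assert fit.converged


def test_optimum_agrees_with_independent_optimizer(rng):
    """Adaptive Nelder-Mead from a perturbed start reaches the same F_ML."""
    Y, _ = _simulate_lgm(rng, 400)
    fit = fit_lgm(Y)
    ybar, S = _moments(Y)
    x0 = _start_values(Y, DEFAULT_LOADINGS) * 1.15 + 0.05
    res = optimize.minimize(
        _objective,
        x0,
        args=(DEFAULT_LOADINGS, ybar, S),
        method="Nelder-Mead",
        options={"maxiter": 40000, "maxfev": 40000, "xatol": 1e-12, "fatol": 1e-14, "adaptive": True},
    )
    assert abs(fit.fml - res.fun) < 1e-5


def test_fml_nonnegative_with_equality_at_saturation(rng):
    Y, _ = _simulate_lgm(rng, 200)
    ybar, S = _moments(Y)
    assert fml_discrepancy(ybar, S, ybar, S) == pytest.approx(0.0, abs=1e-12)
    for _ in range(20):
        A = rng.normal(size=(3, 3))
        Sigma = A @ A.T + 0.1 * np.eye(3)
        mu = rng.normal(size=3)
        assert fml_discrepancy(mu, Sigma, ybar, S) >= -1e-12


def test_chi_square_has_one_degree_of_freedom(rng):
    Y, _ = _simulate_lgm(rng, 300)
    fit = fit_lgm(Y)
    assert fit.df == 1
    assert fit.chi_square >= 0.0


def test_independence_baseline_diagonal_data(rng):
    """Exactly uncorrelated columns give a zero baseline chi-square."""
    Z = rng.normal(size=(200, 3))
    # orthogonalize columns -> sample covariance exactly diagonal
    Q, _ = np.linalg.qr(Z - Z.mean(axis=0))
    Y = Q * np.array([2.0, 1.0, 0.5])
    T_b, df_b = fit_independence_baseline(Y)
    assert df_b == 3
    assert T_b == pytest.approx(0.0, abs=1e-9)
    # invariant to per-column recentering
    T_b2, _ = fit_independence_baseline(Y + np.array([5.0, -3.0, 1.0]))
    assert T_b2 == pytest.approx(T_b, abs=1e-9)


def test_independence_baseline_grows_linearly_in_n(rng):
    cov = 0.5 * np.ones((3, 3)) + 0.5 * np.eye(3)
    Y = rng.multivariate_normal(np.zeros(3), cov, size=4000)
    T1, _ = fit_independence_baseline(Y[:2000])
    T2, _ = fit_independence_baseline(Y)
    assert T2 / T1 == pytest.approx(2.0, rel=0.25)


def _manual_fit(S, n, psi=None, theta=None, mu=None):
    psi = np.array([[0.5, 0.01], [0.01, 0.02]]) if psi is None else psi
    theta = np.array([0.2, 0.2, 0.2]) if theta is None else theta
    mu = np.array([5.0, 0.1]) if mu is None else mu
    Sigma = DEFAULT_LOADINGS @ psi @ DEFAULT_LOADINGS.T + np.diag(theta)
    ybar = DEFAULT_LOADINGS @ mu
    f = fml_discrepancy(ybar, Sigma, ybar, S)
    return GrowthModelFit(
        mu=mu, psi=psi, theta=theta, loadings=DEFAULT_LOADINGS, fml=f,
        chi_square=max((n - 1) * f, 0.0), df=1, loglik=0.0, n_subjects=n,
        converged=True, sample_mean=ybar, sample_cov=S,
    )


def test_fit_indices_saturated_model():
    psi = np.array([[0.5, 0.01], [0.01, 0.02]])
    theta = np.array([0.2, 0.2, 0.2])
    S = DEFAULT_LOADINGS @ psi @ DEFAULT_LOADINGS.T + np.diag(theta)
    fit = _manual_fit(S, 100, psi=psi, theta=theta)
    idx = fit_indices(fit)
    assert idx.chi_square == pytest.approx(0.0, abs=1e-9)
    assert idx.cfi == 1.0 and idx.rmsea == 0.0
    assert idx.srmr == pytest.approx(0.0, abs=1e-9)
    assert idx.gfi == pytest.approx(1.0, abs=1e-9)


def test_fit_indices_gfi_srmr_hand_oracle(rng):
    Y, _ = _simulate_lgm(rng, 250)
    fit = fit_lgm(Y)
    idx = fit_indices(fit)
    S, Sigma = fit.sample_cov, fit.implied_cov
    # two-loop hand evaluation of tr[(M - I)^2] / tr[M^2] with M = Sigma^-1 S
    M = np.linalg.inv(Sigma) @ S
    D = M - np.eye(3)
    num = sum(D[i, j] * D[j, i] for i in range(3) for j in range(3))
    den = sum(M[i, j] * M[j, i] for i in range(3) for j in range(3))
    assert idx.gfi == pytest.approx(1 - num / den, rel=1e-10)
    resid = []
    for i in range(3):
        for j in range(i, 3):
            resid.append((S[i, j] - Sigma[i, j]) / np.sqrt(S[i, i] * S[j, j]))
    assert idx.srmr == pytest.approx(np.sqrt(np.mean(np.square(resid))), rel=1e-10)


def test_rmsea_zero_at_chi_square_equal_df(rng):
    Y, _ = _simulate_lgm(rng, 150)
    fit = fit_lgm(Y)
    fit.chi_square = 1.0  # T = df boundary
    idx = fit_indices(fit)
    assert idx.rmsea == 0.0 and idx.cfi == 1.0


def test_factor_scores_zero_noise_equal_ols_slopes(rng):
    eta = rng.multivariate_normal([4.0, 0.25], [[0.6, 0.0], [0.0, 0.03]], size=300)
    Y = eta @ DEFAULT_LOADINGS.T + rng.normal(0, 1e-6, (300, 3))
    fit = fit_lgm(Y)
    fs = factor_scores(fit, Y)
    pinv = np.linalg.pinv(DEFAULT_LOADINGS)
    ols = Y @ pinv.T
    assert np.abs(fs.scores[:, 1] - ols[:, 1]).max() < 1e-4


def test_factor_scores_population_mean_subject_is_fixed_point(rng):
    Y, _ = _simulate_lgm(rng, 500)
    fit = fit_lgm(Y)
    with_mean = np.vstack([Y, fit.implied_mean])
    fs = factor_scores(fit, with_mean)
    assert fs.scores[-1] == pytest.approx(fit.mu, abs=1e-10)


def test_factor_scores_standardization_and_shrinkage(rng):
    Y, eta = _simulate_lgm(rng, 2000)
    fit = fit_lgm(Y)
    fs = factor_scores(fit, Y)
    assert fs.standardized_slope.mean() == pytest.approx(0.0, abs=1e-10)
    assert fs.standardized_slope.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
    assert fs.scores[:, 1].var(ddof=1) <= fit.psi[1, 1] + 1e-9  # shrinkage
    assert np.corrcoef(eta[:, 1], fs.scores[:, 1])[0, 1] > 0.6


def test_fit_invariances(rng):
    Y, _ = _simulate_lgm(rng, 300)
    fit = fit_lgm(Y)
    perm = rng.permutation(len(Y))
    fit_p = fit_lgm(Y[perm])
    assert fit_p.mu == pytest.approx(fit.mu, abs=1e-6)
    assert fit_p.psi == pytest.approx(fit.psi, abs=1e-6)
    shifted = fit_lgm(Y + 3.0)
    assert shifted.mu[0] == pytest.approx(fit.mu[0] + 3.0, abs=1e-6)
    assert shifted.mu[1] == pytest.approx(fit.mu[1], abs=1e-6)
    assert shifted.psi == pytest.approx(fit.psi, abs=1e-5)


def test_loading_rescale_leaves_standardized_slope_invariant(rng):
    Y, _ = _simulate_lgm(rng, 400)
    u = 4.0
    L2 = DEFAULT_LOADINGS.copy()
    L2[:, 1] /= u
    fit1 = fit_lgm(Y)
    fit2 = fit_lgm(Y, loadings=L2)
    assert fit2.mu[1] == pytest.approx(u * fit1.mu[1], rel=1e-4)
    fs1 = factor_scores(fit1, Y)
    fs2 = factor_scores(fit2, Y)
    assert fs2.standardized_slope == pytest.approx(fs1.standardized_slope, abs=1e-5)


def test_fit_lgm_input_validation(rng):
    with pytest.raises(ValueError):
        fit_lgm(rng.normal(size=(10, 3)))  # too few subjects
    with pytest.raises(ValueError):
        fit_lgm(rng.normal(size=(50, 4)))
    Y = rng.normal(size=(50, 3))
    Y[0, 0] = np.nan
    with pytest.raises(ValueError):
        fit_lgm(Y)
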