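"""Linear latent growth model for three-timepoint expression trajectories.

Each RNA's adjusted log2 expression at weeks 0, 2 and 8 is modelled as

    y_i = Lambda * eta_i + eps_i,      eta_i ~ N((mu_i, mu_s), Psi),
                                       eps_i ~ N(0, diag(theta))

with fixed loadings Lambda = [[1, 0], [1, 2], [1, 8]]: a random intercept
(expression level at baseline) and a random slope (rate of change per
week between weeks 0 and 8).  The model is fitted by maximum likelihood
on the mean and covariance structure; with 9 observed moments and 8 free
parameters the model has 1 degree of freedom, so a chi-square test and
the usual SEM fit indices (CFI, TLI, GFI, RMSEA, SRMR) are available.
Per-subject intercept/slope factor scores use the regression method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

DEFAULT_LOADINGS = np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 8.0]])


@dataclass
class GrowthModelFit:
    mu: np.ndarray            # (mu_intercept, mu_slope)
    psi: np.ndarray           # 2x2 latent covariance
    theta: np.ndarray         # 3 residual variances
    loadings: np.ndarray      # 3x2
    fml: float                # ML discrepancy at the optimum
    chi_square: float         # T = scale * F_ML
    df: int
    loglik: float
    n_subjects: int
    converged: bool
    sample_mean: np.ndarray
    sample_cov: np.ndarray

    @property
    def implied_cov(self) -> np.ndarray:
        return self.loadings @ self.psi @ self.loadings.T + np.diag(self.theta)

    @property
    def implied_mean(self) -> np.ndarray:
        return self.loadings @ self.mu


@dataclass
class FitIndices:
    chi_square: float
    df: int
    chi_p: float
    cfi: float
    tli: float
    gfi: float
    rmsea: float
    srmr: float


@dataclass
class FactorScores:
    scores: np.ndarray             # n x 2 (intercept, slope)
    standardized_slope: np.ndarray # z-scored slope across subjects


def _moments(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ybar = Y.mean(axis=0)
    S = np.cov(Y, rowvar=False, ddof=1)
    return ybar, S


def fml_discrepancy(mu_vec, Sigma, ybar, S) -> float:
    """ML discrepancy F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p + (ybar-mu)' Sigma^-1 (ybar-mu)."""
    p = len(ybar)
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    Sinv = np.linalg.inv(Sigma)
    d = ybar - mu_vec
    return float(logdet_sigma - logdet_s + np.trace(S @ Sinv) - p + d @ Sinv @ d)


def _unpack(params: np.ndarray, loadings: np.ndarray):
    mu = params[:2]
    l11, l21, l22 = params[2:5]
    L = np.array([[l11, 0.0], [l21, l22]])
    psi = L @ L.T
    theta = np.exp(params[5:8])
    Sigma = loadings @ psi @ loadings.T + np.diag(theta)
    return mu, psi, theta, Sigma


def _objective(params, loadings, ybar, S):
    mu, _, _, Sigma = _unpack(params, loadings)
    return fml_discrepancy(loadings @ mu, Sigma, ybar, S)


def _objective_grad(params, loadings, ybar, S):
    """F_ML and its analytic gradient in (mu, Cholesky(Psi), log theta)."""
    mu, _, theta, Sigma = _unpack(params, loadings)
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf, np.zeros_like(params)
    Sinv = np.linalg.inv(Sigma)
    d = ybar - loadings @ mu
    _, logdet_s = np.linalg.slogdet(S)
    f = logdet_sigma - logdet_s + np.trace(S @ Sinv) - len(ybar) + d @ Sinv @ d
    # dF/dSigma and chain rule through the parameterization
    G = Sinv - Sinv @ (S + np.outer(d, d)) @ Sinv
    H = loadings.T @ G @ loadings
    l11, l21, l22 = params[2:5]
    L = np.array([[l11, 0.0], [l21, l22]])
    dL = 2.0 * H @ L
    grad = np.empty(8)
    grad[:2] = -2.0 * loadings.T @ (Sinv @ d)
    grad[2] = dL[0, 0]
    grad[3] = dL[1, 0]
    grad[4] = dL[1, 1]
    grad[5:8] = np.diag(G) * theta
    return float(f), grad


def _start_values(Y: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    # per-subject OLS growth coefficients as method-of-moments start
    pinv = np.linalg.pinv(loadings)
    ab = Y @ pinv.T
    mu0 = ab.mean(axis=0)
    psi0 = np.cov(ab, rowvar=False, ddof=1)
    resid = Y - ab @ loadings.T
    theta0 = np.maximum(resid.var(axis=0, ddof=1), 1e-3 * Y.var(axis=0, ddof=1).mean())
    # shrink Psi toward its diagonal so the Cholesky start is well-conditioned
    psi0 = 0.9 * psi0 + 0.1 * np.diag(np.diag(psi0)) + 1e-8 * np.eye(2)
    L = np.linalg.cholesky(psi0)
    theta0 = np.maximum(theta0, 1e-10)
    return np.array([mu0[0], mu0[1], L[0, 0], L[1, 0], L[1, 1], *np.log(theta0)])


def fit_lgm(
    expr_3col: np.ndarray,
    loadings: np.ndarray | None = None,
    chi_square_scale: str = "n-1",
    max_iter: int = 500,
    tol: float = 1e-12,
) -> GrowthModelFit:
    """Maximum-likelihood fit of the linear growth model to an n x 3 matrix.

    Psi is parameterized through its Cholesky factor and the residual
    variances through their logs, so the implied covariance stays positive
    definite.  The chi-square statistic is T = (n-1) * F_ML by default
    ("n-1", Wishart convention) or n * F_ML ("n").
    """
    Y = np.asarray(expr_3col, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 3:
        raise ValueError("expected an n x 3 matrix (weeks 0, 2, 8)")
    if Y.shape[0] < 20:
        raise ValueError("growth model needs at least 20 subjects")
    if np.any(np.isnan(Y)):
        raise ValueError("complete three-timepoint data required")
    loadings = DEFAULT_LOADINGS if loadings is None else np.asarray(loadings, dtype=float)
    ybar, S = _moments(Y)
    if np.all(np.diag(S) == 0):
        raise ValueError("constant data; growth model not identified")
    evals = np.linalg.eigvalsh(S)
    if evals.min() <= 1e-10 * evals.max():
        # degenerate (e.g. noise-free) data: tiny ridge keeps ln|S| finite;
        # theta is driven to the ridge scale and (mu, Psi) to the moments
        S = S + 1e-8 * np.mean(np.diag(S)) * np.eye(3)

    x0 = _start_values(Y, loadings)
    bounds = [(None, None)] * 5 + [(np.log(1e-12), np.log(1e12))] * 3
    res = optimize.minimize(
        _objective_grad,
        x0,
        args=(loadings, ybar, S),
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    mu, psi, theta, Sigma = _unpack(res.x, loadings)
    n = Y.shape[0]
    scale = (n - 1) if chi_square_scale == "n-1" else n
    fml = float(res.fun)
    # saturated multivariate-normal loglik minus scale*F/2
    _, logdet_s = np.linalg.slogdet(S)
    ll_sat = -0.5 * n * (3 * np.log(2 * np.pi) + logdet_s + 3 * (n - 1) / n)
    loglik = ll_sat - 0.5 * scale * fml
    return GrowthModelFit(
        mu=mu,
        psi=psi,
        theta=theta,
        loadings=loadings,
        fml=fml,
        chi_square=max(scale * fml, 0.0),
        df=1,
        loglik=float(loglik),
        n_subjects=n,
        converged=bool(res.success),
        sample_mean=ybar,
        sample_cov=S,
    )


def fit_independence_baseline(expr_3col: np.ndarray, chi_square_scale: str = "n-1") -> tuple[float, int]:
    """Chi-square of the independence model (free means/variances, zero covariances).

    With the means and variances saturated, F reduces to ln|diag(S)| - ln|S|;
    df = 3 (the three off-diagonal moments).
    """
    Y = np.asarray(expr_3col, dtype=float)
    _, S = _moments(Y)
    _, logdet_s = np.linalg.slogdet(S)
    f = float(np.sum(np.log(np.diag(S))) - logdet_s)
    n = Y.shape[0]
    scale = (n - 1) if chi_square_scale == "n-1" else n
    return max(scale * f, 0.0), 3


def fit_indices(fit: GrowthModelFit, baseline: tuple[float, int] | None = None) -> FitIndices:
    """SEM fit indices for a fitted growth model.

    CFI and TLI compare against the independence baseline; GFI and SRMR
    are computed from the implied versus sample covariance; RMSEA from the
    noncentrality (T - df) per df and subject.
    """
    T, df, n = fit.chi_square, fit.df, fit.n_subjects
    if baseline is None:
        Tb, dfb = fit_independence_baseline_from_moments(fit.sample_cov, n)
    else:
        Tb, dfb = baseline
    num = max(T - df, 0.0)
    den = max(Tb - dfb, T - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    if Tb / dfb <= 1.0:
        tli = 1.0  # baseline fits no worse than chance; capped
    else:
        tli = min(((Tb / dfb) - (T / df)) / ((Tb / dfb) - 1.0), 1.0)
    S = fit.sample_cov
    Sigma = fit.implied_cov
    SigInvS = np.linalg.inv(Sigma) @ S
    I = np.eye(3)
    gfi = 1.0 - np.trace((SigInvS - I) @ (SigInvS - I)) / np.trace(SigInvS @ SigInvS)
    rmsea = np.sqrt(num / (df * (n - 1)))
    dsd = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    std_resid = (S - Sigma) / dsd
    iu = np.triu_indices(3)
    srmr = float(np.sqrt(np.mean(std_resid[iu] ** 2)))
    chi_p = float(stats.chi2.sf(T, df))
    return FitIndices(T, df, chi_p, float(cfi), float(tli), float(gfi), float(rmsea), srmr)


def fit_independence_baseline_from_moments(S: np.ndarray, n: int) -> tuple[float, int]:
    _, logdet_s = np.linalg.slogdet(S)
    f = float(np.sum(np.log(np.diag(S))) - logdet_s)
    return max((n - 1) * f, 0.0), 3


def factor_scores(fit: GrowthModelFit, expr_3col: np.ndarray) -> FactorScores:
    """Regression-method factor scores eta_hat = mu + Psi L' Sigma^-1 (y - L mu).

    The standardized slope is the slope score z-scored across subjects
    (sample SD, ddof=1), matching risk ratios expressed per 1 SD of slope.
    """
    Y = np.asarray(expr_3col, dtype=float)
    Sigma = fit.implied_cov
    sign, _ = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise ValueError("implied covariance is not positive definite")
    Sinv = np.linalg.inv(Sigma)
    A = fit.psi @ fit.loadings.T @ Sinv  # 2x3
    dev = Y - fit.implied_mean[None, :]
    scores = fit.mu[None, :] + dev @ A.T
    slope = scores[:, 1]
    sd = slope.std(ddof=1)
    if sd == 0:
        raise ValueError("slope scores are constant; cannot standardize")
    return FactorScores(scores=scores, standardized_slope=(slope - slope.mean()) / sd)


def fit_gene_panel(adjusted_expression: dict[int, "pd.DataFrame"], genes, **kwargs):
    """Fit the growth model for each gene in `genes`.

    `adjusted_expression` maps week -> genes x subjects table (all weeks
    sharing subject order).  Returns (fits dict, per-gene index table,
    intercept score table, slope score table) as pandas objects.
    """
    import pandas as pd

    weeks = sorted(adjusted_expression)
    subjects = adjusted_expression[weeks[0]].columns
    fits: dict[str, GrowthModelFit] = {}
    rows = []
    inter = {}
    slope = {}
    for g in genes:
        Y = np.column_stack([adjusted_expression[w].loc[g].values for w in weeks])
        fit = fit_lgm(Y, **kwargs)
        idx = fit_indices(fit)
        fs = factor_scores(fit, Y)
        fits[g] = fit
        rows.append(
            {
                "gene": g,
                "mu_intercept": fit.mu[0],
                "mu_slope": fit.mu[1],
                "var_intercept": fit.psi[0, 0],
                "var_slope": fit.psi[1, 1],
                "cov_is": fit.psi[0, 1],
                "theta_t0": fit.theta[0],
                "theta_t2": fit.theta[1],
                "theta_t8": fit.theta[2],
                "chi_square": idx.chi_square,
                "chi_p": idx.chi_p,
                "cfi": idx.cfi,
                "tli": idx.tli,
                "gfi": idx.gfi,
                "rmsea": idx.rmsea,
                "srmr": idx.srmr,
                "converged": fit.converged,
            }
        )
        inter[g] = fs.scores[:, 0]
        slope[g] = fs.standardized_slope
    table = pd.DataFrame(rows).set_index("gene")
    intercepts = pd.DataFrame(inter, index=subjects)
    slopes = pd.DataFrame(slope, index=subjects)
    return fits, table, intercepts, slopes
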