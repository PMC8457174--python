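"""Relating psychiatric dimensions to task behavior.

Inputs are participant summary tables (one row per participant) holding
per-participant performance counts, fitted RL parameters, factor scores
(CIT/AD/IM), and covariates (age, sex, education, ses).  All regression
inputs are z-normalised within the analysis sample; the inverse
temperature enters parameter regressions log-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .history_regression import COVARIATE_NAMES, FACTOR_NAMES, bh_fdr

__all__ = [
    "performance_model",
    "parameter_regression",
    "loo_cv_prediction",
    "loo_cv_predictions_matrix",
    "permutation_test",
    "PermutationResult",
]

log = logging.getLogger(__name__)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _design(summaries: pd.DataFrame, columns: list[str]) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(summaries))]
        + [_zscore(summaries[c].to_numpy(dtype=float)) for c in columns]
    )


# ---------------------------------------------------------------------------
# Performance ~ factors


def _gh_binomial_nll(
    theta: np.ndarray, X: np.ndarray, k: np.ndarray, n: np.ndarray, nodes, weights
) -> float:
    """Adaptive Gauss-Hermite negative log-likelihood.

    Per participant, the binomial x Gaussian integrand is re-centred on its
    mode with curvature-matched scaling (a few vectorised Newton steps)
    before the Hermite rule is applied, so large-n binomials whose mass sits
    far from u = 0 are integrated accurately.
    """
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta  # (N,)

    # mode of log[binom(k; n, expit(eta + sigma u)) * phi(u)] per participant
    u0 = np.zeros_like(eta)
    for _ in range(25):
        p = 1.0 / (1.0 + np.exp(-(eta + sigma * u0)))
        grad = sigma * (k - n * p) - u0
        hess = -(sigma**2) * n * p * (1.0 - p) - 1.0
        step = grad / hess
        u0 = u0 - step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = 1.0 / (1.0 + np.exp(-(eta + sigma * u0)))
    scale = 1.0 / np.sqrt(sigma**2 * n * p * (1.0 - p) + 1.0)  # (-hess)^(-1/2)

    u = u0[:, None] + np.sqrt(2.0) * scale[:, None] * nodes[None, :]
    lin = eta[:, None] + sigma * u
    # binomial coefficient omitted (constant in theta); phi(u) in logs
    ll = (
        k[:, None] * (-np.logaddexp(0.0, -lin))
        + (n - k)[:, None] * (-np.logaddexp(0.0, lin))
        - 0.5 * u**2
        - 0.5 * np.log(2.0 * np.pi)
    )
    # adaptive GH: sum w_j exp(x_j^2) g(u_j) * sqrt(2) * scale
    log_terms = ll + nodes[None, :] ** 2 + np.log(weights)[None, :]
    m = log_terms.max(axis=1, keepdims=True)
    lik = (
        np.log(np.exp(log_terms - m).sum(axis=1))
        + m[:, 0]
        + 0.5 * np.log(2.0)
        + np.log(scale)
    )
    return -float(lik.sum())


def performance_model(
    summaries: pd.DataFrame,
    estimator: str = "random_intercept_logit",
    n_quad: int = 32,
) -> pd.DataFrame:
    """Random-intercept logistic model of per-trial correctness.

    ``summaries`` needs columns n_correct, n_responded, the factors, and
    covariates.  Returns an effect table with FDR q-values over the three
    factor terms.  Predictors are participant-level, so the per-participant
    likelihood is a binomial integrated over a Gaussian random intercept
    (Gauss-Hermite quadrature).
    """
    if len(summaries) < 30:
        raise ValueError("performance model needs >= 30 participants")
    predictors = [*FACTOR_NAMES, *COVARIATE_NAMES]
    X = _design(summaries, predictors)
    k = summaries["n_correct"].to_numpy(dtype=float)
    n = summaries["n_responded"].to_numpy(dtype=float)
    names = ["const", *predictors]

    if estimator == "aggregated_ols":
        return _aggregated_ols(summaries, X, k, n, names)
    if estimator != "random_intercept_logit":
        raise ValueError(f"unknown estimator {estimator!r}")

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    # start from the aggregated empirical-logit OLS solution
    elogit = np.log((k + 0.5) / (n - k + 0.5))
    beta0 = np.linalg.lstsq(X, elogit, rcond=None)[0]
    theta0 = np.concatenate([beta0, [np.log(0.5)]])
    res = minimize(
        _gh_binomial_nll, theta0, args=(X, k, n, nodes, weights),
        method="L-BFGS-B", options={"maxiter": 500},
    )
    if not res.success:
        log.warning("quadrature fit did not converge; falling back to aggregated OLS")
        return _aggregated_ols(summaries, X, k, n, names)
    theta = res.x
    H = _numeric_hessian(
        lambda t: _gh_binomial_nll(t, X, k, n, nodes, weights), theta
    )
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(theta.size - 1, np.nan)
    coef = theta[:-1]
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"term": names, "coef": coef, "se": se, "p": p})
    out["sigma_u"] = np.exp(theta[-1])
    _attach_factor_fdr(out)
    return out


def _aggregated_ols(summaries, X, k, n, names) -> pd.DataFrame:
    import statsmodels.api as sm

    elogit = np.log((k + 0.5) / (n - k + 0.5))
    fit = sm.OLS(elogit, X).fit(cov_type="HC1")
    out = pd.DataFrame(
        {"term": names, "coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    _attach_factor_fdr(out)
    return out


def _attach_factor_fdr(table: pd.DataFrame) -> None:
    mask = table["term"].isin(FACTOR_NAMES)
    table["q"] = np.nan
    table.loc[mask, "q"] = bh_fdr(table.loc[mask, "p"].to_numpy())


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


# ---------------------------------------------------------------------------
# CIT ~ RL parameters


def parameter_regression(
    summaries: pd.DataFrame,
    directions: dict[str, int] | None = None,
) -> pd.DataFrame:
    """OLS of CIT on the fitted RL parameters with one-tailed tests.

    The inverse temperature is log-transformed (its raw skewness and excess
    kurtosis are reported alongside).  One-tailed p-values are computed in
    the hypothesised direction per parameter (default: alpha negative,
    log-beta negative, gamma positive); FDR is applied over those three
    terms.
    """
    import statsmodels.api as sm

    directions = directions or {"alpha": -1, "log_beta": -1, "gamma": 1}
    df = summaries.copy()
    raw_beta = df["beta"].to_numpy(dtype=float)
    df["log_beta"] = np.log(raw_beta)
    param_terms = ["alpha", "log_beta", "gamma", "alpha_F", "alpha_C"]
    predictors = [*param_terms, *COVARIATE_NAMES, "AD", "IM"]
    X = _design(df, predictors)
    names = ["const", *predictors]
    cond = np.linalg.cond(X)
    if cond > 1e8:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        bad = [
            f"{predictors[i]}~{predictors[j]}"
            for i in range(len(predictors))
            for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"collinear predictors (cond={cond:.3g}): {bad}")
    y = _zscore(df["CIT"].to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()
    out = pd.DataFrame(
        {"term": names, "coef": fit.params, "se": fit.bse, "p_two": fit.pvalues}
    )
    tvals = fit.tvalues
    dof = fit.df_resid
    p_one = np.full(len(names), np.nan)
    for i, name in enumerate(names):
        if name in directions:
            p_one[i] = stats.t.sf(directions[name] * tvals[i], dof)
    out["p_one"] = p_one
    mask = out["term"].isin(directions)
    out["q"] = np.nan
    out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p_one"].to_numpy())
    out.attrs["beta_skewness"] = float(stats.skew(raw_beta))
    out.attrs["beta_kurtosis"] = float(stats.kurtosis(raw_beta, fisher=False))
    out.attrs["beta_log_transformed"] = bool(out.attrs["beta_skewness"] > 2)
    return out


# ---------------------------------------------------------------------------
# Leave-one-out prediction and permutation testing


def _loo_machinery(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual-maker matrix and hat diagonal for LOO linear prediction."""
    XtX_inv = np.linalg.inv(X.T @ X)
    H = X @ XtX_inv @ X.T
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-10)
    M = np.eye(X.shape[0]) - H
    return M, h


def _model_columns(model: str) -> list[str]:
    if model == "full":
        return list(FACTOR_NAMES)
    if model == "without_CIT":
        return [f for f in FACTOR_NAMES if f != "CIT"]
    raise ValueError(f"unknown model {model!r}")


def loo_cv_prediction(
    y: np.ndarray, X: pd.DataFrame, model: str = "full"
) -> float:
    """Leave-one-out cross-validated Pearson correlation of a linear model.

    For each i the model is fit on all other rows and predicts row i; the
    closed-form LOO residual e_i / (1 - h_ii) avoids refitting.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 20:
        raise ValueError("need n >= 20 for LOO prediction")
    cols = _model_columns(model)
    Xm = np.column_stack([np.ones(y.size)] + [X[c].to_numpy(dtype=float) for c in cols])
    M, h = _loo_machinery(Xm)
    pred = y - (M @ y) / (1.0 - h)
    if pred.std() == 0:
        log.warning("zero-variance LOO predictions; correlation undefined")
        return np.nan
    return float(np.corrcoef(pred, y)[0, 1])


def loo_cv_predictions_matrix(
    Y: np.ndarray, X: pd.DataFrame, model: str
) -> np.ndarray:
    """Columnwise LOO correlations for a matrix of outcome vectors."""
    cols = _model_columns(model)
    n = Y.shape[0]
    Xm = np.column_stack([np.ones(n)] + [X[c].to_numpy(dtype=float) for c in cols])
    M, h = _loo_machinery(Xm)
    pred = Y - (M @ Y) / (1.0 - h)[:, None]
    pc = pred - pred.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    denom = np.sqrt((pc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (pc * yc).sum(axis=0) / denom


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    observed_diff: float
    r_full: float
    r_without_cit: float
    n_perm: int


def permutation_test(
    y: np.ndarray,
    X: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the LOO-accuracy gain from including CIT.

    The predicted variable is permuted ``n_perm`` times; both the full and
    the CIT-omitting model are refit per permutation, and the p-value is
    the fraction of null accuracy differences at least as large as the
    observed one (with the observed included in the numerator and
    denominator).
    """
    if n_perm < 100:
        log.warning("n_perm=%d is very small; p-value will be coarse", n_perm)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r_full = loo_cv_prediction(y, X, "full")
    r_red = loo_cv_prediction(y, X, "without_CIT")
    observed = r_full - r_red
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    null = loo_cv_predictions_matrix(perms, X, "full") - loo_cv_predictions_matrix(
        perms, X, "without_CIT"
    )
    null = null[np.isfinite(null)]
    p = (1.0 + float((null >= observed).sum())) / (1.0 + null.size)
    return PermutationResult(
        p_value=p,
        observed_diff=float(observed),
        r_full=float(r_full),
        r_without_cit=float(r_red),
        n_perm=n_perm,
    )
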