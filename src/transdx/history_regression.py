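"""Lagged reward/choice history regression of trial-by-trial choices.

The three-option task is reduced to a binary logit for a fixed target
option X.  For each responded trial t with a full lag window, the design
carries, for lags tau = 1..tau_max:

* ``R_tau`` = +1 if X was chosen and the outcome was a success at t - tau,
  -1 if another option was chosen and the outcome was a success, 0 if the
  outcome was not a success ("success" means reward, or no-loss in the
  loss context).  A missed lagged trial contributes 0.
* ``C_tau`` = +1 if X was chosen at t - tau, -1 otherwise, 0 if missed.

Estimation is two-stage by default: ridge-penalised per-participant
logistic fits, followed by group-level least squares of each participant
coefficient on the psychiatric factors and covariates with
heteroscedasticity-robust standard errors.  Total effects are sums of
per-lag coefficients; by linearity the group-level slope of the total
equals the sum of per-lag slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from .bandit_env import ChoiceSession, CorrectLabeling, success_mask

__all__ = [
    "FACTOR_NAMES",
    "COVARIATE_NAMES",
    "HistoryEffects",
    "build_history_design",
    "ridge_logistic",
    "stage1_coefficients",
    "fit_history_model",
    "total_effects",
    "bh_fdr",
    "joint_task_model",
]

log = logging.getLogger(__name__)

FACTOR_NAMES = ("CIT", "AD", "IM")
COVARIATE_NAMES = ("age", "sex", "education", "ses")


def build_history_design(
    session: ChoiceSession,
    labeling: CorrectLabeling | None = None,
    target_option: int = 0,
    tau_max: int = 4,
) -> pd.DataFrame:
    """One row per eligible trial with lagged reward/choice regressors.

    Eligible trials are responded trials t (1-based) with t > tau_max.
    """
    if not 2 <= tau_max <= 6:
        raise ValueError("tau_max must be within [2, 6]")
    n = session.n_trials
    if n <= tau_max:
        log.warning(
            "session %s shorter than tau_max + 1; empty design",
            session.participant_id,
        )
        return _empty_design(tau_max)
    choices = session.choices
    responded = session.responded
    success = success_mask(session)
    is_x = responded & (choices == target_option)

    r_code = np.zeros(n)
    r_code[success & is_x] = 1.0
    r_code[success & responded & ~is_x] = -1.0
    c_code = np.zeros(n)
    c_code[is_x] = 1.0
    c_code[responded & ~is_x] = -1.0

    t_idx = np.arange(tau_max, n)
    keep = responded[t_idx]
    t_idx = t_idx[keep]
    data: dict[str, np.ndarray] = {
        "participant_id": np.repeat(session.participant_id, t_idx.size),
        "trial": t_idx + 1,
        "y": (choices[t_idx] == target_option).astype(float),
    }
    for tau in range(1, tau_max + 1):
        data[f"R{tau}"] = r_code[t_idx - tau]
        data[f"C{tau}"] = c_code[t_idx - tau]
    return pd.DataFrame(data)


def _empty_design(tau_max: int) -> pd.DataFrame:
    cols = ["participant_id", "trial", "y"]
    cols += [f"R{t}" for t in range(1, tau_max + 1)]
    cols += [f"C{t}" for t in range(1, tau_max + 1)]
    return pd.DataFrame({c: [] for c in cols})


def _lag_columns(tau_max: int) -> list[str]:
    return [f"R{t}" for t in range(1, tau_max + 1)] + [
        f"C{t}" for t in range(1, tau_max + 1)
    ]


def ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    penalty: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """IRLS logistic regression with an L2 penalty on non-intercept terms.

    The first column of X is taken to be the intercept.  If the fit
    diverges (quasi-separation), the penalty is escalated tenfold, up to
    1e4, and the event is logged.
    """
    n, p = X.shape
    lam = penalty
    while True:
        beta = np.zeros(p)
        pen = np.full(p, lam)
        pen[0] = 0.0
        ok = True
        for _ in range(max_iter):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            w = mu * (1.0 - mu)
            grad = X.T @ (y - mu) - pen * beta
            H = (X * w[:, None]).T @ X + np.diag(pen)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                ok = False
                break
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                break
            if np.max(np.abs(beta)) > 50.0:
                ok = False
                break
        if ok and np.max(np.abs(beta)) <= 50.0:
            return beta
        if lam >= 1e4:
            return beta
        lam *= 10.0
        log.info("ridge penalty escalated to %g (separation suspected)", lam)


def stage1_coefficients(
    designs: Sequence[pd.DataFrame], tau_max: int, penalty: float = 1.0
) -> pd.DataFrame:
    """Per-participant logistic coefficients for each lag term."""
    lag_cols = _lag_columns(tau_max)
    rows = []
    for d in designs:
        if len(d) == 0:
            continue
        pid = d["participant_id"].iloc[0]
        X = np.column_stack([np.ones(len(d)), d[lag_cols].to_numpy(dtype=float)])
        beta = ridge_logistic(X, d["y"].to_numpy(dtype=float), penalty=penalty)
        rows.append({"participant_id": pid, "intercept": beta[0],
                     **dict(zip(lag_cols, beta[1:]))})
    return pd.DataFrame(rows)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _group_regression(
    coef: pd.DataFrame,
    participants: pd.DataFrame,
    response_cols: Sequence[str],
    predictors: Sequence[str],
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of each per-participant coefficient on z-scored predictors.

    Returns one row per (response, term) with HC1-robust se and two-tailed p.
    ``extra`` may supply additional (non-z-scored) columns such as task codes
    and their interactions.
    """
    import statsmodels.api as sm

    merged = coef.merge(participants, on="participant_id", validate="m:1")
    if len(merged) < len(coef):
        raise ValueError("factor scores missing for some participants")
    Z = np.column_stack([_zscore(merged[p].to_numpy(dtype=float)) for p in predictors])
    names = ["const", *predictors]
    X = np.column_stack([np.ones(len(merged)), Z])
    if extra is not None:
        X = np.column_stack([X, extra.to_numpy(dtype=float)])
        names += list(extra.columns)
    out = []
    for resp in response_cols:
        y = merged[resp].to_numpy(dtype=float)
        fit = sm.OLS(y, X).fit(cov_type="HC1")
        for j, name in enumerate(names):
            out.append(
                {
                    "response": resp,
                    "term": name,
                    "coef": fit.params[j],
                    "se": fit.bse[j],
                    "p": fit.pvalues[j],
                }
            )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class HistoryEffects:
    """Output of the hierarchical history regression."""

    per_participant: pd.DataFrame  # stage-1 coefficients incl. totals
    effects: pd.DataFrame  # per-lag group-level terms
    totals: pd.DataFrame  # total-effect group-level terms with q values
    tau_max: int
    estimator: str


def _add_totals(coef: pd.DataFrame, tau_max: int) -> pd.DataFrame:
    coef = coef.copy()
    coef["total_R"] = coef[[f"R{t}" for t in range(1, tau_max + 1)]].sum(axis=1)
    coef["total_C"] = coef[[f"C{t}" for t in range(1, tau_max + 1)]].sum(axis=1)
    return coef


def _shrink_stage1(
    designs: Sequence[pd.DataFrame], tau_max: int, penalty: float, n_em: int = 3
) -> pd.DataFrame:
    """Laplace-EM approximation of the random-slope GLMM.

    Per-participant modes are found under a Gaussian prior centred on the
    group mean with per-coefficient variances; mean and variances are
    re-estimated from the modes for a few EM sweeps.  This is a cheap
    stand-in for the full joint Laplace fit, with diagonal random-effect
    covariance.
    """
    lag_cols = _lag_columns(tau_max)
    coef = stage1_coefficients(designs, tau_max, penalty=penalty)
    cols = ["intercept", *lag_cols]
    designs = [d for d in designs if len(d) > 0]
    for _ in range(n_em):
        mu = coef[cols].mean(axis=0).to_numpy()
        var = np.maximum(coef[cols].var(axis=0, ddof=1).to_numpy(), 1e-3)
        rows = []
        for d in designs:
            pid = d["participant_id"].iloc[0]
            X = np.column_stack([np.ones(len(d)), d[lag_cols].to_numpy(dtype=float)])
            y = d["y"].to_numpy(dtype=float)
            beta = mu.copy()
            for _ in range(50):
                eta = X @ beta
                p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
                w = p * (1.0 - p)
                grad = X.T @ (y - p) - (beta - mu) / var
                H = (X * w[:, None]).T @ X + np.diag(1.0 / var)
                step = np.linalg.solve(H, grad)
                beta = beta + step
                if np.max(np.abs(step)) < 1e-8:
                    break
            rows.append({"participant_id": pid, **dict(zip(cols, beta))})
        coef = pd.DataFrame(rows)
    return coef


def fit_history_model(
    designs: Sequence[pd.DataFrame],
    participants: pd.DataFrame,
    tau_max: int = 4,
    estimator: str = "two_stage",
    penalty: float = 1.0,
    predictors: Sequence[str] | None = None,
) -> HistoryEffects:
    """Hierarchical estimation of history main effects and factor interactions.

    ``participants`` must hold participant_id, the factor scores (CIT, AD,
    IM) and covariates (age, sex, education, ses).  All predictors are
    z-normalised within the analysis sample.
    """
    if estimator not in ("two_stage", "laplace_glmm"):
        raise ValueError(f"unknown estimator {estimator!r}")
    designs = [d for d in designs if len(d) > 0]
    if len(designs) < 2:
        raise ValueError("group-level model needs at least 2 participants")
    predictors = list(predictors or (*FACTOR_NAMES, *COVARIATE_NAMES))
    if estimator == "laplace_glmm":
        coef = _shrink_stage1(designs, tau_max, penalty)
    else:
        coef = stage1_coefficients(designs, tau_max, penalty=penalty)
    coef = _add_totals(coef, tau_max)
    lag_cols = _lag_columns(tau_max)
    effects = _group_regression(coef, participants, lag_cols, predictors)
    totals = _group_regression(coef, participants, ["total_R", "total_C"], predictors)
    # FDR over the factor-interaction terms, per the number of explanatory
    # variables of interest
    mask = totals["term"].isin(FACTOR_NAMES)
    totals["q"] = np.nan
    totals.loc[mask, "q"] = bh_fdr(totals.loc[mask, "p"].to_numpy())
    return HistoryEffects(
        per_participant=coef,
        effects=effects,
        totals=totals,
        tau_max=tau_max,
        estimator=estimator,
    )


def total_effects(result: HistoryEffects) -> dict[str, float]:
    """Totals keyed 'beta_R', 'beta_C', 'beta_R:CIT', ... from the group model."""
    out: dict[str, float] = {}
    for resp, label in (("total_R", "beta_R"), ("total_C", "beta_C")):
        sub = result.totals[result.totals["response"] == resp]
        out[label] = float(sub.loc[sub["term"] == "const", "coef"].iloc[0])
        for f in FACTOR_NAMES:
            row = sub.loc[sub["term"] == f]
            if len(row):
                out[f"{label}:{f}"] = float(row["coef"].iloc[0])
    return out


def bh_fdr(p_values: np.ndarray, n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = n_tests if n_tests is not None else p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def joint_task_model(
    designs_reward: Sequence[pd.DataFrame],
    designs_loss: Sequence[pd.DataFrame],
    participants: pd.DataFrame,
    tau_max: int = 4,
    estimator: str = "two_stage",
    penalty: float = 1.0,
    task_coding: tuple[float, float] = (1.0, -1.0),
) -> pd.DataFrame:
    """Group-level model pooling both arms with task (+1/-1) interactions.

    Adds a task main effect and task x predictor interactions (so the
    three-way history x factor x task terms appear as ``<factor>:task`` rows
    for the total_R / total_C responses).
    """
    designs_reward = [d for d in designs_reward if len(d) > 0]
    designs_loss = [d for d in designs_loss if len(d) > 0]
    if not designs_reward or not designs_loss:
        raise ValueError("both task arms are required")
    predictors = [*FACTOR_NAMES, *COVARIATE_NAMES]

    def _coef(designs: Sequence[pd.DataFrame], code: float) -> pd.DataFrame:
        if estimator == "laplace_glmm":
            c = _shrink_stage1(designs, tau_max, penalty)
        else:
            c = stage1_coefficients(designs, tau_max, penalty=penalty)
        c = _add_totals(c, tau_max)
        c["task"] = code
        return c

    import statsmodels.api as sm

    coef = pd.concat(
        [_coef(designs_reward, task_coding[0]), _coef(designs_loss, task_coding[1])],
        ignore_index=True,
    )
    if "task" in participants.columns:  # the arm label is derived from the designs
        participants = participants.drop(columns="task")
    merged = coef.merge(participants, on="participant_id", validate="m:1")
    if len(merged) < len(coef):
        raise ValueError("factor scores missing for some participants")
    Z = np.column_stack([_zscore(merged[p].to_numpy(dtype=float)) for p in predictors])
    task = merged["task"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(merged)), Z, task[:, None], Z * task[:, None]])
    names = ["const", *predictors, "task", *(f"{p}:task" for p in predictors)]
    rows = []
    for resp in ("total_R", "total_C"):
        fit = sm.OLS(merged[resp].to_numpy(dtype=float), X).fit(cov_type="HC1")
        for j, name in enumerate(names):
            rows.append(
                {
                    "response": resp,
                    "term": name,
                    "coef": fit.params[j],
                    "se": fit.bse[j],
                    "p": fit.pvalues[j],
                }
            )
    return pd.DataFrame(rows)
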