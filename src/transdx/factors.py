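"""Transdiagnostic factor pipeline for ordinal questionnaire batteries.

Steps: pairwise two-step polychoric correlations, scree-based factor-count
selection (CNG slope-difference rule), minimum-residual extraction with
promax rotation, and Harman idealized-variable factor scores.

The polychoric estimator is batched: thresholds come from the marginal
cumulative proportions via the inverse normal, and each pair's correlation
maximises the bivariate-normal likelihood of its contingency table, with
all pairs optimised simultaneously by golden-section search over rho and a
vectorised bivariate-normal CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "QuestionnaireData",
    "FactorSolution",
    "polychoric_matrix",
    "cng_factor_count",
    "extract_and_rotate",
    "harman_scores",
    "low_loading_filter",
    "nearest_psd",
]

log = logging.getLogger(__name__)

_INF_THRESH = 8.0  # effective +/- infinity on the latent normal scale


@dataclass(frozen=True)
class QuestionnaireData:
    """N x P ordinal response matrix with an item -> instrument map."""

    responses: np.ndarray  # integer codes, any ordered coding per item
    item_names: tuple[str, ...]
    item_instrument: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.responses)
        if r.ndim != 2:
            raise ValueError("responses must be 2-D (participants x items)")
        if not np.issubdtype(r.dtype, np.integer):
            if np.any(~np.isfinite(r)):
                raise ValueError("responses contain missing values")
            r = r.astype(np.int64)
        if np.any(r < 0):
            raise ValueError("negative response codes are not allowed")
        if len(self.item_names) != r.shape[1] or len(self.item_instrument) != r.shape[1]:
            raise ValueError("item metadata length mismatch")
        object.__setattr__(self, "responses", r)

    @property
    def n_participants(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.responses, columns=list(self.item_names))


@dataclass(frozen=True)
class FactorSolution:
    loadings: np.ndarray  # pattern matrix, P x m
    factor_corr: np.ndarray  # m x m
    eigenvalues: np.ndarray  # of the correlation matrix, length P
    n_factors: int
    explained_variance: np.ndarray  # length m
    uniquenesses: np.ndarray  # length P
    scores: np.ndarray | None = None  # N x m, filled by harman_scores


# ---------------------------------------------------------------------------
# Bivariate normal CDF, vectorised


def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: np.ndarray, n_gauss: int = 24) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normals, elementwise.

    Uses the single-integral identity Phi2 = Phi(h)Phi(k) +
    (1/2pi) * int_0^rho exp(-(h^2 - 2 r h k + k^2)/(2(1-r^2))) / sqrt(1-r^2) dr
    with Gauss-Legendre quadrature, vectorised over all arguments.
    """
    x, w = np.polynomial.legendre.leggauss(n_gauss)
    h = np.asarray(h, dtype=float)[..., None]
    k = np.asarray(k, dtype=float)[..., None]
    rho = np.asarray(rho, dtype=float)[..., None]
    r = 0.5 * rho * (x + 1.0)  # nodes on [0, rho]
    omr2 = 1.0 - r * r
    integrand = np.exp(-(h * h - 2.0 * r * h * k + k * k) / (2.0 * omr2)) / np.sqrt(omr2)
    integral = 0.5 * rho[..., 0] * (integrand * w).sum(axis=-1)
    base = stats.norm.cdf(h[..., 0]) * stats.norm.cdf(k[..., 0])
    return np.clip(base + integral / (2.0 * np.pi), 0.0, 1.0)


def _rank_code(column: np.ndarray) -> tuple[np.ndarray, int]:
    levels, coded = np.unique(column, return_inverse=True)
    return coded, levels.size


def _item_thresholds(coded: np.ndarray, n_levels: int) -> np.ndarray:
    counts = np.bincount(coded, minlength=n_levels)
    cum = np.cumsum(counts)[:-1] / coded.size
    return stats.norm.ppf(cum)


def polychoric_matrix(
    data: QuestionnaireData | np.ndarray | pd.DataFrame,
    n_gauss: int = 16,
    n_golden: int = 36,
    rho_bound: float = 0.995,
    block: int = 2000,
) -> np.ndarray:
    """Pairwise two-step polychoric correlation matrix.

    Raises if any item has a single observed level.  A nearest-PSD repair
    (eigenvalue clipping) is applied if the pairwise matrix is indefinite.
    """
    if isinstance(data, QuestionnaireData):
        X = data.responses
        names = data.item_names
    else:
        frame = pd.DataFrame(data)
        X = frame.to_numpy()
        names = tuple(str(c) for c in frame.columns)
    n, p = X.shape
    coded = np.empty((n, p), dtype=np.int64)
    n_levels = np.empty(p, dtype=np.int64)
    for j in range(p):
        coded[:, j], n_levels[j] = _rank_code(X[:, j])
        if n_levels[j] < 2:
            raise ValueError(f"item {names[j]!r} has a single observed level")
    l_max = int(n_levels.max())
    # padded threshold boundaries: tau[j] has length l_max + 1
    tau = np.full((p, l_max + 1), _INF_THRESH)
    tau[:, 0] = -_INF_THRESH
    for j in range(p):
        tau[j, 1:n_levels[j]] = _item_thresholds(coded[:, j], int(n_levels[j]))

    # all pairwise contingency tables via a one-hot cross product
    onehot = np.zeros((n, p * l_max))
    onehot[np.arange(n)[:, None], np.arange(p) * l_max + coded] = 1.0
    cross = onehot.T @ onehot  # (p*l_max, p*l_max)

    iu, ju = np.triu_indices(p, k=1)
    n_pairs = iu.size
    rho_hat = np.empty(n_pairs)

    lo_t = tau[:, :-1]  # lower cell boundary per level
    hi_t = tau[:, 1:]

    for start in range(0, n_pairs, block):
        sl = slice(start, min(start + block, n_pairs))
        bi, bj = iu[sl], ju[sl]
        b = bi.size
        counts = np.empty((b, l_max, l_max))
        for idx in range(b):
            i, j = bi[idx], bj[idx]
            counts[idx] = cross[i * l_max:(i + 1) * l_max, j * l_max:(j + 1) * l_max]
        a_lo = lo_t[bi][:, :, None] * np.ones((1, 1, l_max))
        a_hi = hi_t[bi][:, :, None] * np.ones((1, 1, l_max))
        b_lo = lo_t[bj][:, None, :] * np.ones((1, l_max, 1))
        b_hi = hi_t[bj][:, None, :] * np.ones((1, l_max, 1))
        nonzero = counts > 0

        def neg_loglik(rho: np.ndarray) -> np.ndarray:
            r = rho[:, None, None]
            cell = (
                _bvn_cdf(a_hi, b_hi, r, n_gauss)
                - _bvn_cdf(a_lo, b_hi, r, n_gauss)
                - _bvn_cdf(a_hi, b_lo, r, n_gauss)
                + _bvn_cdf(a_lo, b_lo, r, n_gauss)
            )
            cell = np.maximum(cell, 1e-12)
            return -(np.where(nonzero, counts * np.log(cell), 0.0)).sum(axis=(1, 2))

        rho_hat[sl] = _golden_min(neg_loglik, b, -rho_bound, rho_bound, n_golden)

    R = np.eye(p)
    R[iu, ju] = rho_hat
    R[ju, iu] = rho_hat
    return nearest_psd(R)


def _golden_min(f, n: int, lo: float, hi: float, n_iter: int) -> np.ndarray:
    """Batched golden-section minimisation of a vectorised scalar function."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(n, lo)
    b = np.full(n, hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = f(c)
    fd = f(d)
    for _ in range(n_iter):
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c_cand = b - invphi * (b - a)
        d_cand = a + invphi * (b - a)
        probe = np.where(left, c_cand, d_cand)  # single fresh evaluation
        f_probe = f(probe)
        new_c = np.where(left, c_cand, d)
        new_d = np.where(left, c, d_cand)
        new_fc = np.where(left, f_probe, fd)
        new_fd = np.where(left, fc, f_probe)
        c, d, fc, fd = new_c, new_d, new_fc, new_fd
    return (a + b) / 2.0


def nearest_psd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-semidefinite repair, unit diagonal restored."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= eps:
        return R
    log.info("correlation matrix indefinite (min eig %.3g); clipping", vals.min())
    vals = np.clip(vals, eps, None)
    R2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


# ---------------------------------------------------------------------------
# Factor-number selection


def cng_factor_count(eigenvalues: np.ndarray, flat_tol: float = 1e-8) -> int:
    """Slope-difference scree rule over all triplets of adjacent eigenvalues.

    For each position i, fit least-squares slopes to eigenvalues
    (i, i+1, i+2) and (i+3, i+4, i+5); the factor count is the position
    maximising the slope difference, plus 2 (so the smallest returnable
    count is 3).  A flat scree (no dominant elbow) returns 1 with a warning.
    """
    e = np.asarray(eigenvalues, dtype=float)
    if e.ndim != 1 or e.size < 6:
        raise ValueError("need at least 6 eigenvalues")
    if np.any(np.diff(e) > 1e-10):
        raise ValueError("eigenvalues must be sorted in descending order")
    x = np.arange(3, dtype=float)

    def slope(seg: np.ndarray) -> float:
        return float(np.polyfit(x, seg, 1)[0])

    diffs = np.array(
        [slope(e[i + 3:i + 6]) - slope(e[i:i + 3]) for i in range(e.size - 5)]
    )
    if diffs.max() < flat_tol:
        log.warning("flat scree: no dominant elbow; returning 1 factor")
        return 1
    return int(np.argmax(diffs)) + 3


# ---------------------------------------------------------------------------
# Extraction and rotation


def _minres_loadings(R: np.ndarray, n_factors: int) -> tuple[np.ndarray, np.ndarray]:
    """Unrotated loadings by minimum-residual (ULS) factoring.

    Minimises the sum of squared residual eigenvalues over uniquenesses,
    with the analytic gradient -diag(residual).
    """
    p = R.shape[0]
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.01, 0.99)

    def obj_grad(psi: np.ndarray) -> tuple[float, np.ndarray]:
        Rt = R.copy()
        np.fill_diagonal(Rt, 1.0 - psi)
        vals, vecs = np.linalg.eigh(Rt)
        resid_vals = vals[:-n_factors]
        resid_vecs = vecs[:, :-n_factors]
        f = 0.5 * float((resid_vals**2).sum())
        grad = -((resid_vecs**2) * resid_vals).sum(axis=1)
        return f, grad

    res = minimize(
        obj_grad, psi0, jac=True, method="L-BFGS-B",
        bounds=[(0.005, 0.995)] * p, options={"maxiter": 1000},
    )
    psi = res.x
    if np.any(psi <= 0.0051):
        log.warning("Heywood-adjacent uniquenesses clipped at the lower bound")
    Rt = R.copy()
    np.fill_diagonal(Rt, 1.0 - psi)
    vals, vecs = np.linalg.eigh(Rt)
    top = np.clip(vals[-n_factors:], 0.0, None)[::-1]
    L = vecs[:, -n_factors:][:, ::-1] * np.sqrt(top)
    return L, psi


def _varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation with Kaiser row normalisation."""
    p, k = L.shape
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        B = A @ R
        U, s, Vt = np.linalg.svd(
            A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        R = U @ Vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    return (A @ R) * h[:, None]


def _promax(L_varimax: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation of varimax loadings; returns (pattern, Phi)."""
    X = L_varimax
    Q = X * np.abs(X) ** (power - 1)
    U, *_ = np.linalg.lstsq(X, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)[None, :]
    pattern = X @ U
    ui = np.linalg.inv(U)
    phi = ui @ ui.T
    return pattern, phi


def extract_and_rotate(
    corr_matrix: np.ndarray,
    n_factors: int = 3,
    rotation: str = "promax",
    promax_power: int = 4,
) -> FactorSolution:
    """Minres extraction followed by promax (or varimax, or none)."""
    R = np.asarray(corr_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("corr_matrix must be square")
    if not 1 <= n_factors < R.shape[0]:
        raise ValueError("n_factors out of range")
    eigenvalues = np.linalg.eigvalsh(R)[::-1]
    L, psi = _minres_loadings(R, n_factors)
    if rotation == "none" or n_factors == 1:
        pattern, phi = L, np.eye(n_factors)
    elif rotation == "varimax":
        pattern, phi = _varimax(L), np.eye(n_factors)
    elif rotation == "promax":
        pattern, phi = _promax(_varimax(L), power=promax_power)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    # canonical order and sign: by explained variance, loading sums positive
    structure = pattern @ phi
    ev = np.einsum("ij,ij->j", pattern, structure) / R.shape[0]
    order = np.argsort(ev)[::-1]
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    ev = ev[order]
    signs = np.where(pattern.sum(axis=0) < 0, -1.0, 1.0)
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    return FactorSolution(
        loadings=pattern,
        factor_corr=phi,
        eigenvalues=eigenvalues,
        n_factors=n_factors,
        explained_variance=ev,
        uniquenesses=psi,
    )


def harman_scores(
    data: QuestionnaireData | np.ndarray | pd.DataFrame,
    solution: FactorSolution,
) -> np.ndarray:
    """Factor scores by Harman's idealized-variable method, z-scored per factor.

    Weights are the loadings normalised by the loading cross-products:
    W = Lambda (Lambda' Lambda)^{-1}; scores = Z W.
    """
    X = data.responses if isinstance(data, QuestionnaireData) else np.asarray(
        pd.DataFrame(data).to_numpy(), dtype=float
    )
    X = X.astype(float)
    if np.any(~np.isfinite(X)):
        raise ValueError("missing responses; impute before scoring")
    if X.shape[1] != solution.loadings.shape[0]:
        raise ValueError("item count mismatch between data and solution")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant item column; cannot standardise")
    Z = (X - X.mean(axis=0)) / sd
    L = solution.loadings
    W = L @ np.linalg.inv(L.T @ L)
    S = Z @ W
    return (S - S.mean(axis=0)) / S.std(axis=0, ddof=0)


def low_loading_filter(
    data: QuestionnaireData, solution: FactorSolution, cutoff: float = 0.4
) -> tuple[QuestionnaireData, np.ndarray]:
    """Drop items whose maximum absolute pattern loading is below ``cutoff``."""
    keep = np.max(np.abs(solution.loadings), axis=1) >= cutoff
    if not keep.any():
        raise ValueError("low-loading filter removed every item")
    idx = np.flatnonzero(keep)
    reduced = QuestionnaireData(
        responses=data.responses[:, idx],
        item_names=tuple(data.item_names[i] for i in idx),
        item_instrument=tuple(data.item_instrument[i] for i in idx),
    )
    return reduced, idx
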