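"""End-to-end synthetic studies with planted ground truth.

Latent psychiatric factor scores drive (a) RL parameters of simulated
bandit agents and (b) ordinal questionnaire responses through a blocked
loading matrix, so that every downstream estimator can be checked against
known truth.  The default battery mirrors a five-instrument, 154-item
layout: schizotypy 22 binary items, OCD 42 five-level items, depression 20
and anxiety 40 four-level items, impulsivity 30 four-level items.

Planted links follow the study design being emulated: the first factor
(CIT) is negatively coupled to the learning rate in both task arms, and
positively coupled to the choice-trace weight in the reward arm only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .bandit_env import ChoiceSession, Context, ProbabilitySchedule, generate_schedule
from .factors import QuestionnaireData
from .rl_models import RLParams, simulate_agent

__all__ = [
    "InstrumentBlock",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "questionnaire_from_factors",
    "scenario_library",
    "get_scenario",
    "DEFAULT_BLOCKS",
]

FACTORS = ("CIT", "AD", "IM")


@dataclass(frozen=True)
class InstrumentBlock:
    name: str
    n_items: int
    n_levels: int
    loadings: tuple[float, float, float]  # mean loading on (CIT, AD, IM)
    loading_jitter: float = 0.08


DEFAULT_BLOCKS: tuple[InstrumentBlock, ...] = (
    InstrumentBlock("schizotypy", 22, 2, (0.50, 0.10, 0.05)),
    InstrumentBlock("ocd", 42, 5, (0.65, 0.10, 0.05)),
    InstrumentBlock("depression", 20, 4, (0.15, 0.60, 0.05)),
    InstrumentBlock("anxiety", 40, 4, (0.15, 0.65, 0.05)),
    InstrumentBlock("impulsivity", 30, 4, (0.05, 0.05, 0.60)),
)


def _default_factor_cov() -> np.ndarray:
    # pairwise shared variance r^2 <= 0.15
    return np.array(
        [
            [1.00, 0.30, 0.35],
            [0.30, 1.00, 0.20],
            [0.35, 0.20, 1.00],
        ]
    )


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a two-arm synthetic study."""

    name: str = "custom"
    n_per_arm: int = 200
    n_trials: int = 500
    blocks: tuple[InstrumentBlock, ...] = DEFAULT_BLOCKS
    factor_cov: np.ndarray = field(default_factory=_default_factor_cov)
    model_id: str = "RL2b"
    # alpha_i = expit(alpha_intercept - alpha_cit_slope * CIT_i + noise)
    alpha_intercept: float = -0.4
    alpha_cit_slope: float = 0.8
    alpha_noise_sd: float = 0.3
    # gamma_i = gamma_intercept + gamma_cit_slope[arm] * CIT_i + noise
    gamma_intercept: float = -1.0
    gamma_cit_slope_reward: float = 0.5
    gamma_cit_slope_loss: float = 0.0
    gamma_noise_sd: float = 0.3
    log_beta_mean: float = np.log(5.0)
    log_beta_sd: float = 0.8
    alpha_f_range: tuple[float, float] = (0.02, 0.2)
    alpha_c_range: tuple[float, float] = (0.3, 0.7)
    miss_rate: float = 0.009
    schedule_bounds: tuple[float, float] = (0.1, 0.9)
    schedule_drift_sd: float = 0.1
    schedule_switch_rate: float = 0.04

    def __post_init__(self) -> None:
        cov = np.asarray(self.factor_cov, dtype=float)
        vals = np.linalg.eigvalsh(cov)
        if vals.min() < -1e-10:
            raise ValueError("factor covariance must be positive semidefinite")
        off = cov[~np.eye(3, dtype=bool)]
        if np.any(off**2 > 0.15 + 1e-12):
            raise ValueError("pairwise shared factor variance exceeds 0.15")
        object.__setattr__(self, "factor_cov", cov)

    @property
    def n_items(self) -> int:
        return sum(b.n_items for b in self.blocks)


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    schedule: ProbabilitySchedule
    sessions: dict[str, list[ChoiceSession]]  # keyed by arm ("reward"/"loss")
    questionnaire: QuestionnaireData
    ground_truth: pd.DataFrame  # one row per participant
    loading_matrix: np.ndarray  # P x 3 used for the questionnaire


def _build_loadings(
    blocks: tuple[InstrumentBlock, ...], rng: np.random.Generator
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...], list[np.ndarray]]:
    loadings, names, instruments, thresholds = [], [], [], []
    for b in blocks:
        for i in range(b.n_items):
            lam = np.array(b.loadings) + rng.uniform(
                -b.loading_jitter, b.loading_jitter, size=3
            )
            loadings.append(lam)
            names.append(f"{b.name}_{i + 1:03d}")
            instruments.append(b.name)
            # equal-mass ordinal bins on the latent scale
            cuts = stats.norm.ppf(np.linspace(0, 1, b.n_levels + 1)[1:-1])
            thresholds.append(cuts)
    return np.array(loadings), tuple(names), tuple(instruments), thresholds


def questionnaire_from_factors(
    scores: np.ndarray,
    loadings: np.ndarray,
    thresholds: list[np.ndarray],
    seed: int | np.random.Generator = 0,
    factor_corr: np.ndarray | None = None,
    item_names: tuple[str, ...] | None = None,
    item_instrument: tuple[str, ...] | None = None,
) -> QuestionnaireData:
    """Ordinal responses from a linear latent-factor model.

    Item latent value = Lambda f + e with unique variance 1 - communality
    (communality = lambda' Phi lambda); the ordinal level is the threshold
    bin of the latent value.
    """
    scores = np.asarray(scores, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape[0] != len(thresholds):
        raise ValueError("loadings rows must match item count")
    phi = np.eye(loadings.shape[1]) if factor_corr is None else np.asarray(factor_corr)
    communality = np.einsum("ij,jk,ik->i", loadings, phi, loadings)
    if np.any(communality >= 1.0):
        worst = int(np.argmax(communality))
        raise ValueError(f"item {worst} communality {communality[worst]:.3f} >= 1")
    for j, cuts in enumerate(thresholds):
        if len(cuts) < 1:
            raise ValueError(f"item {j} has no thresholds (single response bin)")
        if np.any(np.diff(cuts) <= 0):
            raise ValueError(f"item {j} thresholds are not strictly increasing")
    rng = np.random.default_rng(seed)
    n, p = scores.shape[0], loadings.shape[0]
    latent = scores @ loadings.T + rng.normal(
        0.0, np.sqrt(1.0 - communality), size=(n, p)
    )
    responses = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        responses[:, j] = np.searchsorted(thresholds[j], latent[:, j])
    if item_names is None:
        item_names = tuple(f"item_{j + 1:03d}" for j in range(p))
    if item_instrument is None:
        item_instrument = tuple("unknown" for _ in range(p))
    return QuestionnaireData(
        responses=responses, item_names=item_names, item_instrument=item_instrument
    )


def _draw_params(
    config: CohortConfig, cit: np.ndarray, arm: str, rng: np.random.Generator
) -> pd.DataFrame:
    n = cit.size
    alpha = expit(
        config.alpha_intercept
        - config.alpha_cit_slope * cit
        + rng.normal(0.0, config.alpha_noise_sd, n)
    )
    g_slope = (
        config.gamma_cit_slope_reward if arm == "reward" else config.gamma_cit_slope_loss
    )
    gamma = (
        config.gamma_intercept
        + g_slope * cit
        + rng.normal(0.0, config.gamma_noise_sd, n)
    )
    beta = np.exp(rng.normal(config.log_beta_mean, config.log_beta_sd, n))
    beta = np.clip(beta, 0.05, 25.0)
    alpha_f = rng.uniform(*config.alpha_f_range, n)
    alpha_c = rng.uniform(*config.alpha_c_range, n)
    # guard against links pushing parameters onto the fitting box edges
    at_edge = (alpha < 0.002) | (alpha > 0.998) | (np.abs(gamma) > 9.99)
    if at_edge.mean() > 0.01:
        raise ValueError(
            f"{at_edge.mean():.1%} of planted parameters sit at the box edges; "
            "rescale the link slopes or noise"
        )
    return pd.DataFrame(
        {"alpha": alpha, "beta": beta, "gamma": gamma, "alpha_F": alpha_f,
         "alpha_C": alpha_c}
    )


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(48.0, 11.6, n), 20, 69).round(0),
            "sex": rng.integers(1, 3, n),  # 1 male, 2 female
            "education": rng.integers(1, 8, n),
            "ses": rng.integers(1, 11, n),
        }
    )


def generate_cohort(config: CohortConfig, seed: int = 0) -> Cohort:
    """Generate sessions, questionnaires, and the ground-truth ledger.

    Bit-identical for the same config and seed.  Both arms share one
    probability schedule (the no-loss probabilities equal the reward
    probabilities).
    """
    root = np.random.SeedSequence([seed, 0xC0401])
    ss_sched, ss_load, ss_factors, ss_params, ss_quest, ss_cov, ss_sess = (
        root.spawn(7)
    )
    schedule = generate_schedule(
        n_trials=config.n_trials,
        bounds=config.schedule_bounds,
        drift_sd=config.schedule_drift_sd,
        switch_rate=config.schedule_switch_rate,
        seed=np.random.default_rng(ss_sched),
    )
    loadings, item_names, item_instruments, thresholds = _build_loadings(
        config.blocks, np.random.default_rng(ss_load)
    )

    n_total = 2 * config.n_per_arm
    fac_rng = np.random.default_rng(ss_factors)
    factor_scores = fac_rng.multivariate_normal(
        np.zeros(3), config.factor_cov, size=n_total, method="cholesky"
    )

    questionnaire = questionnaire_from_factors(
        factor_scores,
        loadings,
        thresholds,
        seed=np.random.default_rng(ss_quest),
        factor_corr=config.factor_cov,
        item_names=item_names,
        item_instrument=item_instruments,
    )

    par_rng = np.random.default_rng(ss_params)
    cov_frame = _draw_covariates(n_total, np.random.default_rng(ss_cov))
    truth_rows = []
    sessions: dict[str, list[ChoiceSession]] = {"reward": [], "loss": []}
    sess_seeds = np.random.default_rng(ss_sess).integers(0, 2**63, size=n_total)
    idx = 0
    for arm in ("reward", "loss"):
        arm_slice = slice(idx, idx + config.n_per_arm)
        cit = factor_scores[arm_slice, 0]
        params = _draw_params(config, cit, arm, par_rng)
        for row in range(config.n_per_arm):
            g = idx + row
            pid = f"{arm[0]}{row + 1:04d}"
            p = RLParams(**{k: float(params[k].iloc[row]) for k in params.columns})
            sessions[arm].append(
                simulate_agent(
                    schedule,
                    Context(arm),
                    config.model_id,
                    p,
                    miss_rate=config.miss_rate,
                    seed=int(sess_seeds[g]),
                    participant_id=pid,
                )
            )
            truth_rows.append(
                {
                    "participant_id": pid,
                    "task": 1.0 if arm == "reward" else -1.0,
                    "CIT": factor_scores[g, 0],
                    "AD": factor_scores[g, 1],
                    "IM": factor_scores[g, 2],
                    **{k: float(params[k].iloc[row]) for k in params.columns},
                    **{k: cov_frame[k].iloc[g] for k in cov_frame.columns},
                }
            )
        idx += config.n_per_arm
    ground_truth = pd.DataFrame(truth_rows)
    return Cohort(
        config=config,
        schedule=schedule,
        sessions=sessions,
        questionnaire=questionnaire,
        ground_truth=ground_truth,
        loading_matrix=loadings,
    )


def cohort_summaries(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Per-arm participant summary tables (ground-truth parameters plus
    correctness counts), ready for :mod:`transdx.dimension_stats`."""
    from .bandit_env import label_correct

    labeling = label_correct(cohort.schedule)
    out = {}
    for arm, code in (("reward", 1.0), ("loss", -1.0)):
        sub = cohort.ground_truth[cohort.ground_truth["task"] == code].copy()
        by_id = {s.participant_id: s for s in cohort.sessions[arm]}
        n_resp, n_corr = [], []
        for pid in sub["participant_id"]:
            s = by_id[pid]
            ok = s.choices[s.responded] == labeling.correct_option[s.responded]
            n_resp.append(int(s.responded.sum()))
            n_corr.append(int(ok.sum()))
        sub["n_responded"] = n_resp
        sub["n_correct"] = n_corr
        out[arm] = sub.reset_index(drop=True)
    return out


def scenario_library() -> dict[str, CohortConfig]:
    """Named study configurations for tests and the CLI."""
    scenarios = {
        "paper_like": CohortConfig(name="paper_like"),
        "null": CohortConfig(
            name="null",
            alpha_cit_slope=0.0,
            gamma_cit_slope_reward=0.0,
            gamma_cit_slope_loss=0.0,
        ),
        "strong_effects": CohortConfig(
            name="strong_effects",
            alpha_cit_slope=1.2,
            gamma_cit_slope_reward=0.8,
            alpha_noise_sd=0.15,
            gamma_noise_sd=0.15,
        ),
        "small_n_smoke": CohortConfig(
            name="small_n_smoke", n_per_arm=20, n_trials=100
        ),
    }
    return scenarios


def get_scenario(name: str) -> CohortConfig:
    scenarios = scenario_library()
    if name not in scenarios:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(scenarios))}"
        )
    return scenarios[name]
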