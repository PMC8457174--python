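"""Three-option bandit task: probability schedules, sessions, and performance.

A cohort arm shares a single :class:`ProbabilitySchedule` (every participant
faces the same per-trial success probabilities).  In the reward context the
schedule entries are reward probabilities and outcomes are coded {1, 0};
in the loss context they are no-loss probabilities and outcomes are coded
{0, -1}.  The "correct" option on a trial is the one with the highest
success probability (ties broken toward the lowest option index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a trial with no response

__all__ = [
    "MISSING",
    "Context",
    "ProbabilitySchedule",
    "ChoiceSession",
    "CorrectLabeling",
    "generate_schedule",
    "label_correct",
    "performance",
    "success_mask",
    "sessions_to_frame",
    "frame_to_sessions",
    "schedule_to_frame",
    "frame_to_schedule",
]


class Context(str, Enum):
    """Task framing: seek rewards or avoid losses."""

    REWARD = "reward"
    LOSS = "loss"


@dataclass(frozen=True)
class ProbabilitySchedule:
    """Per-trial success probability of each option, shared across an arm."""

    probs: np.ndarray  # (n_trials, n_options), entries in [0, 1]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] < 1 or probs.shape[1] < 2:
            raise ValueError("probs must be a (n_trials, n_options>=2) matrix")
        if np.any(probs < 0.0) or np.any(probs > 1.0) or not np.all(np.isfinite(probs)):
            raise ValueError("schedule probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", probs)

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    @property
    def n_options(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class ChoiceSession:
    """One participant's choices and outcomes in one task context.

    ``choices[t]`` is an option index or :data:`MISSING`.  ``outcomes[t]`` is
    1/0 in the reward context, 0/-1 in the loss context, and 0 (ignored)
    where the choice is missing.
    """

    participant_id: str
    context: Context
    choices: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        choices = np.asarray(self.choices, dtype=np.int64)
        outcomes = np.asarray(self.outcomes, dtype=float)
        if choices.shape != outcomes.shape or choices.ndim != 1:
            raise ValueError("choices and outcomes must be 1-D and equal length")
        context = Context(self.context)
        responded = choices != MISSING
        valid = {Context.REWARD: (0.0, 1.0), Context.LOSS: (-1.0, 0.0)}[context]
        if not np.all(np.isin(outcomes[responded], valid)):
            raise ValueError(f"outcomes inconsistent with {context.value} context coding")
        object.__setattr__(self, "choices", choices)
        object.__setattr__(self, "outcomes", outcomes)
        object.__setattr__(self, "context", context)

    @property
    def n_trials(self) -> int:
        return self.choices.shape[0]

    @property
    def responded(self) -> np.ndarray:
        return self.choices != MISSING

    @property
    def n_responded(self) -> int:
        return int(self.responded.sum())

    @property
    def miss_fraction(self) -> float:
        return 1.0 - self.n_responded / self.n_trials


@dataclass(frozen=True)
class CorrectLabeling:
    """Index of the best option per trial (argmax, lowest index on ties)."""

    correct_option: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.correct_option.shape[0]


def generate_schedule(
    n_trials: int = 500,
    n_options: int = 3,
    bounds: Sequence[float] = (0.2, 0.8),
    drift_sd: float = 0.02,
    switch_rate: float = 0.005,
    seed: int | np.random.Generator = 0,
    start: Sequence[float] | None = None,
) -> ProbabilitySchedule:
    """Generate a drifting probability schedule.

    Each option's probability follows a Gaussian random walk reflected at
    ``bounds``.  At rate ``switch_rate`` per trial, a "best-option switch"
    event swaps the currently highest probability with a uniformly chosen
    other option, so the identity of the correct option changes occasionally
    even when drift alone would not reorder the options.

    Deterministic for a fixed integer seed.
    """
    low, high = float(bounds[0]), float(bounds[1])
    if not (0.0 <= low < high <= 1.0):
        raise ValueError(f"invalid bounds {bounds!r}: need 0 <= low < high <= 1")
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if drift_sd < 0.0:
        raise ValueError("drift_sd must be non-negative")
    rng = np.random.default_rng(seed)

    if start is None:
        # spread starting values across the admissible band, best option random
        p = np.linspace(high, low, n_options)
        rng.shuffle(p)
    else:
        p = np.asarray(start, dtype=float).copy()
        if p.shape != (n_options,):
            raise ValueError("start must have one entry per option")
        if np.any(p < low) or np.any(p > high):
            raise ValueError("start values must lie within bounds")

    probs = np.empty((n_trials, n_options))
    probs[0] = p
    for t in range(1, n_trials):
        p = p + rng.normal(0.0, drift_sd, size=n_options) if drift_sd > 0 else p.copy()
        # reflect at the bounds (single reflection suffices for small steps)
        p = np.where(p < low, 2 * low - p, p)
        p = np.where(p > high, 2 * high - p, p)
        p = np.clip(p, low, high)
        if switch_rate > 0 and rng.random() < switch_rate:
            best = int(np.argmax(p))
            other = int(rng.integers(n_options - 1))
            other = other if other < best else other + 1
            p[[best, other]] = p[[other, best]]
        probs[t] = p
    return ProbabilitySchedule(probs=probs)


def label_correct(schedule: ProbabilitySchedule) -> CorrectLabeling:
    """Label the best option per trial; ties go to the lowest option index."""
    # np.argmax already returns the first (lowest-index) maximal entry
    return CorrectLabeling(correct_option=np.argmax(schedule.probs, axis=1))


def performance(
    session: ChoiceSession, labeling: CorrectLabeling
) -> tuple[float, np.ndarray]:
    """Proportion of correct choices over responded trials.

    Returns ``(proportion, is_correct)`` where ``is_correct`` is a boolean
    vector over responded trials only.  Missing trials are excluded from
    both numerator and denominator.
    """
    if session.n_trials != labeling.n_trials:
        raise ValueError("session and labeling differ in n_trials")
    responded = session.responded
    if not responded.any():
        raise ValueError("all trials missing: performance undefined")
    is_correct = session.choices[responded] == labeling.correct_option[responded]
    return float(is_correct.mean()), is_correct


def success_mask(session: ChoiceSession) -> np.ndarray:
    """Per-trial success indicator under the context-aware recode.

    Reward context: success = reward (outcome 1).  Loss context: success =
    no-loss (outcome 0), i.e. no-loss is treated as reward.  Entries at
    missing trials are False.
    """
    if session.context is Context.REWARD:
        ok = session.outcomes == 1.0
    else:
        ok = session.outcomes == 0.0
    return ok & session.responded


# ---------------------------------------------------------------------------
# CSV interchange


def sessions_to_frame(sessions: Sequence[ChoiceSession]) -> pd.DataFrame:
    """Long table with columns participant_id, trial (1-based), choice (1-3
    or NA), outcome, context."""
    parts = []
    for s in sessions:
        choice = s.choices.astype(float) + 1.0
        choice[s.choices == MISSING] = np.nan
        outcome = s.outcomes.astype(float)
        outcome[s.choices == MISSING] = np.nan
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "trial": np.arange(1, s.n_trials + 1),
                    "choice": choice,
                    "outcome": outcome,
                    "context": s.context.value,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_sessions(frame: pd.DataFrame) -> list[ChoiceSession]:
    sessions = []
    for pid, grp in frame.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial")
        context = Context(grp["context"].iloc[0])
        choices = grp["choice"].to_numpy(dtype=float)
        missing = ~np.isfinite(choices)
        ch = np.where(missing, MISSING, np.nan_to_num(choices) - 1).astype(np.int64)
        out = np.nan_to_num(grp["outcome"].to_numpy(dtype=float))
        out[missing] = 0.0
        sessions.append(
            ChoiceSession(participant_id=str(pid), context=context, choices=ch, outcomes=out)
        )
    return sessions


def schedule_to_frame(schedule: ProbabilitySchedule) -> pd.DataFrame:
    cols = {f"p{i + 1}": schedule.probs[:, i] for i in range(schedule.n_options)}
    return pd.DataFrame({"trial": np.arange(1, schedule.n_trials + 1), **cols})


def frame_to_schedule(frame: pd.DataFrame) -> ProbabilitySchedule:
    pcols = sorted(
        (c for c in frame.columns if c.startswith("p") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    probs = frame.sort_values("trial")[pcols].to_numpy(dtype=float)
    return ProbabilitySchedule(probs=probs)
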