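"""Eight reinforcement-learning models of three-option bandit behavior.

The model space crosses four learning families with an optional
value-forgetting mechanism ("b" variants):

====== ========================================================== ==========
id     mechanism                                                  parameters
====== ========================================================== ==========
RL1a   Q-learning with softmax choice                             alpha, beta
RL1b   + forgetting of unchosen values                            + alpha_F
RL2a   + additive choice trace in the softmax                     alpha, beta, gamma, alpha_C
RL2b   + forgetting                                               + alpha_F
RL3a   asymmetric learning rates for +/- prediction errors        alpha_pos, alpha_neg, beta
RL3b   + forgetting                                               + alpha_F
RL4a   Pearce-Hall associability-modulated learning rate          eta, kappa, beta
RL4b   + forgetting                                               + alpha_F
====== ========================================================== ==========

Choice rule: ``p(a) ∝ exp(beta * Q[a] + gamma * trace[a])`` with gamma
fixed at 0 outside the RL2 family.  Value update: ``Q[c] += alpha_eff *
(outcome - Q[c])`` with ``alpha_eff`` = alpha (RL1/RL2), alpha_pos or
alpha_neg by prediction-error sign (RL3), or kappa * associability (RL4,
with ``assoc <- eta*|delta| + (1-eta)*assoc`` applied after the value
update, assoc0 = 1).  Forgetting decays unchosen values toward the initial
value Q0 = 0: ``Q[u] <- (1 - alpha_F) * Q[u]``.  Choice trace: ``trace[a]
<- (1 - alpha_C) * trace[a] + alpha_C * 1{a = chosen}``.

Missed trials contribute no likelihood term and cause no state update.
Loss-context outcomes are used in their native {0, -1} coding by default;
``outcome_coding="success"`` recodes no-loss as 1 and loss as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numba import njit

from .bandit_env import MISSING, ChoiceSession, Context, ProbabilitySchedule

__all__ = [
    "MODELS",
    "RLParams",
    "AgentState",
    "choice_probabilities",
    "update_values",
    "update_trace",
    "negative_log_likelihood",
    "simulate_agent",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    family: int  # 1..4
    forget: bool
    param_names: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)


def _spec(model_id: str, family: int, forget: bool, names: tuple[str, ...]) -> ModelSpec:
    if forget:
        names = names + ("alpha_F",)
    return ModelSpec(model_id, family, forget, names)


MODELS: dict[str, ModelSpec] = {
    m.model_id: m
    for m in [
        _spec("RL1a", 1, False, ("alpha", "beta")),
        _spec("RL1b", 1, True, ("alpha", "beta")),
        _spec("RL2a", 2, False, ("alpha", "beta", "gamma", "alpha_C")),
        _spec("RL2b", 2, True, ("alpha", "beta", "gamma", "alpha_C")),
        _spec("RL3a", 3, False, ("alpha_pos", "alpha_neg", "beta")),
        _spec("RL3b", 3, True, ("alpha_pos", "alpha_neg", "beta")),
        _spec("RL4a", 4, False, ("eta", "kappa", "beta")),
        _spec("RL4b", 4, True, ("eta", "kappa", "beta")),
    ]
}


@dataclass(frozen=True)
class RLParams:
    """Full parameter record; each model reads its own subset."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    alpha_F: float = 0.0
    alpha_C: float = 0.0
    alpha_pos: float = 0.0
    alpha_neg: float = 0.0
    eta: float = 0.0
    kappa: float = 0.0

    def validate(self, model_id: str) -> None:
        spec = get_model(model_id)
        for name in spec.param_names:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} is not finite")
            if name == "beta":
                if v < 0:
                    raise ValueError("beta must be >= 0")
            elif name != "gamma" and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self, model_id: str | None = None) -> dict[str, float]:
        names = get_model(model_id).param_names if model_id else self.__dataclass_fields__
        return {n: float(getattr(self, n)) for n in names}


@dataclass(frozen=True)
class AgentState:
    """Learner state: option values, choice traces, and associability."""

    Q: np.ndarray = field(default_factory=lambda: np.zeros(3))
    trace: np.ndarray = field(default_factory=lambda: np.zeros(3))
    assoc: float = 1.0


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {', '.join(MODELS)}"
        ) from None


def choice_probabilities(state: AgentState, beta: float, gamma: float = 0.0) -> np.ndarray:
    """Softmax over ``beta*Q + gamma*trace``; floored away from exact 0/1."""
    logits = beta * state.Q + gamma * state.trace
    logits = logits - logits.max()
    p = np.exp(logits)
    p /= p.sum()
    p = np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    return p / p.sum()


def update_values(
    state: AgentState,
    chosen: int,
    outcome: float,
    params: RLParams,
    model_id: str,
) -> AgentState:
    """One trial's value update (and associability update for RL4)."""
    spec = get_model(model_id)
    if not 0 <= chosen < state.Q.shape[0]:
        raise ValueError(f"chosen option {chosen} out of range")
    Q = state.Q.copy()
    assoc = state.assoc
    delta = outcome - Q[chosen]
    if spec.family == 3:
        alpha_eff = params.alpha_pos if delta >= 0 else params.alpha_neg
    elif spec.family == 4:
        alpha_eff = params.kappa * assoc
    else:
        alpha_eff = params.alpha
    Q[chosen] += alpha_eff * delta
    if spec.forget:
        unchosen = np.arange(Q.shape[0]) != chosen
        Q[unchosen] *= 1.0 - params.alpha_F  # decay toward Q0 = 0
    if spec.family == 4:
        assoc = params.eta * abs(delta) + (1.0 - params.eta) * assoc
    return replace(state, Q=Q, assoc=assoc)


def update_trace(state: AgentState, chosen: int, alpha_C: float) -> AgentState:
    trace = (1.0 - alpha_C) * state.trace
    trace[chosen] += alpha_C
    return replace(state, trace=trace)


# ---------------------------------------------------------------------------
# Fast kernels.  The per-trial loop dominates fitting cost, so it is jitted.


@njit(cache=True)
def _nll_kernel(choices, outcomes, alpha, beta, gamma, alpha_f, alpha_c, family):
    n_opt = 3
    Q = np.zeros(n_opt)
    trace = np.zeros(n_opt)
    assoc = 1.0
    # family 3 packs (alpha_pos, alpha_neg) into (alpha, alpha_f slot is real)
    # -> handled by caller passing alpha=alpha_pos, gamma=alpha_neg for f3,
    #    alpha=eta, gamma=kappa for f4; see _pack_kernel_args.
    nll = 0.0
    for t in range(choices.shape[0]):
        c = choices[t]
        if c < 0:
            continue
        m = -1.0e300
        if family == 2:
            for a in range(n_opt):
                v = beta * Q[a] + gamma * trace[a]
                if v > m:
                    m = v
            denom = 0.0
            pc = 0.0
            for a in range(n_opt):
                e = math.exp(beta * Q[a] + gamma * trace[a] - m)
                denom += e
                if a == c:
                    pc = e
        else:
            for a in range(n_opt):
                v = beta * Q[a]
                if v > m:
                    m = v
            denom = 0.0
            pc = 0.0
            for a in range(n_opt):
                e = math.exp(beta * Q[a] - m)
                denom += e
                if a == c:
                    pc = e
        p = pc / denom
        if p < 1e-12:
            p = 1e-12
        nll -= math.log(p)
        delta = outcomes[t] - Q[c]
        if family == 3:
            a_eff = alpha if delta >= 0 else gamma  # alpha_pos / alpha_neg
        elif family == 4:
            a_eff = gamma * assoc  # kappa * assoc
        else:
            a_eff = alpha
        Q[c] += a_eff * delta
        if alpha_f > 0.0:
            for a in range(n_opt):
                if a != c:
                    Q[a] *= 1.0 - alpha_f
        if family == 4:
            assoc = alpha * abs(delta) + (1.0 - alpha) * assoc  # eta in alpha slot
        if family == 2:
            for a in range(n_opt):
                if a == c:
                    trace[a] = (1.0 - alpha_c) * trace[a] + alpha_c
                else:
                    trace[a] = (1.0 - alpha_c) * trace[a]
    return nll


@njit(cache=True)
def _simulate_kernel(
    probs, u_choice, u_outcome, u_miss, miss_rate,
    alpha, beta, gamma, alpha_f, alpha_c, family, success_value, fail_value,
):
    n_trials, n_opt = probs.shape
    choices = np.empty(n_trials, dtype=np.int64)
    outcomes = np.zeros(n_trials)
    Q = np.zeros(n_opt)
    trace = np.zeros(n_opt)
    assoc = 1.0
    for t in range(n_trials):
        if u_miss[t] < miss_rate:
            choices[t] = -1
            continue
        m = -1.0e300
        for a in range(n_opt):
            v = beta * Q[a] + (gamma * trace[a] if family == 2 else 0.0)
            if v > m:
                m = v
        denom = 0.0
        for a in range(n_opt):
            denom += math.exp(
                beta * Q[a] + (gamma * trace[a] if family == 2 else 0.0) - m
            )
        # inverse-CDF sample
        r = u_choice[t] * denom
        acc = 0.0
        c = n_opt - 1
        for a in range(n_opt):
            acc += math.exp(
                beta * Q[a] + (gamma * trace[a] if family == 2 else 0.0) - m
            )
            if r <= acc:
                c = a
                break
        choices[t] = c
        success = u_outcome[t] < probs[t, c]
        outcome = success_value if success else fail_value
        outcomes[t] = outcome
        delta = outcome - Q[c]
        if family == 3:
            a_eff = alpha if delta >= 0 else gamma
        elif family == 4:
            a_eff = gamma * assoc
        else:
            a_eff = alpha
        Q[c] += a_eff * delta
        if alpha_f > 0.0:
            for a in range(n_opt):
                if a != c:
                    Q[a] *= 1.0 - alpha_f
        if family == 4:
            assoc = alpha * abs(delta) + (1.0 - alpha) * assoc
        if family == 2:
            for a in range(n_opt):
                if a == c:
                    trace[a] = (1.0 - alpha_c) * trace[a] + alpha_c
                else:
                    trace[a] = (1.0 - alpha_c) * trace[a]
    return choices, outcomes


def _pack_kernel_args(params: RLParams, spec: ModelSpec) -> tuple[float, float, float, float, float]:
    """Map the named parameters onto the kernel's generic slots."""
    if spec.family == 3:
        a, g = params.alpha_pos, params.alpha_neg
    elif spec.family == 4:
        a, g = params.eta, params.kappa
    else:
        a, g = params.alpha, (params.gamma if spec.family == 2 else 0.0)
    alpha_f = params.alpha_F if spec.forget else 0.0
    return a, params.beta, g, alpha_f, params.alpha_C


def negative_log_likelihood(
    session: ChoiceSession,
    model_id: str,
    params: RLParams,
    outcome_coding: Literal["native", "success"] = "native",
) -> float:
    """Summed ``-ln p(choice_t)`` over responded trials.

    ``outcome_coding="success"`` recodes loss-context outcomes {0, -1} to
    {1, 0} before the value updates (no-loss treated as reward).
    """
    if session.n_responded == 0:
        raise ValueError("session has no responded trials")
    params.validate(model_id)
    spec = get_model(model_id)
    outcomes = session.outcomes
    if outcome_coding == "success" and session.context is Context.LOSS:
        outcomes = outcomes + 1.0
    elif outcome_coding not in ("native", "success"):
        raise ValueError(f"unknown outcome_coding {outcome_coding!r}")
    a, b, g, af, ac = _pack_kernel_args(params, spec)
    return float(
        _nll_kernel(session.choices, np.ascontiguousarray(outcomes, dtype=float),
                    a, b, g, af, ac, spec.family)
    )


def simulate_agent(
    schedule: ProbabilitySchedule,
    context: Context | str,
    model_id: str,
    params: RLParams,
    miss_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
) -> ChoiceSession:
    """Simulate a session of the given model on a schedule.

    Outcomes are Bernoulli in the schedule's per-trial success probability,
    coded {1, 0} in the reward context and {0, -1} in the loss context.
    Trials go missing independently with probability ``miss_rate``.
    """
    params.validate(model_id)
    spec = get_model(model_id)
    context = Context(context)
    if not 0.0 <= miss_rate < 1.0:
        raise ValueError("miss_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    u_choice = rng.random(n)
    u_outcome = rng.random(n)
    u_miss = rng.random(n)
    success_value, fail_value = (1.0, 0.0) if context is Context.REWARD else (0.0, -1.0)
    a, b, g, af, ac = _pack_kernel_args(params, spec)
    choices, outcomes = _simulate_kernel(
        np.ascontiguousarray(schedule.probs), u_choice, u_outcome, u_miss,
        miss_rate, a, b, g, af, ac, spec.family, success_value, fail_value,
    )
    return ChoiceSession(
        participant_id=participant_id, context=context, choices=choices, outcomes=outcomes
    )
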