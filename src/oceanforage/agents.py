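"""Parametric synthetic participants for the foraging / threat-checking task.

An agent chooses, whenever it is free to act, between foraging and checking
via a logistic policy on standardized threat (time pressure before predator
discovery, proximity after) and standardized reward rate; hiding is a
deterministic threshold on the same threat index.  Interresponse times (IRTs)
are log-normal with additive effects, in log-seconds, of switching, checking,
threat, reward rate, the switch-by-check interaction, and of having just
discovered a predator; realized IRTs are floored at the previous action's
duration (the fish cannot act before the previous action finishes).

Because z-scoring cannot be done online during generation, agents standardize
against fixed *anchor* moments (means/sds of threat and reward rate).  The
anchor defaults were calibrated once against the default cohort's realized
within-participant moments and frozen, so the generative coefficients live on
(approximately) the same scale the analysis estimates — which is what makes
parameter-recovery tests against the nominal group means meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .derived_vars import proximity, time_pressure
from .task_env import (
    PHASE_POST,
    PHASE_PRE,
    EnvState,
    TaskConfig,
    run_session,
)

__all__ = ["AgentParams", "CohortSpec", "Agent", "policy_logit", "decide_and_time", "generate_cohort"]


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic participant.

    ``beta_*`` are logit weights on standardized regressors; ``irt_*`` are
    log-second effects in the log-normal IRT model.  ``hide_threshold`` is the
    raw threat-index level that forces a hide.  ``*_anchor_*`` are the fixed
    standardization moments (see module docstring).
    """

    beta0: float = 0.1
    beta_tp: float = 1.4
    beta_rr: float = -0.3
    hide_threshold: float = 0.65
    irt_base: float = 0.6
    irt_switch: float = 0.25
    irt_check: float = 0.10
    irt_tp: float = 0.08
    irt_rr: float = -0.05
    irt_switch_x_check: float = -0.20
    irt_discovery: float = 0.30
    irt_sd: float = 0.25
    # standardization anchors (frozen calibration; see docs/methods.md)
    tp_anchor_mean: float = 0.27
    tp_anchor_sd: float = 0.16
    prox_anchor_mean: float = 0.52
    prox_anchor_sd: float = 0.16
    rr_anchor_mean: float = 47.0
    rr_anchor_sd: float = 25.0

    def __post_init__(self) -> None:
        if self.irt_sd <= 0:
            raise ValueError("irt_sd must be positive")
        for name in ("tp_anchor_sd", "prox_anchor_sd", "rr_anchor_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "AgentParams":
        return dataclasses.replace(self, **kw)


def _zero_sds() -> dict[str, float]:
    return {
        "beta0": 0.15,
        "beta_tp": 0.3,
        "beta_rr": 0.15,
        "hide_threshold": 0.05,
        "irt_base": 0.1,
        "irt_switch": 0.08,
        "irt_check": 0.05,
        "irt_tp": 0.04,
        "irt_rr": 0.03,
        "irt_switch_x_check": 0.06,
        "irt_discovery": 0.1,
        "irt_sd": 0.0,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Group-level specification of a synthetic cohort (defaults: N = 23)."""

    n_agents: int = 23
    param_means: AgentParams = field(default_factory=AgentParams)
    param_sds: dict[str, float] = field(default_factory=_zero_sds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")


def policy_logit(p: AgentParams, tp_std: float, rr_std: float) -> float:
    """Probability of checking (vs foraging) given standardized inputs."""
    if not (np.isfinite(tp_std) and np.isfinite(rr_std)):
        raise ValueError("policy inputs must be finite")
    x = p.beta0 + p.beta_tp * tp_std + p.beta_rr * rr_std
    # numerically stable logistic
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def _threat(p: AgentParams, state: EnvState) -> tuple[float, float]:
    """(raw threat index, standardized threat) at the agent's decision time."""
    if state.phase == PHASE_POST and state.obs_distance is not None:
        raw = proximity(
            state.obs_distance, state.predator_speed, state.t - state.obs_time
        )
        return raw, (raw - p.prox_anchor_mean) / p.prox_anchor_sd
    ref = state.last_check_onset if state.last_check_onset is not None else 0.0
    raw = time_pressure(max(0.0, state.t - ref), state.predator_speed)
    return raw, (raw - p.tp_anchor_mean) / p.tp_anchor_sd


def decide_and_time(
    p: AgentParams, state: EnvState, rng: np.random.Generator
) -> tuple[str, float]:
    """Sample the next action and its IRT given the current state.

    The hide rule preempts the logistic choice when the threat index reaches
    ``hide_threshold``.  The IRT is ``exp(linear predictor + noise)`` floored
    at the previous action's duration.
    """
    threat_raw, threat_std = _threat(p, state)
    rr_std = (state.reward_rate - p.rr_anchor_mean) / p.rr_anchor_sd
    if threat_raw >= p.hide_threshold:
        action = "hide"
    else:
        pc = policy_logit(p, threat_std, rr_std)
        action = "check" if rng.random() < pc else "forage"

    is_check = action == "check"
    is_switch = state.prev_action in ("forage", "check") and (
        (state.prev_action == "check") != is_check
    )
    lp = (
        p.irt_base
        + p.irt_switch * is_switch
        + p.irt_check * is_check
        + p.irt_tp * threat_std
        + p.irt_rr * rr_std
        + p.irt_switch_x_check * (is_switch and is_check)
        + p.irt_discovery * state.just_discovered
    )
    noise = p.irt_sd * rng.standard_normal() if p.irt_sd > 0 else 0.0
    irt = max(float(np.exp(lp + noise)), state.prev_duration)
    return action, irt


class Agent:
    """Stateful policy wrapper: round-robin sector search before discovery,
    targeted checks after, fresh sector cursor per block."""

    def __init__(self, params: AgentParams, n_sectors: int = 4):
        self.params = params
        self.n_sectors = n_sectors
        self._cursor = 0

    def __call__(self, state: EnvState, rng: np.random.Generator) -> tuple:
        action, irt = decide_and_time(self.params, state, rng)
        if action != "check":
            return action, irt
        if state.phase == PHASE_POST and state.obs_sector is not None:
            return ("check", int(state.obs_sector)), irt
        sector = self._cursor % self.n_sectors
        self._cursor += 1
        return ("check", sector), irt


def _draw_params(
    means: AgentParams, sds: dict[str, float], rng: np.random.Generator
) -> AgentParams:
    kw = {}
    for name, sd in sds.items():
        mu = getattr(means, name)
        val = mu + sd * rng.standard_normal() if sd > 0 else mu
        if name == "irt_sd":
            val = max(val, 1e-3)
        kw[name] = float(val)
    return means.replace(**kw)


def generate_cohort(
    spec: CohortSpec, cfg: TaskConfig
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate ``n_agents`` sessions; return (logs, ground-truth table).

    Per-agent parameters are Gaussian draws around ``param_means`` with sds
    ``param_sds``; the returned truth table holds one row per agent with the
    realized parameters (the recovery targets).
    """
    root = np.random.default_rng(spec.seed)
    param_rng, *session_rngs = root.spawn(spec.n_agents + 1)
    logs, truth_rows = [], []
    for pid in range(spec.n_agents):
        params = _draw_params(spec.param_means, spec.param_sds, param_rng)
        agent_factory = lambda params=params: Agent(params, cfg.n_sectors)
        log = run_session(
            cfg, agent_factory, session_rngs[pid], participant_id=pid
        )
        logs.append(log)
        row = {"participant_id": pid}
        row.update(dataclasses.asdict(params))
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return logs, truth
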