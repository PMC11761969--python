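"""Discrete-event simulator of the ocean foraging / threat-checking task.

The task: an animated fish forages for food in a 2D ocean while predators
approach, hidden, from one of ``n_sectors`` directions.  The player freely and
continuously chooses between *foraging* (collect the current reward rate),
*checking* a sector (which reveals the predator if it is there), and *hiding*
(safe from capture).  Reward rate follows a bounded random walk; the predator
appears after a random delay at the screen edge and closes on the center at a
type-specific speed.  A block ends when the predator reaches the center —
capturing the fish (−``capture_penalty`` points) unless it is hiding, in which
case the predator exits — or at ``block_duration``, whichever comes first.

Time is continuous; the simulator is event-driven (it advances from action
onset to action onset), so it is exact up to float precision rather than up to
an integration step.  All randomness flows from a single
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACTIONS",
    "EVENT_KINDS",
    "LOG_COLUMNS",
    "PHASE_PRE",
    "PHASE_POST",
    "TaskConfig",
    "EnvState",
    "step_environment",
    "apply_action",
    "run_block",
    "run_session",
    "predator_schedule",
    "session_time",
    "block_end_times",
    "validate_log",
    "always_forage_policy",
    "round_robin_policy",
    "scripted_policy",
]

ACTIONS = ("forage", "check", "hide", "return")
EVENT_KINDS = (
    "forage",
    "check",
    "hide",
    "return",
    "predator_discovered",
    "capture",
    "block_end",
)
PHASE_PRE = "pre_PD"
PHASE_POST = "post_PD"

#: Canonical column order of a SessionLog table.
LOG_COLUMNS = [
    "participant_id",
    "block_id",
    "predator_type",
    "t",
    "event_kind",
    "sector",
    "reward_rate_at_event",
    "phase_at_event",
    "energy_after",
]


def _default_speeds() -> dict[str, float]:
    # Uninterrupted arrival spans ~10-30 s after the appearance delay,
    # consistent with the reported first-hide times (fast ~12 s, slow ~19 s).
    return {"fast": 0.125, "medium": 0.071, "slow": 0.05}


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the task environment.

    Durations are in seconds, reward in arbitrary "units", predator speeds in
    screen-radii per second (the screen is normalized to unit radius).
    """

    n_blocks: int = 27
    block_duration: float = 90.0
    forage_duration: float = 1.5
    check_duration: float = 1.0
    hide_return_duration: float = 0.5
    reward_range: tuple[float, float] = (0.0, 90.0)
    reward_walk_sd: float = 3.0
    reward_step_dt: float = 0.5
    predator_speeds: dict[str, float] = field(default_factory=_default_speeds)
    predator_delay_range: tuple[float, float] = (2.0, 10.5)
    n_sectors: int = 4
    capture_penalty: float = 100.0
    block_gap: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.block_duration <= 0 or self.forage_duration <= 0:
            raise ValueError("block_duration and forage_duration must be positive")
        if self.check_duration <= 0 or self.hide_return_duration <= 0:
            raise ValueError("check and hide/return durations must be positive")
        if not (self.reward_range[0] < self.reward_range[1]):
            raise ValueError("reward_range must be an increasing pair")
        if not (0 <= self.predator_delay_range[0] <= self.predator_delay_range[1]):
            raise ValueError("predator_delay_range must be ordered and non-negative")
        if self.n_blocks < 1 or self.n_sectors < 1:
            raise ValueError("n_blocks and n_sectors must be >= 1")
        if len(self.predator_speeds) != 3:
            raise ValueError("exactly 3 predator speeds are required")
        speeds = list(self.predator_speeds.values())
        if not all(s > 0 for s in speeds) or len(set(speeds)) != 3:
            raise ValueError("predator speeds must be positive and strictly ordered")
        if self.reward_walk_sd < 0 or self.reward_step_dt <= 0:
            raise ValueError("invalid reward walk parameters")

    @property
    def slot_duration(self) -> float:
        """Length of one block slot on the session timeline (block + gap)."""
        return self.block_duration + self.block_gap

    @property
    def session_duration(self) -> float:
        return self.n_blocks * self.slot_duration

    def action_duration(self, action: str) -> float:
        if action == "forage":
            return self.forage_duration
        if action == "check":
            return self.check_duration
        if action in ("hide", "return"):
            return self.hide_return_duration
        raise ValueError(f"unknown action {action!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reward_range"] = list(self.reward_range)
        d["predator_delay_range"] = list(self.predator_delay_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "reward_range" in d:
            d["reward_range"] = tuple(d["reward_range"])
        if "predator_delay_range" in d:
            d["predator_delay_range"] = tuple(d["predator_delay_range"])
        return cls(**d)


@dataclass
class EnvState:
    """Instantaneous environment state within one block.

    Observable fields mirror what the player can know: the predator's sector
    and distance are populated only via the ``obs_*`` fields once a check has
    revealed it (``predator_sector``/``predator_distance`` hold the latent
    truth and are used by the simulator itself).
    """

    t: float
    reward_rate: float
    predator_present: bool
    predator_sector: int
    predator_distance: float
    fish_mode: str  # center | foraging | checking | hiding
    energy: float
    phase: str  # pre_PD | post_PD
    block_alive: bool
    captured: bool = False
    # block constants
    predator_type: str = "slow"
    predator_speed: float = 0.05
    predator_delay: float = 2.0
    # player-observable history summary
    last_check_onset: float | None = None
    obs_distance: float | None = None
    obs_time: float | None = None
    obs_sector: int | None = None
    just_discovered: bool = False
    prev_action: str | None = None
    prev_onset: float | None = None
    prev_duration: float = 0.0
    # internal reward-walk bookkeeping
    _walk_step: int = 0

    def copy(self) -> "EnvState":
        return replace(self)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect ``x`` into [lo, hi] (assumes overshoot < 2*(hi-lo))."""
    if x < lo:
        x = 2 * lo - x
    if x > hi:
        x = 2 * hi - x
    return min(max(x, lo), hi)


def _latent_distance(state: EnvState, t: float) -> float:
    """Latent predator distance at block time ``t`` (unit radius at appearance)."""
    if t < state.predator_delay:
        return 1.0
    return max(0.0, 1.0 - state.predator_speed * (t - state.predator_delay))


def arrival_time(delay: float, speed: float, initial_distance: float = 1.0) -> float:
    """Closed-form time at which an uninterrupted predator reaches the center."""
    return delay + initial_distance / speed


def step_environment(
    state: EnvState, dt: float, cfg: TaskConfig, rng: np.random.Generator
) -> EnvState:
    """Advance the environment by ``dt`` seconds (no player action).

    The reward walk advances by one reflected Gaussian increment per
    ``reward_step_dt`` boundary crossed; the predator appears after its delay
    and closes at its speed.  If the predator reaches the center within the
    step the block ends: a capture (with penalty) unless the fish is hiding,
    in which case the predator exits.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if state.phase not in (PHASE_PRE, PHASE_POST) or state.fish_mode not in (
        "center",
        "foraging",
        "checking",
        "hiding",
    ):
        raise ValueError("invalid state flags")
    new = state.copy()
    if dt == 0:
        return new
    t1 = state.t + dt

    # reward walk on its fixed grid
    lo, hi = cfg.reward_range
    n_steps = int(np.floor(t1 / cfg.reward_step_dt)) - state._walk_step
    if n_steps > 0:
        increments = rng.normal(0.0, cfg.reward_walk_sd, size=n_steps)
        v = new.reward_rate
        for eps in increments:
            v = _reflect(v + eps, lo, hi)
        new.reward_rate = v
        new._walk_step += n_steps

    # predator kinematics
    arr = arrival_time(state.predator_delay, state.predator_speed)
    new.predator_present = t1 >= state.predator_delay and state.block_alive
    new.predator_distance = _latent_distance(state, t1)
    if state.block_alive and arr <= t1:
        new.block_alive = False
        new.predator_present = False
        if new.fish_mode != "hiding":
            new.captured = True
            new.energy -= cfg.capture_penalty
    new.t = t1
    return new


def apply_action(
    state: EnvState, action: str | tuple[str, int], cfg: TaskConfig
) -> tuple[EnvState, dict]:
    """Apply a player action at the current state time; return (state, event row).

    ``action`` is the action name, or ``("check", sector)``.  The returned row
    is a SessionLog row dict (participant/block identity filled by the caller).
    Forage credits the reward rate at dive onset; a check of the predator's
    sector while it is present reveals it (first reveal flips the phase and
    the caller should also emit the ``predator_discovered`` row returned in
    the ``"discovery"`` key).
    """
    sector: int | None = None
    if isinstance(action, tuple):
        action, sector = action
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    if state.fish_mode == "hiding" and action != "return":
        raise ValueError("only 'return' is permitted while hiding")
    if action == "return" and state.fish_mode != "hiding":
        raise ValueError("'return' is only permitted while hiding")
    if action == "check":
        if sector is None:
            sector = 0
        if not (0 <= sector < cfg.n_sectors):
            raise ValueError(f"check sector {sector} outside [0, {cfg.n_sectors})")

    new = state.copy()
    new.just_discovered = False
    row = {
        "t": state.t,
        "event_kind": action,
        "sector": np.nan,
        "reward_rate_at_event": state.reward_rate,
        "phase_at_event": state.phase,
        "energy_after": state.energy,
    }
    duration = cfg.action_duration(action)
    discovery_row = None

    if action == "forage":
        new.fish_mode = "foraging"
        new.energy += state.reward_rate  # payout fixed at dive onset
        row["energy_after"] = new.energy
    elif action == "check":
        new.fish_mode = "checking"
        new.last_check_onset = state.t
        row["sector"] = float(sector)
        if state.predator_present and sector == state.predator_sector:
            new.obs_distance = state.predator_distance
            new.obs_time = state.t
            new.obs_sector = state.predator_sector
            if state.phase == PHASE_PRE:
                new.phase = PHASE_POST
                new.just_discovered = True
                discovery_row = {
                    "t": state.t,
                    "event_kind": "predator_discovered",
                    "sector": float(state.predator_sector),
                    "reward_rate_at_event": state.reward_rate,
                    "phase_at_event": PHASE_POST,
                    "energy_after": new.energy,
                }
    elif action == "hide":
        new.fish_mode = "hiding"
    elif action == "return":
        new.fish_mode = "center"

    new.prev_action = action
    new.prev_onset = state.t
    new.prev_duration = duration
    out = {"row": row, "discovery": discovery_row}
    return new, out


Policy = Callable[[EnvState, np.random.Generator], tuple]


def always_forage_policy(state: EnvState, rng: np.random.Generator) -> tuple:
    """Forage as fast as possible; never check or hide."""
    return "forage", max(state.prev_duration, 1e-9)


def round_robin_policy(n_sectors: int = 4) -> Policy:
    """Factory: check sectors 0,1,2,... in order, back-to-back."""
    counter = {"n": 0}

    def policy(state: EnvState, rng: np.random.Generator) -> tuple:
        k = counter["n"]
        counter["n"] = k + 1
        return ("check", k % n_sectors), max(state.prev_duration, 1e-9)

    return policy


def scripted_policy(script: Sequence[tuple]) -> Policy:
    """Policy replaying a fixed list of ``(action, onset_time)`` pairs."""
    script = list(script)

    def policy(state: EnvState, rng: np.random.Generator) -> tuple:
        if not script:
            return "forage", np.inf  # past the script: never act again
        action, onset = script.pop(0)
        irt = onset - (state.prev_onset if state.prev_onset is not None else 0.0)
        return action, irt

    return policy


def _init_state(
    cfg: TaskConfig, predator_type: str, rng: np.random.Generator
) -> EnvState:
    lo, hi = cfg.reward_range
    speed = cfg.predator_speeds[predator_type]
    return EnvState(
        t=0.0,
        reward_rate=float(rng.uniform(lo, hi)),
        predator_present=False,
        predator_sector=int(rng.integers(cfg.n_sectors)),
        predator_distance=1.0,
        fish_mode="center",
        energy=0.0,
        phase=PHASE_PRE,
        block_alive=True,
        predator_type=predator_type,
        predator_speed=speed,
        predator_delay=float(rng.uniform(*cfg.predator_delay_range)),
    )


def run_block(
    cfg: TaskConfig,
    policy: Policy,
    block_id: int,
    predator_type: str,
    rng: np.random.Generator,
    participant_id: int = 0,
    start_energy: float = 0.0,
) -> tuple[list[dict], float]:
    """Simulate one block; return (rows, final energy).

    The policy is called whenever the fish is free to act and returns
    ``(action, irt)`` where ``irt`` is the onset-to-onset interval from the
    previous action onset (from block start for the first action).  IRTs are
    floored at the previous action's duration.  The block terminates at
    capture, predator exit (fish hiding when the predator arrives), or
    ``block_duration``.
    """
    if predator_type not in cfg.predator_speeds:
        raise ValueError(f"unknown predator type {predator_type!r}")
    state = _init_state(cfg, predator_type, rng)
    state.energy = start_energy
    arr = arrival_time(state.predator_delay, state.predator_speed)
    end_t = min(cfg.block_duration, arr)
    rows: list[dict] = []

    def emit(row: dict) -> None:
        row = dict(row)
        row.update(
            participant_id=participant_id,
            block_id=block_id,
            predator_type=predator_type,
        )
        rows.append(row)

    while state.block_alive and state.fish_mode != "hiding":
        prev_onset = state.prev_onset if state.prev_onset is not None else 0.0
        t_free = prev_onset + state.prev_duration  # fish free to act
        if t_free >= end_t:
            break
        if t_free > state.t:
            state = step_environment(state, t_free - state.t, cfg, rng)
            if not state.block_alive:
                break
        try:
            action, irt = policy(state, rng)
        except TypeError as exc:  # policy returned a bare action
            raise ValueError(
                f"policy must return (action, irt); failed at t={state.t:.3f} "
                f"(phase {state.phase})"
            ) from exc
        onset = prev_onset + max(float(irt), state.prev_duration)
        if onset >= end_t:
            break
        state = step_environment(state, onset - state.t, cfg, rng)
        if not state.block_alive:
            break
        try:
            state, out = apply_action(state, action, cfg)
        except ValueError as exc:
            raise ValueError(
                f"invalid action {action!r} at t={state.t:.3f} "
                f"(fish_mode={state.fish_mode})"
            ) from exc
        act_name = out["row"]["event_kind"]
        if act_name == "forage" and onset + cfg.forage_duration > end_t:
            # dive interrupted by block end: no payout
            state.energy -= out["row"]["reward_rate_at_event"]
            out["row"]["energy_after"] = state.energy
        emit(out["row"])
        if out["discovery"] is not None:
            emit(out["discovery"])

    # terminal event
    state = step_environment(state, end_t - state.t, cfg, rng)
    terminal = {
        "t": round(end_t, 3),
        "event_kind": "capture" if state.captured else "block_end",
        "sector": np.nan,
        "reward_rate_at_event": state.reward_rate,
        "phase_at_event": state.phase,
        "energy_after": state.energy,
    }
    emit(terminal)
    for row in rows:
        row["t"] = round(row["t"], 3)  # 1 ms event-log resolution
    return rows, state.energy


def predator_schedule(cfg: TaskConfig, rng: np.random.Generator) -> list[str]:
    """Balanced, shuffled predator-type schedule over ``n_blocks`` blocks."""
    types = sorted(cfg.predator_speeds)
    base, extra = divmod(cfg.n_blocks, len(types))
    schedule = [t for t in types for _ in range(base)]
    schedule += list(rng.permutation(types)[:extra])
    rng.shuffle(schedule)  # type: ignore[arg-type]
    return [str(s) for s in schedule]


def run_session(
    cfg: TaskConfig,
    policy_factory: Callable[[], Policy] | Policy,
    rng: np.random.Generator | int | None = None,
    participant_id: int = 0,
) -> pd.DataFrame:
    """Simulate a full session (``n_blocks`` blocks) for one participant.

    ``policy_factory`` may be a policy or a zero-argument callable returning a
    fresh policy per block (for policies with per-block memory).  Returns a
    SessionLog :class:`pandas.DataFrame` in canonical column order.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    schedule = predator_schedule(cfg, rng)
    block_seeds = rng.spawn(cfg.n_blocks)
    all_rows: list[dict] = []
    energy = 0.0
    for b, (ptype, brng) in enumerate(zip(schedule, block_seeds)):
        policy = policy_factory() if _is_factory(policy_factory) else policy_factory
        rows, energy = run_block(
            cfg, policy, b, ptype, brng, participant_id=participant_id,
            start_energy=energy,
        )
        all_rows.extend(rows)
    log = pd.DataFrame(all_rows, columns=LOG_COLUMNS)
    return log


def _is_factory(obj) -> bool:
    return callable(obj) and not _looks_like_policy(obj)


def _looks_like_policy(obj) -> bool:
    import inspect

    try:
        sig = inspect.signature(obj)
    except (TypeError, ValueError):
        return True
    return len(sig.parameters) >= 2


def session_time(cfg: TaskConfig, block_id: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Absolute session time of within-block times (fixed slots of block+gap)."""
    return np.asarray(block_id) * cfg.slot_duration + np.asarray(t)


def block_end_times(log: pd.DataFrame) -> pd.Series:
    """Within-block end time of each block (terminal capture/block_end row)."""
    term = log[log["event_kind"].isin(["capture", "block_end"])]
    return term.set_index("block_id")["t"]


def validate_log(log: pd.DataFrame, cfg: TaskConfig | None = None) -> None:
    """Check SessionLog invariants; raise ``ValueError`` naming the first violation.

    Checks: known event kinds, time-ordering within blocks, at most one capture
    per block, post-PD rows preceded by a discovery row, and the energy ledger
    (final energy == sum of forage gains − captures × penalty when ``cfg`` is
    given).
    """
    unknown = set(log["event_kind"]) - set(EVENT_KINDS)
    if unknown:
        idx = log.index[log["event_kind"].isin(unknown)][0]
        raise ValueError(f"unknown event kind {log.loc[idx, 'event_kind']!r} at row {idx}")
    for (pid, bid), g in log.groupby(["participant_id", "block_id"], sort=False):
        t = g["t"].to_numpy()
        if np.any(np.diff(t) < 0):
            bad = g.index[1:][np.diff(t) < 0][0]
            raise ValueError(f"non-monotone time at row {bad} (participant {pid}, block {bid})")
        if int((g["event_kind"] == "capture").sum()) > 1:
            raise ValueError(f"multiple captures in block {bid} of participant {pid}")
        post = g["phase_at_event"] == PHASE_POST
        if post.any():
            first_post = g[post].iloc[0]
            if first_post["event_kind"] != "predator_discovered":
                raise ValueError(
                    f"post_PD rows without discovery in block {bid} of participant {pid}"
                )
    if cfg is not None:
        for pid, g in log.groupby("participant_id", sort=False):
            acts = g[g["event_kind"] == "forage"]
            # recompute gains: credited forages only (energy_after - previous energy)
            final = g["energy_after"].iloc[-1]
            gains = 0.0
            prev_energy = 0.0
            for _, row in g.iterrows():
                if row["event_kind"] == "forage":
                    gains += row["energy_after"] - prev_energy
                prev_energy = row["energy_after"]
            n_capture = int((g["event_kind"] == "capture").sum())
            expect = gains - n_capture * cfg.capture_penalty
            if abs(final - expect) > 1e-6:
                raise ValueError(
                    f"energy ledger violated for participant {pid}: "
                    f"final {final} != {expect}"
                )
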