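"""Derived environmental variables: time pressure, proximity, reward rate.

*Time pressure* is the pre-discovery threat index: the time elapsed since the
last check (or block start, whichever is later) multiplied by the predator's
speed.  It is a sawtooth — rising at slope ``speed`` between checks, reset to
zero by each check.  *Proximity* is the post-discovery threat index: one minus
the predator's last observed distance projected forward at its known speed,
so it lies in [0, 1] and is non-decreasing between observations.

Two reset conventions coexist and are both exposed:

- at the *event level* (used by the behavioral fits) the time pressure of an
  action is referenced to the last check onset *strictly before* it — a check
  does not zero out the very time pressure that motivated it;
- on the *TR grid* (used to align modulators with BOLD volumes) a grid point
  falling exactly on a check onset reads zero (reset applies at onset).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task_env import PHASE_POST, PHASE_PRE, TaskConfig, session_time

__all__ = [
    "time_pressure",
    "proximity",
    "event_series",
    "standardize",
    "sample_on_grid",
    "collinearity_report",
]

ACTION_EVENTS = ("forage", "check", "hide")


def time_pressure(t_since_reference, speed):
    """Pre-PD threat index: elapsed time since reference times predator speed."""
    t = np.asarray(t_since_reference, dtype=float)
    s = np.asarray(speed, dtype=float)
    if np.any(t < 0) or np.any(s < 0):
        raise ValueError("time_pressure inputs must be non-negative")
    out = t * s
    return float(out) if out.ndim == 0 else out


def proximity(last_observed_distance, speed, dt_since_observation):
    """Post-PD threat index in [0, 1]: 1 − projected predator distance."""
    d = np.asarray(last_observed_distance, dtype=float)
    dt = np.asarray(dt_since_observation, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("observed distance must lie in [0, 1]")
    if np.any(dt < 0):
        raise ValueError("dt since observation must be non-negative")
    out = 1.0 - np.maximum(0.0, d - np.asarray(speed, float) * dt)
    return float(out) if out.ndim == 0 else out


def event_series(log: pd.DataFrame, cfg: TaskConfig) -> pd.DataFrame:
    """Evaluate derived variables at every action onset of a SessionLog.

    Returns one row per forage/check/hide event with columns
    ``time_pressure`` (reset reference = last check onset strictly before the
    event), ``proximity`` (NaN pre-PD), ``threat`` (the phase-appropriate
    index), ``reward_rate``, ``phase``, sequence descriptors (``prev_kind``,
    ``is_switch``, ``after_discovery``) and the onset-to-onset ``irt`` (NaN
    for the first action of a block).
    """
    if log.empty:
        raise ValueError("empty SessionLog")
    recs = []
    for (pid, bid), g in log.groupby(["participant_id", "block_id"], sort=False):
        g = g.reset_index(drop=True)
        speed = cfg.predator_speeds[g.loc[0, "predator_type"]]
        term = g[g["event_kind"].isin(["capture", "block_end"])]
        # terminal row sits at the predator's arrival time for predator-ended
        # blocks, which pins the latent distance: d(t) = speed * (t_term - t).
        t_term = float(term["t"].iloc[0]) if not term.empty else np.nan
        disc = g[g["event_kind"] == "predator_discovered"]
        discovered = not disc.empty
        last_check = 0.0
        prev_kind, prev_onset = None, np.nan
        just_discovered = False
        for _, row in g.iterrows():
            kind = row["event_kind"]
            if kind == "predator_discovered":
                just_discovered = True
                continue
            if kind not in ACTION_EVENTS:
                continue
            t = row["t"]
            tp = time_pressure(max(0.0, t - last_check), speed)
            if row["phase_at_event"] == PHASE_POST and discovered:
                d = min(1.0, max(0.0, speed * (t_term - t)))
                prox = proximity(d, speed, 0.0)
            else:
                prox = np.nan
            threat = prox if row["phase_at_event"] == PHASE_POST else tp
            recs.append(
                {
                    "participant_id": pid,
                    "block_id": bid,
                    "predator_type": row["predator_type"],
                    "t": t,
                    "event_kind": kind,
                    "phase": row["phase_at_event"],
                    "time_pressure": tp,
                    "proximity": prox,
                    "threat": threat,
                    "reward_rate": row["reward_rate_at_event"],
                    "prev_kind": prev_kind,
                    "is_switch": int(
                        prev_kind in ("forage", "check")
                        and kind in ("forage", "check")
                        and kind != prev_kind
                    ),
                    "after_discovery": int(just_discovered),
                    "irt": t - prev_onset if np.isfinite(prev_onset) else np.nan,
                }
            )
            just_discovered = False
            if kind == "check":
                last_check = t
            prev_kind, prev_onset = kind, t
    return pd.DataFrame.from_records(recs)


def standardize(
    series: pd.DataFrame,
    columns: tuple[str, ...] = ("threat", "reward_rate"),
    by: tuple[str, ...] = ("participant_id", "phase"),
) -> pd.DataFrame:
    """Append within-group z-scored copies ``z_<col>`` (ddof=0).

    Zero-variance groups yield zeros (flagged via the ``z_<col>`` all-zero
    pattern rather than NaN so degenerate designs fail loudly downstream).
    """
    out = series.copy()
    for col in columns:
        g = out.groupby(list(by))[col]
        mu = g.transform("mean")
        sd = g.transform(lambda x: x.std(ddof=0))
        z = (out[col] - mu) / sd.replace(0.0, np.nan)
        out[f"z_{col}"] = z.fillna(0.0)
    return out


def sample_on_grid(
    log: pd.DataFrame, cfg: TaskConfig, grid: np.ndarray
) -> pd.DataFrame:
    """Evaluate derived variables for one participant on a session-time grid.

    ``grid`` holds absolute session times (seconds); blocks occupy fixed slots
    of ``block_duration + block_gap``.  Between a block's end and the next
    block's start (and after a check onset, per the reset-at-onset convention)
    time pressure reads zero; reward rate holds its last event value.  Returns
    a tidy frame with an ``active`` flag marking in-block samples.
    """
    if log.empty:
        raise ValueError("empty SessionLog")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (len(grid) > 1 and np.any(np.diff(grid) <= 0)):
        raise ValueError("grid must be increasing with positive spacing")
    pid = log["participant_id"].iloc[0]
    n = len(grid)
    tp = np.zeros(n)
    rr = np.full(n, np.nan)
    prox = np.full(n, np.nan)
    phase = np.array([PHASE_PRE] * n, dtype=object)
    active = np.zeros(n, dtype=bool)

    slot = cfg.slot_duration
    block_ids = np.floor(grid / slot).astype(int)
    t_in = grid - block_ids * slot

    last_rr = np.nan
    for bid, g in log.groupby("block_id", sort=True):
        g = g.sort_values("t", kind="stable").reset_index(drop=True)
        speed = cfg.predator_speeds[g.loc[0, "predator_type"]]
        term = g[g["event_kind"].isin(["capture", "block_end"])]
        end_t = term["t"].iloc[0] if not term.empty else cfg.block_duration
        checks = g.loc[g["event_kind"] == "check", "t"].to_numpy()
        disc = g[g["event_kind"] == "predator_discovered"]
        t_disc = disc["t"].iloc[0] if not disc.empty else np.inf
        ev_t = g["t"].to_numpy()
        ev_rr = g["reward_rate_at_event"].to_numpy()
        mask = block_ids == bid
        if not mask.any():
            last_rr = ev_rr[-1]
            continue
        tt = t_in[mask]
        in_block = tt <= end_t
        active[mask] = in_block
        # time pressure: sawtooth, reset at block start and at check onsets
        ref = np.zeros(len(tt))
        if len(checks):
            idx = np.searchsorted(checks, tt, side="right") - 1
            ref = np.where(idx >= 0, checks[np.clip(idx, 0, None)], 0.0)
        tp[mask] = np.where(in_block, (tt - ref) * speed, 0.0)
        # reward rate: last event value at or before t (block-local); grid
        # points before the block's first event read its first event value
        idx = np.searchsorted(ev_t, tt, side="right") - 1
        rr_vals = np.where(idx >= 0, ev_rr[np.clip(idx, 0, None)], ev_rr[0])
        rr[mask] = rr_vals
        # phase and proximity after discovery
        post = tt >= t_disc
        phase_block = np.where(post, PHASE_POST, PHASE_PRE)
        phase[mask] = phase_block
        if np.isfinite(t_disc) and t_disc != np.inf:
            d0 = max(0.0, 1.0 - speed * (t_disc - _block_delay(g, speed)))
            pvals = proximity(d0, speed, np.maximum(0.0, tt - t_disc))
            prox[mask] = np.where(post & in_block, pvals, np.nan)
        last_rr = ev_rr[-1]

    return pd.DataFrame(
        {
            "participant_id": pid,
            "t": grid,
            "block_id": block_ids,
            "time_pressure": tp,
            "proximity": prox,
            "reward_rate": rr,
            "phase": phase,
            "active": active,
        }
    )


def _block_delay(block_rows: pd.DataFrame, speed: float) -> float:
    """Back out the predator appearance delay from the terminal-row geometry.

    An uninterrupted predator arrives at ``delay + 1/speed``; the terminal row
    of a capture/exit block sits at that arrival time.
    """
    term = block_rows[block_rows["event_kind"].isin(["capture", "block_end"])]
    if term.empty:
        return np.inf
    return float(term["t"].iloc[0]) - 1.0 / speed


def collinearity_report(
    series: pd.DataFrame,
    variables: tuple[str, ...] = ("time_pressure", "reward_rate"),
    by: tuple[str, ...] = ("participant_id", "block_id"),
) -> pd.DataFrame:
    """Pairwise Pearson correlations per group plus a pooled row.

    Groups with fewer than 3 samples or a zero-variance variable report NaN
    and are flagged in the ``degenerate`` column.
    """
    rows = []
    pairs = [
        (a, b) for i, a in enumerate(variables) for b in variables[i + 1 :]
    ]

    def corr_block(df, label):
        rec = dict(zip(by, label if isinstance(label, tuple) else (label,)))
        rec["n"] = len(df)
        degenerate = len(df) < 3
        for a, b in pairs:
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rec[f"r_{a}_{b}"] = np.nan
                degenerate = True
            else:
                rec[f"r_{a}_{b}"] = float(np.corrcoef(x[ok], y[ok])[0, 1])
        rec["degenerate"] = degenerate
        return rec

    for label, g in series.groupby(list(by), sort=False):
        rows.append(corr_block(g, label))
    pooled = corr_block(series, tuple(["pooled"] * len(by)))
    rows.append(pooled)
    return pd.DataFrame(rows)
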