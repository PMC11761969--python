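"""Synthetic ROI BOLD timecourses with known ground truth.

A region's noiseless signal is a sum of hemodynamic responses to the session's
events.  Each event contributes an amplitude equal to its class's event beta
plus modulator betas times the (centered, standardized) modulator values at
the event; the amplitudes are convolved with a canonical double-gamma HRF and
sampled on the TR grid.  On top of that sit a linear drift, parametric
cardiac/respiratory sinusoids (aliased naturally by TR sampling), and AR(1)
Gaussian noise whose sd is set from the requested SNR (sd of the event-related
signal divided by noise sd).

Seed→target couplings for PPI testing are injected at the *neural* level:
extra event amplitudes ``gamma * seed_amplitude * psych * modulator`` are
added to the target before convolution, so the analysis module's BOLD-level
PPI approximation is tested against a stricter truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .task_env import TaskConfig, session_time

__all__ = [
    "HrfSpec",
    "RoiGroundTruth",
    "RoiTimecourse",
    "hrf_kernel",
    "hrf_value",
    "event_amplitudes",
    "synthesize_roi",
    "inject_ppi",
]

DEFAULT_TR = 1.962  # seconds


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma HRF (peak minus scaled undershoot), unit peak."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        if min(
            self.peak_delay,
            self.undershoot_delay,
            self.peak_dispersion,
            self.undershoot_dispersion,
            self.duration,
        ) <= 0:
            raise ValueError("HRF timing parameters must be positive")


def _raw_hrf(spec: HrfSpec, t: np.ndarray) -> np.ndarray:
    peak = stats.gamma.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    h = peak - spec.undershoot_ratio * under
    return np.where(t >= 0, h, 0.0)


from functools import lru_cache


@lru_cache(maxsize=32)
def _peak_value(spec: HrfSpec) -> float:
    tt = np.arange(0.0, spec.duration, 0.01)
    return float(_raw_hrf(spec, tt).max())


def hrf_kernel(spec: HrfSpec, dt: float) -> np.ndarray:
    """Sample the kernel on [0, duration) at step ``dt``; peak scaled to 1."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, spec.duration, dt)
    return _raw_hrf(spec, t) / _peak_value(spec)


def hrf_value(spec: HrfSpec, t: np.ndarray) -> np.ndarray:
    """Kernel evaluated at arbitrary (possibly negative) lags, unit peak."""
    t = np.asarray(t, float)
    out = _raw_hrf(spec, t) / _peak_value(spec)
    out = np.where((t < 0) | (t >= spec.duration), 0.0, out)
    return out


@dataclass(frozen=True)
class RoiGroundTruth:
    """Generative parameters of one ROI's timecourse.

    ``event_betas`` map event-class names to response amplitudes (units of
    HRF peak height); ``mod_betas`` map ``(class, modulator)`` pairs to
    parametric-modulation amplitudes per sd of the modulator.
    """

    roi: str
    event_betas: dict[str, float] = field(default_factory=dict)
    mod_betas: dict[tuple[str, str], float] = field(default_factory=dict)
    ar1: float = 0.3
    snr: float = 0.5
    noise_sd: float | None = None  # overrides snr when set
    cardiac_amp: float = 0.5
    cardiac_freq: float = 1.05  # Hz
    resp_amp: float = 0.5
    resp_freq: float = 0.3  # Hz
    drift_amp: float = 0.5


@dataclass
class RoiTimecourse:
    participant_id: int
    roi: str
    tr: float
    values: np.ndarray
    noiseless: np.ndarray | None = None

    @property
    def n_volumes(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr


def event_amplitudes(
    events: pd.DataFrame,
    truth: RoiGroundTruth,
    class_col: str = "glm_class",
    modulators: tuple[str, ...] = ("z_threat", "z_reward_rate"),
) -> pd.DataFrame:
    """Neural amplitude of every event under a ground-truth parameterization.

    ``events`` needs absolute onsets (``t_abs``), a class column, and the
    modulator columns (already standardized); modulator values are centered
    within class before scaling, matching the analysis convention.
    """
    ev = events.copy()
    amp = np.zeros(len(ev))
    mod_short = {"z_threat": "tp", "z_reward_rate": "rr"}
    for cls, beta in truth.event_betas.items():
        m = (ev[class_col] == cls).to_numpy()
        amp[m] += beta
        for mod in modulators:
            key = (cls, mod_short.get(mod, mod))
            if key in truth.mod_betas and m.any():
                vals = ev.loc[m, mod].to_numpy(float)
                amp[m] += truth.mod_betas[key] * (vals - vals.mean())
    ev["amplitude"] = amp
    return ev.reset_index(drop=True)


def _event_signal(
    onsets: np.ndarray, amps: np.ndarray, spec: HrfSpec, tr: float, n_volumes: int
) -> np.ndarray:
    """Continuous-time superposition of HRFs sampled exactly on the TR grid."""
    tv = np.arange(n_volumes) * tr
    live = np.asarray(amps) != 0.0
    onsets = np.asarray(onsets, float)[live]
    amps = np.asarray(amps, float)[live]
    if len(onsets) == 0:
        return np.zeros(n_volumes)
    lags = tv[:, None] - onsets[None, :]
    inside = (lags >= 0) & (lags < spec.duration)
    h = np.zeros_like(lags)
    h[inside] = _raw_hrf(spec, lags[inside]) / _peak_value(spec)
    return h @ amps


def synthesize_roi(
    events: pd.DataFrame,
    truth: RoiGroundTruth,
    spec: HrfSpec,
    n_volumes: int,
    rng: np.random.Generator,
    tr: float = DEFAULT_TR,
    participant_id: int = 0,
    precomputed_signal: np.ndarray | None = None,
) -> RoiTimecourse:
    """Generate one ROI timecourse from events with amplitudes.

    ``events`` must carry ``t_abs`` and ``amplitude`` columns (see
    :func:`event_amplitudes`).  Events whose response extends beyond the scan
    are truncated.  Pass ``precomputed_signal`` to reuse the noiseless event
    signal across noise realizations.
    """
    if precomputed_signal is not None:
        sig = precomputed_signal
    else:
        onsets = events["t_abs"].to_numpy(float)
        amps = events["amplitude"].to_numpy(float)
        scan_end = n_volumes * tr
        keep = onsets < scan_end
        sig = _event_signal(onsets[keep], amps[keep], spec, tr, n_volumes)
    tv = np.arange(n_volumes) * tr

    sig_sd = float(np.std(sig))
    if truth.noise_sd is not None:
        noise_sd = truth.noise_sd
    else:
        noise_sd = sig_sd / truth.snr if sig_sd > 0 else 1.0

    drift = truth.drift_amp * (tv - tv.mean()) / (tv[-1] - tv[0] if n_volumes > 1 else 1.0)
    phase_c, phase_r = rng.uniform(0, 2 * np.pi, size=2)
    confounds = truth.cardiac_amp * np.sin(
        2 * np.pi * truth.cardiac_freq * tv + phase_c
    ) + truth.resp_amp * np.sin(2 * np.pi * truth.resp_freq * tv + phase_r)

    white = rng.standard_normal(n_volumes)
    ar = sps.lfilter([1.0], [1.0, -truth.ar1], white)
    ar *= noise_sd * np.sqrt(1 - truth.ar1**2)  # stationary sd = noise_sd

    values = sig + drift + confounds + ar
    return RoiTimecourse(participant_id, truth.roi, tr, values, noiseless=sig)


def inject_ppi(
    target_events: pd.DataFrame,
    seed_events: pd.DataFrame,
    gamma: float,
    psych_col: str = "psych",
    modulator_col: str = "z_threat",
) -> pd.DataFrame:
    """Add neural-level three-way coupling events to a target's event table.

    For every event with a nonzero psychological code the target gains an
    extra amplitude ``gamma * seed_amplitude * psych * modulator`` (modulator
    centered over the coupled events).  With ``gamma=0`` the target events are
    returned unchanged, so identical RNG streams give identical series.
    """
    if gamma == 0.0:
        return target_events
    # events sharing an onset (a discovery and its check) act as one neural unit
    seed = seed_events.groupby("t_abs")["amplitude"].sum()
    ev = target_events.copy()
    psych = ev.get(psych_col)
    if psych is None:
        raise ValueError(f"events lack a {psych_col!r} column")
    coupled = psych.to_numpy(float) != 0.0
    if not coupled.any():
        return ev
    mod = ev.loc[coupled, modulator_col].to_numpy(float)
    mod = mod - mod.mean()
    seed_amp = seed.reindex(ev.loc[coupled, "t_abs"]).to_numpy(float)
    if np.isnan(seed_amp).any():
        raise ValueError("seed and target event grids are misaligned")
    extra = gamma * seed_amp * psych.to_numpy(float)[coupled] * mod
    ev.loc[coupled, "amplitude"] = ev.loc[coupled, "amplitude"].to_numpy() + extra
    return ev
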