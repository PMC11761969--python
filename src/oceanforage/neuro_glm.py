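"""ROI-level fMRI analyses: switch-locked GLM with parametric modulators,
group factorial ANOVAs on betas, brain–behavior correlation, event-locked
epoching with leave-one-out peak tests, and PPI regressions.

The event-related GLM time-locks delta regressors to behavioral events
(switches to checking, switches to foraging, repeats, predator discovery,
hides), adds parametric modulator columns (delta times the mean-centered
standardized threat / reward-rate value), convolves everything with a
double-gamma HRF on an oversampled grid, resamples to the TR grid and
high-pass filters with a discrete-cosine basis (100 s cutoff).  Fits are
ordinary least squares, optionally prewhitened with a single-pass AR(1)
Cochrane–Orcutt step.

PPI regressions follow the standard BOLD-level approximation: the seed's
filtered, mean-centered BOLD series is multiplied with *convolved*
psychological terms (the psychological sticks — and their neural-level
product with the modulator — are convolved before the product is formed).
Group inference on each term is a one-sample t over participants, reported as
a Z via the normal quantile of its p value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bold_sim import DEFAULT_TR, HrfSpec, RoiTimecourse, hrf_kernel
from .derived_vars import event_series, standardize
from .task_env import PHASE_POST, PHASE_PRE, TaskConfig, session_time

__all__ = [
    "DesignSpec",
    "DesignMatrix",
    "GlmFit",
    "EpochSet",
    "glm_events",
    "assign_psych",
    "build_design",
    "dct_basis",
    "fit_glm",
    "group_beta_anova",
    "brain_behavior_corr",
    "epoch_timecourses",
    "loo_peak_test",
    "ppi_regression",
    "ppi_group",
    "ppi_factorial",
]

EVENT_CLASSES = (
    "check_switch",
    "forage_switch",
    "check_repeat",
    "forage_repeat",
    "discovery",
    "hide",
)


def glm_events(
    log: pd.DataFrame, cfg: TaskConfig, phase: str | None = "pre"
) -> pd.DataFrame:
    """Event table for GLM construction: absolute onsets, event class,
    standardized modulators.

    Actions are classed by type and whether they switch from the previous
    action; ``discovery`` and ``hide`` are their own classes.  When ``phase``
    is given, forage/check classes are restricted to that phase while
    discovery and hide events are kept regardless (nuisance coverage).
    """
    ev = standardize(event_series(log, cfg))
    kind = ev["event_kind"]
    cls = np.where(
        kind == "hide",
        "hide",
        np.where(
            ev["is_switch"].astype(bool),
            kind.astype(str) + "_switch",
            kind.astype(str) + "_repeat",
        ),
    )
    ev = ev.assign(glm_class=cls)
    disc = log[log["event_kind"] == "predator_discovered"]
    if not disc.empty:
        drows = pd.DataFrame(
            {
                "participant_id": disc["participant_id"].to_numpy(),
                "block_id": disc["block_id"].to_numpy(),
                "t": disc["t"].to_numpy(),
                "event_kind": "predator_discovered",
                "phase": disc["phase_at_event"].to_numpy(),
                "z_threat": 0.0,
                "z_reward_rate": 0.0,
                "glm_class": "discovery",
            }
        )
        ev = pd.concat([ev, drows], ignore_index=True)
    if phase is not None:
        want = {"pre": PHASE_PRE, "post": PHASE_POST}[phase]
        action_cls = ev["glm_class"].str.startswith(("check", "forage"))
        ev = ev[~action_cls | (ev["phase"] == want)]
    ev = ev.copy()
    ev["t_abs"] = session_time(cfg, ev["block_id"].to_numpy(), ev["t"].to_numpy())
    return ev.sort_values("t_abs", kind="stable").reset_index(drop=True)


def assign_psych(
    events: pd.DataFrame,
    positive: tuple[str, ...] = ("check_switch", "check_repeat"),
    negative: tuple[str, ...] = ("forage_switch", "forage_repeat"),
) -> pd.DataFrame:
    """Add a ±1/0 psychological-contrast column over event classes."""
    ev = events.copy()
    ev["psych"] = np.where(
        ev["glm_class"].isin(positive),
        1.0,
        np.where(ev["glm_class"].isin(negative), -1.0, 0.0),
    )
    return ev


@dataclass(frozen=True)
class DesignSpec:
    """Regressor recipe for the switch-locked GLM."""

    event_classes: tuple[str, ...] = EVENT_CLASSES
    modulated: dict = field(
        default_factory=lambda: {
            "check_switch": ("z_threat", "z_reward_rate"),
            "forage_switch": ("z_threat", "z_reward_rate"),
        }
    )
    hrf: HrfSpec = field(default_factory=HrfSpec)
    highpass_cutoff: float | None = 100.0
    oversample: int = 8
    confound_freqs: tuple[float, ...] = (1.05, 0.3)
    include_confounds: bool = True
    drift: bool = True


@dataclass
class DesignMatrix:
    """Named, HRF-convolved, high-pass-filtered design for one participant."""

    X: pd.DataFrame
    convolved: dict[str, bool]
    basis: np.ndarray  # orthonormal DCT columns projected out (incl. constant)
    tr: float
    spec: DesignSpec
    omitted_classes: tuple[str, ...] = ()

    @property
    def names(self) -> list[str]:
        return list(self.X.columns)

    def filter(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, float)
        return y - self.basis @ (self.basis.T @ y)


def dct_basis(n_volumes: int, tr: float, cutoff: float | None) -> np.ndarray:
    """Orthonormal DCT-II columns with period above ``cutoff`` (plus constant).

    ``cutoff=None`` disables filtering entirely (an empty basis)."""
    if cutoff is None:
        return np.zeros((n_volumes, 0))
    total = n_volumes * tr
    k_max = int(np.floor(2.0 * total / cutoff))
    n = np.arange(n_volumes)
    cols = [np.full(n_volumes, 1.0 / np.sqrt(n_volumes))]
    for k in range(1, max(k_max, 1)):
        cols.append(np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * n + 1) * k / (2 * n_volumes)))
    return np.column_stack(cols)


def _convolve_sticks(
    onsets: np.ndarray,
    amps: np.ndarray,
    kernel: np.ndarray,
    dt: float,
    n_fine: int,
    oversample: int,
) -> np.ndarray:
    sticks = np.zeros(n_fine)
    idx = np.round(onsets / dt).astype(int)
    ok = (idx >= 0) & (idx < n_fine)
    np.add.at(sticks, idx[ok], amps[ok])
    conv = np.convolve(sticks, kernel)[:n_fine]
    return conv[::oversample]


def build_design(
    events: pd.DataFrame,
    tr: float,
    n_volumes: int,
    spec: DesignSpec | None = None,
) -> DesignMatrix:
    """Build the switch-locked design matrix from a :func:`glm_events` table.

    Each present event class gets a delta regressor; modulated classes get
    additional delta-times-centered-modulator columns.  All task columns are
    convolved on a ``tr/oversample`` grid, resampled to the TR grid, and
    DCT-high-pass filtered.  Confound columns (sin/cos pairs at the
    physiological frequencies, linear drift) and the intercept are appended
    centered but unfiltered.  Event classes with zero events are recorded in
    ``omitted_classes``.
    """
    spec = spec or DesignSpec()
    dt = tr / spec.oversample
    n_fine = n_volumes * spec.oversample
    kernel = hrf_kernel(spec.hrf, dt)
    basis = dct_basis(n_volumes, tr, spec.highpass_cutoff)

    cols: dict[str, np.ndarray] = {}
    convolved: dict[str, bool] = {}
    omitted = []
    scan_end = n_volumes * tr
    for cls in spec.event_classes:
        sub = events[(events["glm_class"] == cls) & (events["t_abs"] < scan_end)]
        if sub.empty:
            omitted.append(cls)
            continue
        onsets = sub["t_abs"].to_numpy(float)
        col = _convolve_sticks(
            onsets, np.ones(len(sub)), kernel, dt, n_fine, spec.oversample
        )
        cols[cls] = col
        convolved[cls] = True
        for mod in spec.modulated.get(cls, ()):
            raw = sub[mod].to_numpy(float)
            if np.std(raw) <= 1e-12 * (1.0 + np.abs(raw).max()):
                omitted.append(f"{cls}_x_{mod}")  # constant modulator
                continue
            vals = raw - raw.mean()
            name = f"{cls}_x_{mod}"
            cols[name] = _convolve_sticks(
                onsets, vals, kernel, dt, n_fine, spec.oversample
            )
            convolved[name] = True

    # high-pass filter the task columns
    for name in list(cols):
        cols[name] = cols[name] - basis @ (basis.T @ cols[name])

    tv = np.arange(n_volumes) * tr
    if spec.drift:
        drift = tv - tv.mean()
        cols["drift"] = drift / np.abs(drift).max()
        convolved["drift"] = False
    if spec.include_confounds:
        for f in spec.confound_freqs:
            s = np.sin(2 * np.pi * f * tv)
            c = np.cos(2 * np.pi * f * tv)
            cols[f"sin_{f:g}Hz"] = s - s.mean()
            cols[f"cos_{f:g}Hz"] = c - c.mean()
            convolved[f"sin_{f:g}Hz"] = convolved[f"cos_{f:g}Hz"] = False
    cols["const"] = np.ones(n_volumes)
    convolved["const"] = False

    X = pd.DataFrame(cols)
    if X.columns.duplicated().any():
        dupes = X.columns[X.columns.duplicated()].tolist()
        raise ValueError(f"duplicated design columns: {dupes}")
    return DesignMatrix(X, convolved, basis, tr, spec, tuple(omitted))


@dataclass
class GlmFit:
    betas: pd.Series
    se: pd.Series
    tvalues: pd.Series
    resid_var: float
    df: int
    ar1: float | None = None
    residuals: np.ndarray | None = None


def _ols(M: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    df = len(y) - M.shape[1]
    sigma2 = float(resid @ resid) / max(df, 1)
    cov = sigma2 * np.linalg.pinv(M.T @ M)
    return beta, resid, sigma2, df


def fit_glm(
    y: np.ndarray | RoiTimecourse,
    X: DesignMatrix,
    prewhiten: bool = False,
) -> GlmFit:
    """OLS fit of a (high-pass-filtered) timecourse on a design matrix.

    With ``prewhiten`` an AR(1) coefficient is estimated from the OLS
    residuals and a single Cochrane–Orcutt transform is applied before
    refitting.  Rank-deficient designs are rejected with the offending
    columns named.
    """
    if isinstance(y, RoiTimecourse):
        y = y.values
    y = X.filter(np.asarray(y, float))
    M = X.X.to_numpy(float)
    if len(y) < M.shape[1] + 2:
        raise ValueError("need at least n_columns + 2 volumes")
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError(
            "rank-deficient design; offending columns: " + ", ".join(_collinear(X.X))
        )
    beta, resid, sigma2, df = _ols(M, y)
    rho = None
    if prewhiten:
        rho = float(resid[1:] @ resid[:-1] / (resid @ resid))
        yw = np.empty_like(y)
        Mw = np.empty_like(M)
        yw[0] = y[0] * np.sqrt(1 - rho**2)
        Mw[0] = M[0] * np.sqrt(1 - rho**2)
        yw[1:] = y[1:] - rho * y[:-1]
        Mw[1:] = M[1:] - rho * M[:-1]
        beta, resid, sigma2, df = _ols(Mw, yw)
        M = Mw
    cov = sigma2 * np.linalg.pinv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    names = X.names
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.nan)
    return GlmFit(
        pd.Series(beta, index=names),
        pd.Series(se, index=names),
        pd.Series(tvals, index=names),
        sigma2,
        df,
        ar1=rho,
        residuals=resid,
    )


def _collinear(X: pd.DataFrame) -> list[str]:
    M = X.to_numpy(float)
    sd = M.std(axis=0)
    names = list(X.columns)
    bad = [n for n, s in zip(names, sd) if s == 0 and n != "const"]
    Z = (M - M.mean(0)) / np.where(sd > 0, sd, 1.0)
    C = np.abs(Z.T @ Z) / len(M)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if sd[i] > 0 and sd[j] > 0 and C[i, j] > 1 - 1e-10:
                bad += [names[i], names[j]]
    return sorted(set(bad)) or ["<unidentified>"]


def group_beta_anova(betas: pd.DataFrame, formula: str | None = None) -> pd.DataFrame:
    """Factorial ANOVA on participant-level betas.

    ``betas`` is a long table with a ``beta`` column and categorical factor
    columns (e.g. ``roi``, ``switch_type``, ``feature``); participants are
    the replicates.  The default model crosses all factor columns fully.
    Missing cells are rejected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    factors = [c for c in betas.columns if c not in ("beta", "participant_id")]
    counts = betas.groupby(factors, observed=True).size()
    expected = int(np.prod([betas[f].nunique() for f in factors]))
    if len(counts) < expected or (counts == 0).any():
        raise ValueError("incomplete factorial table (missing cells)")
    if formula is None:
        formula = "beta ~ " + " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=betas).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return table


def brain_behavior_corr(
    betas: np.ndarray, behavior: np.ndarray, n_tests: int = 1
) -> dict:
    """Pearson correlation of per-participant betas with a behavioral index,
    Bonferroni-corrected across ``n_tests`` regions."""
    x = np.asarray(betas, float)
    y = np.asarray(behavior, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "p": np.nan, "p_bonferroni": np.nan, "n": len(x), "undefined": True}
    r, p = stats.pearsonr(x, y)
    return {
        "r": float(r),
        "p": float(p),
        "p_bonferroni": float(min(1.0, p * n_tests)),
        "n": len(x),
        "undefined": False,
    }


@dataclass
class EpochSet:
    """Event-locked windows on a shared upsampled time axis."""

    data: np.ndarray  # (n_epochs, n_times)
    times: np.ndarray  # seconds relative to event onset
    n_dropped: int
    baseline: str = "onset"

    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)


def epoch_timecourses(
    y: np.ndarray | RoiTimecourse,
    event_times: np.ndarray,
    tr: float | None = None,
    window: tuple[float, float] = (-2.0, 12.0),
    upsample: int = 4,
) -> EpochSet:
    """Event-locked epochs by linear-interpolation upsampling.

    Each epoch is baselined by subtracting the (interpolated) value at the
    event onset.  Events whose window exceeds the scan are dropped, counted
    in ``n_dropped``.
    """
    if isinstance(y, RoiTimecourse):
        tr = y.tr
        y = y.values
    if tr is None:
        raise ValueError("tr required for array input")
    y = np.asarray(y, float)
    tv = np.arange(len(y)) * tr
    step = tr / upsample
    rel = np.arange(window[0], window[1] + step / 2, step)
    epochs, dropped = [], 0
    for t0 in np.asarray(event_times, float):
        tt = t0 + rel
        if tt[0] < tv[0] or tt[-1] > tv[-1]:
            dropped += 1
            continue
        vals = np.interp(tt, tv, y)
        vals = vals - np.interp(t0, tv, y)
        epochs.append(vals)
    if not epochs:
        raise ValueError("no complete windows inside the scan")
    return EpochSet(np.asarray(epochs), rel, dropped)


def loo_peak_test(
    traces: np.ndarray, times: np.ndarray, direction: str = "max"
) -> dict:
    """Leave-one-out peak statistics on participant-mean epoch traces.

    For each participant the peak latency is located on the group-mean trace
    *excluding* that participant; the participant's own value at that latency
    is then collected and the collection tested against zero with a
    two-sided Wilcoxon signed-rank test.
    """
    traces = np.asarray(traces, float)
    n_p, n_t = traces.shape
    if n_p < 6:
        raise ValueError("leave-one-out peak test requires >= 6 participants")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    total = traces.sum(axis=0)
    values = np.empty(n_p)
    latencies = np.empty(n_p)
    for i in range(n_p):
        loo = (total - traces[i]) / (n_p - 1)
        idx = int(np.argmax(loo) if direction == "max" else np.argmin(loo))
        values[i] = traces[i, idx]
        latencies[i] = times[idx]
    stat, p = stats.wilcoxon(values, alternative="two-sided", method="auto")
    return {
        "mean_peak_latency": float(latencies.mean()),
        "p": float(p),
        "statistic": float(stat),
        "values": values,
        "latencies": latencies,
    }


def _confound_columns(n_volumes: int, tr: float, freqs: tuple[float, ...]) -> dict:
    tv = np.arange(n_volumes) * tr
    cols = {}
    for f in freqs:
        s, c = np.sin(2 * np.pi * f * tv), np.cos(2 * np.pi * f * tv)
        cols[f"sin_{f:g}Hz"] = s - s.mean()
        cols[f"cos_{f:g}Hz"] = c - c.mean()
    return cols


def ppi_regression(
    target: RoiTimecourse | np.ndarray,
    seed: RoiTimecourse | np.ndarray,
    events: pd.DataFrame,
    X_base: DesignMatrix | None = None,
    tr: float = DEFAULT_TR,
    hrf: HrfSpec | None = None,
    highpass_cutoff: float = 100.0,
    oversample: int = 8,
    modulator_col: str = "z_threat",
    confound_freqs: tuple[float, ...] = (1.05, 0.3),
) -> pd.DataFrame:
    """Three-way PPI regression of a target ROI on a seed ROI.

    ``events`` must carry ``t_abs``, a ±1/0 ``psych`` column (see
    :func:`assign_psych`) and the modulator column.  The model regresses the
    filtered target on the task design (``X_base``; built from the events
    when not supplied — covering the task-evoked signal is what keeps the
    product terms unbiased), the filtered mean-centered seed BOLD, convolved
    psychological terms (psych, modulator, their neural-level product), and
    the two- and three-way products of the seed with those terms.
    Psychological mains that are exact linear combinations of the task design
    (the psych contrast always is, when every event class has its own
    regressor) are dropped and recorded in the ``note`` column of the
    returned table.
    """
    if isinstance(target, RoiTimecourse):
        tr = target.tr
        target = target.values
    if isinstance(seed, RoiTimecourse):
        seed = seed.values
    target = np.asarray(target, float)
    seed = np.asarray(seed, float)
    if target.shape != seed.shape:
        raise ValueError("seed and target must share the volume grid")
    if np.allclose(target, seed):
        raise ValueError("seed and target are identical series")
    psych = events["psych"].to_numpy(float)
    coupled = psych != 0
    if not coupled.any() or len(np.unique(psych[coupled])) < 2:
        raise ValueError("psychological contrast is constant; PPI undefined")

    n_volumes = len(target)
    hrf = hrf or HrfSpec()
    if X_base is None:
        X_base = build_design(
            events,
            tr,
            n_volumes,
            DesignSpec(
                hrf=hrf,
                highpass_cutoff=highpass_cutoff,
                oversample=oversample,
                confound_freqs=confound_freqs,
            ),
        )
    dt = tr / oversample
    n_fine = n_volumes * oversample
    kernel = hrf_kernel(hrf, dt)
    basis = X_base.basis

    def hp(col: np.ndarray) -> np.ndarray:
        return col - basis @ (basis.T @ col)

    onsets = events.loc[coupled, "t_abs"].to_numpy(float)
    psy = psych[coupled]
    mod = events.loc[coupled, modulator_col].to_numpy(float)
    mod = mod - mod.mean()

    def conv(amps: np.ndarray) -> np.ndarray:
        return hp(_convolve_sticks(onsets, amps, kernel, dt, n_fine, oversample))

    y = hp(target)
    seed_f = hp(seed)
    seed_c = seed_f - seed_f.mean()
    P = conv(psy)
    M = conv(mod)
    PM = conv(psy * mod)

    base_cols = {name: X_base.X[name].to_numpy(float) for name in X_base.names}
    candidates = {
        "seed": seed_c,
        "psych": P,
        "modulator": M,
        "psych_x_modulator": PM,
        "seed_x_psych": _center(seed_c * P),
        "seed_x_modulator": _center(seed_c * M),
        "seed_x_psych_x_modulator": _center(seed_c * PM),
    }
    cols = dict(base_cols)
    dropped: list[str] = []
    for name, col in candidates.items():
        M_cur = np.column_stack(list(cols.values()))
        resid = col - M_cur @ np.linalg.lstsq(M_cur, col, rcond=None)[0]
        if np.sum(resid**2) <= 1e-10 * max(np.sum(col**2), 1e-300):
            if name.startswith("seed_x"):
                raise ValueError(
                    f"PPI term {name!r} is collinear with the base model "
                    "(degenerate psychological contrast?)"
                )
            dropped.append(name)
            continue
        cols[name] = col

    X = pd.DataFrame(cols)
    beta, resid, sigma2, df = _ols(X.to_numpy(float), y)
    cov = sigma2 * np.linalg.pinv(X.to_numpy(float).T @ X.to_numpy(float))
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.nan)
    out = pd.DataFrame({"term": X.columns, "estimate": beta, "se": se, "t": tvals})
    out["note"] = ""
    if dropped:
        out.attrs["dropped_mains"] = dropped
        out.loc[out.index[-1], "note"] = "dropped collinear mains: " + ",".join(dropped)
    return out


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def ppi_group(fits: list[pd.DataFrame], term: str) -> dict:
    """Group one-sample t over participants on a PPI term, reported as Z."""
    vals = np.array(
        [float(f.loc[f["term"] == term, "estimate"].iloc[0]) for f in fits]
    )
    if len(vals) < 2:
        raise ValueError("need >= 2 participants")
    t, p = stats.ttest_1samp(vals, 0.0)
    z = float(np.sign(t) * stats.norm.isf(p / 2))
    return {"term": term, "mean": float(vals.mean()), "t": float(t), "z": z, "p": float(p), "n": len(vals)}


def ppi_factorial(peaks: pd.DataFrame) -> dict:
    """Two-way ANOVA plus Tukey HSD on per-participant peak PPI values.

    ``peaks`` is a long table with columns ``participant_id``, ``cortical``,
    ``subcortical`` and ``peak`` covering a complete 2×2 design.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    cells = peaks.groupby(["cortical", "subcortical"]).size()
    if len(cells) < peaks["cortical"].nunique() * peaks["subcortical"].nunique():
        raise ValueError("incomplete 2x2 table of peak values")
    fit = smf.ols("peak ~ C(cortical) * C(subcortical)", data=peaks).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    tukey_cortical = pairwise_tukeyhsd(peaks["peak"], peaks["cortical"])
    tukey_subcortical = pairwise_tukeyhsd(peaks["peak"], peaks["subcortical"])
    cell_labels = peaks["cortical"].astype(str) + ":" + peaks["subcortical"].astype(str)
    tukey_cells = pairwise_tukeyhsd(peaks["peak"], cell_labels)
    return {
        "anova": anova,
        "tukey_cortical": _tukey_frame(tukey_cortical),
        "tukey_subcortical": _tukey_frame(tukey_subcortical),
        "tukey_cells": _tukey_frame(tukey_cells),
    }


def _tukey_frame(res) -> pd.DataFrame:
    return pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
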