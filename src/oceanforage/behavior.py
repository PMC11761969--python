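"""Behavioral statistics: check-vs-forage choice model, IRT models, action
proportions, first-event times, and two-stage group inference.

All inference is two-stage summary statistics: a per-participant fit (logistic
for choice, OLS for IRTs) followed by a two-tailed one-sample t test of the
per-participant estimates against zero, with a t-based 95% CI.  Logistic fits
use iteratively reweighted least squares with separation detection and no
regularization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .derived_vars import event_series, standardize
from .task_env import PHASE_POST, PHASE_PRE, TaskConfig

__all__ = [
    "ParticipantFit",
    "GroupResult",
    "logistic_irls",
    "fit_check_vs_forage",
    "fit_irt_model",
    "pre_switch_design",
    "action_proportions",
    "first_event_times",
    "group_onesample",
    "fit_cohort",
    "group_table",
]

PHASES = {"pre": PHASE_PRE, "post": PHASE_POST}


@dataclass
class ParticipantFit:
    participant_id: int
    model: str
    coef: pd.DataFrame | None  # columns: term, estimate, se
    n_events: int
    excluded: bool = False
    reason: str = ""
    notes: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        if self.excluded or self.coef is None:
            return np.nan
        row = self.coef[self.coef["term"] == term]
        return float(row["estimate"].iloc[0]) if len(row) else np.nan


@dataclass
class GroupResult:
    term: str
    mean: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    n: int


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Maximum-likelihood logistic regression by IRLS.

    Returns ``(beta, se, converged, separated)``.  Separation is flagged when
    the linear predictor diverges while classifying the data perfectly — the
    MLE does not exist in that case and the coefficients are meaningless.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    beta = np.zeros(k)
    converged = separated = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.maximum(p * (1 - p), 1e-12)
        if np.max(np.abs(eta)) > 30:
            preds = (eta > 0).astype(float)
            if np.all(preds == y):
                separated = True
                break
        z = eta + (y - p) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.maximum(p * (1 - p), 1e-12)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return beta, se, converged, separated


def _prepare_events(
    log_or_events: pd.DataFrame, cfg: TaskConfig | None
) -> pd.DataFrame:
    """Accept a raw SessionLog or a pre-computed event series."""
    if "threat" in log_or_events.columns:
        ev = log_or_events
    else:
        if cfg is None:
            raise ValueError("cfg required when passing a raw SessionLog")
        ev = event_series(log_or_events, cfg)
    if "z_threat" not in ev.columns:
        ev = standardize(ev)
    return ev


def fit_check_vs_forage(
    log: pd.DataFrame,
    cfg: TaskConfig | None = None,
    phase: str = "pre",
    min_checks: int = 10,
    min_forages: int = 10,
) -> ParticipantFit:
    """Per-participant logistic regression of check (=1) vs forage (=0) on
    standardized threat and reward rate at action onset.

    Hides are excluded from the contrast.  Participants with too few events
    of either class, or with a separated/degenerate design, are flagged as
    excluded and carry no coefficients.
    """
    ev = _prepare_events(log, cfg)
    pid = int(ev["participant_id"].iloc[0])
    d = ev[(ev["phase"] == PHASES[phase]) & ev["event_kind"].isin(["forage", "check"])]
    n_check = int((d["event_kind"] == "check").sum())
    n_forage = int((d["event_kind"] == "forage").sum())

    def excluded(reason: str) -> ParticipantFit:
        return ParticipantFit(pid, "check_vs_forage", None, len(d), True, reason)

    if n_check < min_checks:
        return excluded(f"not enough check actions ({n_check} < {min_checks})")
    if n_forage < min_forages:
        return excluded(f"not enough forage actions ({n_forage} < {min_forages})")

    terms = ["intercept", "z_threat", "z_rr"]
    cols = [np.ones(len(d)), d["z_threat"].to_numpy(), d["z_reward_rate"].to_numpy()]
    notes = []
    keep = [0]
    for j in (1, 2):
        if np.std(cols[j]) < 1e-12:
            notes.append(f"dropped constant regressor {terms[j]}")
        else:
            keep.append(j)
    X = np.column_stack([cols[j] for j in keep])
    y = (d["event_kind"] == "check").to_numpy(float)
    beta, se, converged, separated = logistic_irls(X, y)
    if separated or not converged:
        return excluded("perfect separation or non-convergence")
    coef = pd.DataFrame(
        {"term": [terms[j] for j in keep], "estimate": beta, "se": se}
    )
    fit = ParticipantFit(pid, "check_vs_forage", coef, len(d), notes=notes)
    return fit


def _irt_frame(ev: pd.DataFrame) -> pd.DataFrame:
    """Onset-to-onset IRTs between consecutive forage/check actions within a
    block; first-in-block (undefined) intervals are dropped."""
    d = ev[ev["event_kind"].isin(["forage", "check"])].copy()
    d = d.sort_values(["block_id", "t"], kind="stable")
    d["irt"] = d.groupby("block_id")["t"].diff()
    d = d[np.isfinite(d["irt"])]
    return d


def pre_switch_design(run_lengths: int) -> np.ndarray:
    """Design matrix for a forage run of given length ending in a check:
    intercept plus the negative distance (in actions) to the upcoming check."""
    k = int(run_lengths)
    return np.column_stack([np.ones(k), -np.arange(k, 0, -1, dtype=float)])


def fit_irt_model(
    log: pd.DataFrame,
    cfg: TaskConfig | None = None,
    spec: str = "main",
    phase: str = "pre",
    min_intervals: int = 10,
) -> ParticipantFit:
    """Per-participant linear model on standardized IRTs.

    ``spec='main'``: switch, check, standardized threat and reward rate, and
    the switch-by-check interaction.  ``spec='pre_switch_slope'``: within
    forage runs ending in a check, the negative distance (in actions) to the
    upcoming check.  ``spec='discovery'``: an indicator for the action
    immediately after predator discovery (phases pooled).
    """
    ev = _prepare_events(log, cfg)
    pid = int(ev["participant_id"].iloc[0])
    if spec not in ("main", "pre_switch_slope", "discovery"):
        raise ValueError(f"unknown IRT model spec {spec!r}")
    if spec == "discovery":
        d = _irt_frame(ev)
    else:
        d = _irt_frame(ev[ev["phase"] == PHASES[phase]])

    if spec == "main":
        terms = ["intercept", "switch", "check", "z_threat", "z_rr", "switch_x_check"]
        sw = d["is_switch"].to_numpy(float)
        ch = (d["event_kind"] == "check").to_numpy(float)
        X = np.column_stack(
            [np.ones(len(d)), sw, ch, d["z_threat"], d["z_reward_rate"], sw * ch]
        )
    elif spec == "discovery":
        terms = ["intercept", "after_discovery"]
        X = np.column_stack([np.ones(len(d)), d["after_discovery"].to_numpy(float)])
    else:  # pre_switch_slope
        rows, dist = [], []
        for _, g in d.groupby("block_id", sort=False):
            kinds = g["event_kind"].to_numpy()
            idx = g.index.to_numpy()
            run: list[int] = []
            for i, kind in enumerate(kinds):
                if kind == "forage":
                    run.append(i)
                else:  # check terminates the run
                    for j, r in enumerate(run):
                        rows.append(idx[r])
                        dist.append(-(len(run) - j))
                    run = []
        d = d.loc[rows]
        terms = ["intercept", "neg_distance_to_switch"]
        X = np.column_stack([np.ones(len(d)), np.asarray(dist, float)])

    if len(d) < min_intervals:
        return ParticipantFit(
            pid, f"irt_{spec}", None, len(d), True,
            f"too few qualifying intervals ({len(d)} < {min_intervals})",
        )
    y = d["irt"].to_numpy(float)
    y = (y - y.mean()) / y.std(ddof=0)
    # drop constant non-intercept columns (degenerate designs)
    keep = [0] + [j for j in range(1, X.shape[1]) if np.std(X[:, j]) > 1e-12]
    X = X[:, keep]
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = len(y) - X.shape[1]
    resid = y - X @ beta
    sigma2 = resid @ resid / max(dof, 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    coef = pd.DataFrame(
        {
            "term": [terms[j] for j in keep],
            "estimate": beta,
            "se": np.sqrt(np.diag(cov)),
        }
    )
    return ParticipantFit(pid, f"irt_{spec}", coef, len(d))


def action_proportions(
    log: pd.DataFrame, phase: str = "pre", cfg: TaskConfig | None = None
) -> dict[str, float]:
    """Percentages of forage/check/hide among actions in a phase (sum 100)."""
    if "event_kind" not in log.columns:
        raise ValueError("expected a SessionLog or event series")
    d = log[
        log["event_kind"].isin(["forage", "check", "hide"])
        & (log[_phase_col(log)] == PHASES[phase])
    ]
    if d.empty:
        raise ValueError(f"no actions in phase {phase!r}")
    counts = d["event_kind"].value_counts()
    total = counts.sum()
    return {
        kind: 100.0 * counts.get(kind, 0) / total for kind in ("forage", "check", "hide")
    }


def _phase_col(df: pd.DataFrame) -> str:
    return "phase_at_event" if "phase_at_event" in df.columns else "phase"


def first_event_times(
    logs: list[pd.DataFrame], event_kind: str, by_predator_type: bool = True
) -> pd.DataFrame:
    """Mean ± sd (across participants) of first-occurrence times per block.

    First occurrences are averaged within participant (over that type's
    blocks), then summarized across participants.  Types in which the event
    never occurs are reported with NaN and ``missing=True``.
    """
    per_participant = []
    types = set()
    for log in logs:
        pid = log["participant_id"].iloc[0]
        types.update(log["predator_type"].unique())
        ev = log[log["event_kind"] == event_kind]
        firsts = ev.groupby("block_id").first().reset_index()
        key = "predator_type" if by_predator_type else None
        if key:
            m = firsts.groupby(key)["t"].mean()
            for ptype, val in m.items():
                per_participant.append(
                    {"participant_id": pid, "predator_type": ptype, "mean_t": val}
                )
        else:
            per_participant.append(
                {"participant_id": pid, "predator_type": "all", "mean_t": firsts["t"].mean()}
            )
    pp = pd.DataFrame(per_participant)
    out = []
    groups = sorted(types) if by_predator_type else ["all"]
    for ptype in groups:
        vals = (
            pp.loc[pp["predator_type"] == ptype, "mean_t"]
            if not pp.empty
            else pd.Series(dtype=float)
        )
        out.append(
            {
                "predator_type": ptype,
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "n": len(vals),
                "missing": len(vals) == 0,
            }
        )
    return pd.DataFrame(out)


def group_onesample(fits: list[ParticipantFit], term: str) -> GroupResult:
    """Two-tailed one-sample t test of per-participant estimates against 0."""
    vals = np.array(
        [f.estimate(term) for f in fits if not f.excluded], dtype=float
    )
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 included participants")
    mean = vals.mean()
    t, p = stats.ttest_1samp(vals, 0.0)
    half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
    return GroupResult(term, mean, mean - half, mean + half, float(t), n - 1, float(p), n)


def fit_cohort(
    logs: list[pd.DataFrame],
    cfg: TaskConfig,
    model: str = "check_vs_forage",
    **kw,
) -> list[ParticipantFit]:
    """Apply a per-participant fit to every log of a cohort."""
    fitter = {
        "check_vs_forage": fit_check_vs_forage,
        "irt_main": lambda log, cfg, **k: fit_irt_model(log, cfg, spec="main", **k),
        "irt_pre_switch_slope": lambda log, cfg, **k: fit_irt_model(
            log, cfg, spec="pre_switch_slope", **k
        ),
        "irt_discovery": lambda log, cfg, **k: fit_irt_model(
            log, cfg, spec="discovery", **k
        ),
    }[model]
    return [fitter(log, cfg, **kw) for log in logs]


def group_table(fits: list[ParticipantFit]) -> pd.DataFrame:
    """GroupResult rows for every term appearing in the included fits."""
    terms: list[str] = []
    for f in fits:
        if not f.excluded and f.coef is not None:
            for t in f.coef["term"]:
                if t not in terms:
                    terms.append(t)
    rows = []
    for term in terms:
        r = group_onesample(fits, term)
        rows.append(vars(r))
    return pd.DataFrame(rows)
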