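"""File formats, run configuration, and the end-to-end pipeline.

All tables are TSV (UTF-8, "." decimal, header row mandatory); booleans are
0/1 and times are float seconds.  Readers validate headers and the
time-ordering invariants and report offending line numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, bold_sim, derived_vars, neuro_glm
from .agents import AgentParams, CohortSpec, generate_cohort
from .bold_sim import DEFAULT_TR, HrfSpec, RoiGroundTruth
from .task_env import EVENT_KINDS, LOG_COLUMNS, TaskConfig, validate_log

__all__ = [
    "RunConfig",
    "write_session_log",
    "read_session_log",
    "write_table",
    "read_table",
    "write_roi_timecourse",
    "read_roi_timecourses",
    "pipeline_run",
]

ROI_COLUMNS = ["participant_id", "roi", "volume_index", "t", "value"]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_session_log(log: pd.DataFrame, path: str | Path) -> Path:
    return write_table(log[LOG_COLUMNS], path)


def read_session_log(
    path: str | Path, chunksize: int | None = None
) -> pd.DataFrame:
    """Read and validate a SessionLog TSV.

    With ``chunksize`` the file is streamed in bounded-memory chunks (the
    validation state carried between chunks is one row per participant/block),
    so arbitrarily large logs can be checked without a full load; the
    concatenated frame is still returned for in-memory use.
    """
    path = Path(path)
    header = pd.read_csv(path, sep="\t", nrows=0)
    missing = [c for c in LOG_COLUMNS if c not in header.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    chunks = []
    last_t: dict[tuple, float] = {}
    offset = 2  # header is line 1
    reader = (
        pd.read_csv(path, sep="\t", chunksize=chunksize)
        if chunksize
        else [pd.read_csv(path, sep="\t")]
    )
    for chunk in reader:
        bad_kind = ~chunk["event_kind"].isin(EVENT_KINDS)
        if bad_kind.any():
            line = offset + int(np.flatnonzero(bad_kind)[0])
            raise ValueError(
                f"{path}: unknown event kind "
                f"{chunk['event_kind'][bad_kind].iloc[0]!r} at line {line}"
            )
        for i, row in enumerate(
            chunk[["participant_id", "block_id", "t"]].itertuples(index=False)
        ):
            key = (row.participant_id, row.block_id)
            if key in last_t and row.t < last_t[key] - 1e-9:
                raise ValueError(
                    f"{path}: non-monotone time within block at line {offset + i}"
                )
            last_t[key] = row.t
        chunks.append(chunk)
        offset += len(chunk)
    return pd.concat(chunks, ignore_index=True)


def write_roi_timecourse(tc: bold_sim.RoiTimecourse, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "participant_id": tc.participant_id,
            "roi": tc.roi,
            "volume_index": np.arange(tc.n_volumes),
            "t": tc.times,
            "value": tc.values,
        }
    )
    return write_table(df, path)


def read_roi_timecourses(path: str | Path) -> dict[tuple[int, str], bold_sim.RoiTimecourse]:
    df = read_table(path, required=ROI_COLUMNS)
    out = {}
    for (pid, roi), g in df.groupby(["participant_id", "roi"]):
        g = g.sort_values("volume_index")
        if not np.array_equal(g["volume_index"].to_numpy(), np.arange(len(g))):
            raise ValueError(f"{path}: missing volumes for participant {pid} roi {roi}")
        tr = float(np.median(np.diff(g["t"]))) if len(g) > 1 else DEFAULT_TR
        out[(int(pid), str(roi))] = bold_sim.RoiTimecourse(
            int(pid), str(roi), tr, g["value"].to_numpy(float)
        )
    return out


def _default_truths() -> dict:
    """Ground-truth template echoing the qualitative pattern the analyses
    should detect: positive check-switch and threat-modulation responses in
    the subcortical regions, negligible reward-rate modulation."""
    base_events = {
        "check_switch": 1.0,
        "forage_switch": -0.5,
        "check_repeat": 0.4,
        "forage_repeat": 0.2,
        "discovery": 0.8,
        "hide": 0.3,
    }
    mods = {
        ("check_switch", "tp"): 0.5,
        ("forage_switch", "tp"): 0.3,
        ("check_switch", "rr"): 0.0,
        ("forage_switch", "rr"): 0.0,
    }
    rois = {}
    for roi in ("Hb", "DRN", "VTA", "SN"):
        rois[roi] = RoiGroundTruth(roi, dict(base_events), dict(mods))
    return rois


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    task: TaskConfig = field(default_factory=TaskConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    hrf: HrfSpec = field(default_factory=HrfSpec)
    tr: float = DEFAULT_TR
    phase: str = "pre"
    seed: int = 0
    rois: tuple[str, ...] = ("Hb", "DRN", "VTA", "SN")
    ppi_seed_roi: str = "Hb"
    ppi_target_roi: str = "DRN"
    ppi_gamma: float = -0.5

    def to_dict(self) -> dict:
        return {
            "task": self.task.to_dict(),
            "cohort": {
                "n_agents": self.cohort.n_agents,
                "param_means": dataclasses.asdict(self.cohort.param_means),
                "param_sds": dict(self.cohort.param_sds),
                "seed": self.cohort.seed,
            },
            "hrf": dataclasses.asdict(self.hrf),
            "tr": self.tr,
            "phase": self.phase,
            "seed": self.seed,
            "rois": list(self.rois),
            "ppi_seed_roi": self.ppi_seed_roi,
            "ppi_target_roi": self.ppi_target_roi,
            "ppi_gamma": self.ppi_gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        if "task" in kw:
            kw["task"] = TaskConfig.from_dict(kw["task"])
        if "cohort" in kw:
            c = dict(kw["cohort"])
            if "param_means" in c:
                c["param_means"] = AgentParams(**c["param_means"])
            kw["cohort"] = CohortSpec(**c)
        if "hrf" in kw:
            kw["hrf"] = HrfSpec(**kw["hrf"])
        if "rois" in kw:
            kw["rois"] = tuple(kw["rois"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def _n_volumes(cfg: TaskConfig, tr: float) -> int:
    return int(np.ceil(cfg.session_duration / tr))


def pipeline_run(config: RunConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the full pipeline: simulate → derive → behavior → BOLD → GLM → PPI.

    Writes stage outputs and an archived config under ``out_dir`` and returns
    a report dict (also written as JSON) with group-level tables and stage
    output hashes; identical config + seed reproduce identical hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    cohort = dataclasses.replace(config.cohort, seed=seed)
    cfg = config.task
    report: dict = {"seed": seed}

    # --- simulate
    logs, truth = generate_cohort(cohort, cfg)
    for log in logs:
        validate_log(log, cfg)
    log_all = pd.concat(logs, ignore_index=True)
    write_session_log(log_all, out / "session_logs.tsv")
    write_table(truth, out / "agent_truth.tsv")

    # --- derived series + collinearity
    events = pd.concat(
        [derived_vars.standardize(derived_vars.event_series(l, cfg)) for l in logs],
        ignore_index=True,
    )
    write_table(events, out / "derived_events.tsv")
    pre = events[events["phase"] == "pre_PD"]
    coll = derived_vars.collinearity_report(pre)
    write_table(coll, out / "collinearity.tsv")
    report["median_abs_r_tp_rr"] = float(
        coll.loc[coll["participant_id"] != "pooled", "r_time_pressure_reward_rate"]
        .abs()
        .median()
    )

    # --- behavior
    fits = behavior.fit_cohort(logs, cfg, "check_vs_forage", phase=config.phase)
    gt = behavior.group_table(fits)
    write_table(gt, out / "behavior_group.tsv")
    report["behavior"] = gt.to_dict("records")
    report["n_excluded"] = int(sum(f.excluded for f in fits))

    # --- BOLD simulation + GLM
    truths = _default_truths()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    n_vol = _n_volumes(cfg, config.tr)
    spec = neuro_glm.DesignSpec(hrf=config.hrf)
    beta_rows = []
    ppi_fits = []
    for pid, log in enumerate(logs):
        ev = neuro_glm.glm_events(log, cfg, phase=config.phase)
        X = neuro_glm.build_design(ev, config.tr, n_vol, spec)
        amp = {
            roi: bold_sim.event_amplitudes(ev, truths[roi]) for roi in config.rois
        }
        seed_roi, tgt_roi = config.ppi_seed_roi, config.ppi_target_roi
        ev_psych = neuro_glm.assign_psych(amp[tgt_roi])
        coupled = bold_sim.inject_ppi(ev_psych, amp[seed_roi], config.ppi_gamma)
        series = {}
        for roi in config.rois:
            table = coupled if roi == tgt_roi else amp[roi]
            series[roi] = bold_sim.synthesize_roi(
                table, truths[roi], config.hrf, n_vol, rng.spawn(1)[0],
                tr=config.tr, participant_id=pid,
            )
        for roi in config.rois:
            fit = neuro_glm.fit_glm(series[roi], X, prewhiten=True)
            for cls in ("check_switch", "forage_switch"):
                for mod, feat in (("z_threat", "threat"), ("z_reward_rate", "reward_rate")):
                    name = f"{cls}_x_{mod}"
                    if name in fit.betas.index:
                        beta_rows.append(
                            {
                                "participant_id": pid,
                                "roi": roi,
                                "switch_type": cls,
                                "feature": feat,
                                "beta": fit.betas[name],
                            }
                        )
        ppi_ev = neuro_glm.assign_psych(ev)
        ppi_fits.append(
            neuro_glm.ppi_regression(
                series[tgt_roi], series[seed_roi], ppi_ev, tr=config.tr, hrf=config.hrf
            )
        )
    betas = pd.DataFrame(beta_rows)
    write_table(betas, out / "glm_betas.tsv")
    anova = neuro_glm.group_beta_anova(betas[["roi", "switch_type", "feature", "beta"]].assign(participant_id=betas["participant_id"]))
    anova.to_csv(out / "glm_anova.tsv", sep="\t")
    report["glm_anova"] = {
        idx: {"F": float(row["F"]), "p": float(row["PR(>F)"])}
        for idx, row in anova.iterrows()
        if np.isfinite(row.get("F", np.nan))
    }
    three_way = neuro_glm.ppi_group(ppi_fits, "seed_x_psych_x_modulator")
    report["ppi_three_way"] = three_way
    pd.DataFrame([three_way]).pipe(write_table, out / "ppi_group.tsv")

    # --- archive config + hashes
    config.to_yaml(out / "config.yaml")
    hashes = {}
    for f in sorted(out.glob("*.tsv")):
        hashes[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    report["hashes"] = hashes
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
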