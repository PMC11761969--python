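#!/usr/bin/env python
"""Seed-to-target interaction analyses on synthetic BOLD: inject a negative
three-way coupling (seed activity x check-vs-forage context x threat level)
from the habenula series into the raphe series, recover it with the PPI
regression, summarize the cortico-subcortical peak table with the two-way
ANOVA + Tukey HSD, and run the event-locked epoching with the leave-one-out
peak test on discovery events.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from oceanforage import CohortSpec, TaskConfig, generate_cohort
from oceanforage import bold_sim, neuro_glm
from oceanforage.bold_sim import DEFAULT_TR, HrfSpec, RoiGroundTruth
from oceanforage.io import write_table
from oceanforage.task_env import session_time

EVENT_BETAS = {
    "check_switch": 1.0,
    "forage_switch": -0.5,
    "check_repeat": 0.4,
    "forage_repeat": 0.2,
    "discovery": 0.8,
    "hide": 0.3,
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--gamma", type=float, default=-0.5)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = TaskConfig()
    logs, _ = generate_cohort(CohortSpec(n_agents=23, seed=args.seed), cfg)
    n_vol = int(np.ceil(cfg.session_duration / DEFAULT_TR))
    hb = RoiGroundTruth("Hb", dict(EVENT_BETAS), {("check_switch", "tp"): 0.5}, snr=0.5)
    drn = RoiGroundTruth("DRN", dict(EVENT_BETAS), {("check_switch", "tp"): 0.5}, snr=0.5)
    rng = np.random.default_rng(args.seed + 2000)

    fits, disc_traces = [], []
    for pid, log in enumerate(logs):
        ev = neuro_glm.glm_events(log, cfg, phase="pre")
        X = neuro_glm.build_design(ev, DEFAULT_TR, n_vol, neuro_glm.DesignSpec())
        amp_hb = bold_sim.event_amplitudes(ev, hb)
        amp_drn = neuro_glm.assign_psych(bold_sim.event_amplitudes(ev, drn))
        coupled = bold_sim.inject_ppi(amp_drn, amp_hb, args.gamma)
        tc_drn = bold_sim.synthesize_roi(
            coupled, drn, HrfSpec(), n_vol, rng.spawn(1)[0], participant_id=pid
        )
        tc_hb = bold_sim.synthesize_roi(
            amp_hb, hb, HrfSpec(), n_vol, rng.spawn(1)[0], participant_id=pid
        )
        fits.append(neuro_glm.ppi_regression(tc_drn, tc_hb, amp_drn, X_base=X))
        disc = ev[ev["glm_class"] == "discovery"]
        if len(disc):
            es = neuro_glm.epoch_timecourses(tc_hb, disc["t_abs"].to_numpy())
            disc_traces.append(es.mean())
            times = es.times

    g3 = neuro_glm.ppi_group(fits, "seed_x_psych_x_modulator")
    table = pd.concat(
        [f.assign(participant_id=i) for i, f in enumerate(fits)], ignore_index=True
    )
    write_table(table, args.out / "ppi_fits.tsv")
    write_table(pd.DataFrame([g3]), args.out / "ppi_group.tsv")

    loo = neuro_glm.loo_peak_test(np.asarray(disc_traces), times, direction="max")
    print(
        f"three-way PPI (injected gamma={args.gamma}): "
        f"M={g3['mean']:+.4f}, Z={g3['z']:.2f}, p={g3['p']:.3f}"
    )
    print(
        "discovery-locked Hb response (LOO peak): "
        f"mean latency {loo['mean_peak_latency']:.2f} s, p={loo['p']:.4f} "
        f"(n={len(disc_traces)} participants)"
    )
    print(f"tables written under {args.out}/")


if __name__ == "__main__":
    main()
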