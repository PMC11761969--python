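#!/usr/bin/env python
"""Fit the behavioral models to a simulated cohort and summarize at the group
level: check-vs-forage logistic weights (threat and reward), the IRT models
(switch / check / interaction, pre-switch slowing, discovery slowing), action
proportions and the threat/reward decorrelation diagnostic.

Reads the logs written by 01_simulate_cohort.py (or simulates afresh with
--seed if they are absent) and writes tidy group tables under --out.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from oceanforage import CohortSpec, TaskConfig, generate_cohort
from oceanforage import behavior, derived_vars
from oceanforage.io import read_session_log, write_table


def load_logs(out: Path, seed: int, cfg: TaskConfig):
    path = out / "session_logs.tsv"
    if path.exists():
        log_all = read_session_log(path)
        return [g.reset_index(drop=True) for _, g in log_all.groupby("participant_id")]
    logs, _ = generate_cohort(CohortSpec(n_agents=23, seed=seed), cfg)
    return logs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--phase", choices=["pre", "post"], default="pre")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = TaskConfig()
    logs = load_logs(args.out, args.seed, cfg)

    choice_fits = behavior.fit_cohort(logs, cfg, "check_vs_forage", phase=args.phase)
    choice_group = behavior.group_table(choice_fits)
    write_table(choice_group, args.out / f"behavior_choice_group_{args.phase}.tsv")

    rows = []
    for model in ("irt_main", "irt_pre_switch_slope", "irt_discovery"):
        kw = {} if model == "irt_discovery" else {"phase": args.phase}
        fits = behavior.fit_cohort(logs, cfg, model, **kw)
        g = behavior.group_table(fits)
        g.insert(0, "model", model)
        rows.append(g)
    irt_group = pd.concat(rows, ignore_index=True)
    write_table(irt_group, args.out / f"behavior_irt_group_{args.phase}.tsv")

    props = pd.DataFrame(
        [behavior.action_proportions(l, phase=args.phase) for l in logs]
    )
    write_table(
        props.describe().reset_index(), args.out / f"action_proportions_{args.phase}.tsv"
    )

    gt = choice_group.set_index("term")
    print(f"check-vs-forage ({args.phase}-PD), N={int(gt.loc['z_threat', 'n'])}:")
    for term, label in [("z_threat", "threat"), ("z_rr", "reward rate")]:
        r = gt.loc[term]
        print(
            f"  {label:12s} M={r['mean']:+.3f}  t({int(r['df'])})={r['t']:.2f}"
            f"  p={r['p']:.2e}"
        )
    im = irt_group[irt_group["model"] == "irt_main"].set_index("term")
    for term in ("switch", "check", "z_threat", "z_rr", "switch_x_check"):
        if term in im.index:
            r = im.loc[term]
            print(f"  IRT {term:15s} M={r['mean']:+.3f}  t={r['t']:.2f}")
    print(f"group tables written under {args.out}/")


if __name__ == "__main__":
    main()
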