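#!/usr/bin/env python
"""Perturbation responses: peri-perturbation steps and the 6S statistic.

For each perturbation trial of the simulated session, labels the six
pre- and six post-perturbation steps (PD/NPD, 1D..6ND), computes the
6S deviation from the baseline means for every gait parameter, and
averages the last three repetitions.  Writes ``results/six_s.tsv``
(one row per trial x parameter) and ``results/peri_steps.tsv`` (per
label means/SDs), and prints which perturbation type disturbs each
margin of stability the most.
"""

import json
from pathlib import Path

import pandas as pd

from gaitstab import detect_heel_strikes, peri_step_table, read_trial
from gaitstab.perturbation_response import analyze_perturbation_trial
from gaitstab.stability_metrics import baseline_summary, step_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    base = read_trial(ROOT / "session" / "baseline.tsv")
    summary = baseline_summary(step_table(base), base.meta.dominant_side)
    order = json.loads((ROOT / "session" / "session.json").read_text())["order"]

    six_rows, all_windows = [], []
    for ptype in order:
        trial = read_trial(ROOT / "session" / f"{ptype}.tsv")
        steps = step_table(trial, detect_heel_strikes(trial))
        windows, per_rep, avg = analyze_perturbation_trial(steps, trial.events_log, summary)
        all_windows.extend(windows)
        for param, value in avg.values.items():
            six_rows.append(
                {
                    "subject": trial.meta.subject_id,
                    "ptype": ptype,
                    "parameter": param,
                    "six_s": value,
                    "n_reps": avg.n_repetitions,
                }
            )

    six = pd.DataFrame(six_rows)
    six.to_csv(ROOT / "six_s.tsv", sep="\t", index=False)
    peri = peri_step_table(all_windows, summary)
    peri.to_csv(ROOT / "peri_steps.tsv", sep="\t", index=False)

    for param, label in (("mos_ml", "ML margin"), ("mos_ap", "AP margin")):
        ranked = six[six["parameter"] == param].sort_values("six_s", ascending=False)
        top = ranked.iloc[0]
        print(f"{label}: largest 6S from {top['ptype']} ({top['six_s']:.3f} m)")
        print(ranked[["ptype", "six_s"]].round(4).to_string(index=False), "\n")
    print("wrote six_s.tsv and peri_steps.tsv")


if __name__ == "__main__":
    main()
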