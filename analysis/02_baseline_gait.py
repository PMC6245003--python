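#!/usr/bin/env python
"""Baseline gait: heel strikes, per-step parameters, 100-step summary.

Reads the baseline trial written by 01_simulate_session.py, detects
heel strikes from the anterior heel-minus-pelvis peaks, computes step
time/length/width and the ML/AP margins of stability per step, and
averages 100 consecutive dominant (BD) and non-dominant (BND) steps.
Writes ``results/baseline_steps.tsv`` and ``results/baseline_summary.tsv``.
"""

from pathlib import Path

from gaitstab import detect_heel_strikes, read_trial
from gaitstab.stability_metrics import baseline_summary, step_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    trial = read_trial(ROOT / "session" / "baseline.tsv")
    events = detect_heel_strikes(trial)
    print(f"baseline: {events.n_events} heel strikes, "
          f"{events.stride_count('L')} left strides, {events.stride_count('R')} right strides")

    steps = step_table(trial, events)
    steps.to_csv(ROOT / "baseline_steps.tsv", sep="\t", index=False)

    summary = baseline_summary(steps, trial.meta.dominant_side)
    summary.stats.to_csv(ROOT / "baseline_summary.tsv", sep="\t")
    print(f"\nBaseline means over {summary.n_steps['D']} steps per side:")
    print(summary.stats.round(4).to_string())
    print("\nwrote baseline_steps.tsv and baseline_summary.tsv")


if __name__ == "__main__":
    main()
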