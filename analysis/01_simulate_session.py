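#!/usr/bin/env python
"""Generate one synthetic perturbation session and write it to disk.

A session is a 2-minute baseline walking trial plus six perturbation
trials (ipsi/contralateral sway, belt acceleration/deceleration,
visual, auditory), each with four triggers at non-dominant heel
strikes.  Trials are written as TSV with event sidecars under
``results/session/`` together with per-step ground-truth tables, so
the later analysis steps can run purely from files.
"""

import json
from pathlib import Path

from gaitstab import make_session, write_trial

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "session"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    session = make_session(seed=SEED)
    names = []
    for name, syn in session.items():
        if name == "order":
            continue
        write_trial(syn.trial, OUT / f"{name}.tsv")
        syn.truth["steps"].to_csv(OUT / f"{name}.truth.tsv", sep="\t", index=False)
        names.append(name)
        print(
            f"{name:12s} {syn.trial.n_samples:6d} samples, "
            f"{len(syn.truth['strikes']):4d} heel strikes, "
            f"{len(syn.trial.events_log)} perturbations"
        )
    (OUT / "session.json").write_text(
        json.dumps({"seed": SEED, "order": session["order"], "trials": names}, indent=1)
    )
    print(f"\nPresentation order: {session['order']}")
    print(f"Wrote {len(names)} trials to {OUT}")


if __name__ == "__main__":
    main()
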