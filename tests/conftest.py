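"""Shared fixtures: expensive synthetic trials are built once per session."""

import pytest

from gaitstab import detect_heel_strikes, make_gait_trial, make_session
from gaitstab.stability_metrics import baseline_summary, step_table


@pytest.fixture(scope="session")
def base_syn():
    """Noiseless 130 s baseline walking trial (117 strides at defaults)."""
    return make_gait_trial(duration=130.0, seed=1)


@pytest.fixture(scope="session")
def base_events(base_syn):
    return detect_heel_strikes(base_syn.trial)


@pytest.fixture(scope="session")
def base_steps(base_syn, base_events):
    return step_table(base_syn.trial, base_events)


@pytest.fixture(scope="session")
def base_summary(base_steps):
    return baseline_summary(base_steps, dominant_side="R")


@pytest.fixture(scope="session")
def session_fx():
    """One full perturbation session: baseline + 6 trials x 4 repetitions."""
    return make_session(seed=7)


@pytest.fixture(scope="session")
def session_analysis(session_fx):
    """Full pipeline run over the session: baseline summary, peri windows
    and last-3-averaged 6S results per perturbation type."""
    from gaitstab.perturbation_response import analyze_perturbation_trial

    base = session_fx["baseline"]
    steps = step_table(base.trial)
    summary = baseline_summary(steps, base.params.dominant_side)
    results, windows = {}, {}
    for ptype in ("sway_ipsi", "sway_contra", "belt_acc", "belt_dec", "visual", "auditory"):
        syn = session_fx[ptype]
        st = step_table(syn.trial)
        wins, _, avg = analyze_perturbation_trial(st, syn.trial.events_log, summary)
        results[ptype] = avg
        windows[ptype] = wins
    return {"baseline_steps": steps, "summary": summary, "results": results, "windows": windows}
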