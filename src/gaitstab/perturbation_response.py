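"""Peri-perturbation step labelling and the 6S deviation statistic.

Perturbations are triggered at a non-dominant heel strike, so the first
post-perturbation step (the step terminated by the next heel strike)
always lands on the dominant side.  Post steps are labelled 1D, 2ND,
3D, 4ND, 5D, 6ND; the six steps immediately preceding the trigger form
the pre-window, summarised as PD (mean of the three dominant-ending pre
steps) and NPD (mean of the three non-dominant-ending ones).

The total perturbation response for a gait parameter p is

    6S = sum_{i=1}^{2} sum_{j=1}^{3} | B(i) - P(i + (j-1)*2) |

where B(1)/B(2) are the dominant/non-dominant baseline means and
P(1..6) are the six post-perturbation steps — i.e. the L1 norm of the
side-matched deviation vector.  It deliberately ignores the time course
of recovery: a large fast-recovering deviation and a small slow one can
score equally.  Per-repetition 6S values are averaged over the last
three repetitions of each perturbation trial (the first exposure is a
startle and is excluded by this rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IncompleteWindow, TriggerMisaligned, WindowOverlap
from .stability_metrics import GAIT_PARAMETERS, BaselineSummary
from .trajectory_io import PerturbationEvent

#: Post-perturbation step labels in temporal order.
POST_LABELS = ("1D", "2ND", "3D", "4ND", "5D", "6ND")

#: Number of pre/post steps in a peri-perturbation window.
WINDOW_STEPS = 6

#: Default tolerance (samples) between trigger and the matching ND heel strike.
TRIGGER_TOLERANCE = 3


@dataclass
class PeriWindow:
    """Six pre- and six post-perturbation steps around one trigger."""

    event: PerturbationEvent
    pre: pd.DataFrame  # 6 rows, oldest first, last row ends at the trigger strike
    post: pd.DataFrame  # 6 rows labelled 1D..6ND
    dominant_side: str

    def pre_mean(self, parameter: str, side: str) -> float:
        """PD / NPD pre-perturbation mean; ``side`` is 'D' or 'ND'."""
        want = self.dominant_side if side == "D" else ("L" if self.dominant_side == "R" else "R")
        return float(self.pre.loc[self.pre["side"] == want, parameter].mean())


def extract_peri_window(
    steps: pd.DataFrame,
    event: PerturbationEvent,
    dominant_side: str,
    all_events: list | None = None,
    trigger_tol: int = TRIGGER_TOLERANCE,
) -> PeriWindow:
    """Slice the peri-perturbation window of ``event`` out of a step table.

    ``steps`` is a temporally ordered step table (`stability_metrics.step_table`).
    The trigger must coincide (within ``trigger_tol`` samples) with a
    non-dominant heel strike; when ``all_events`` is given, windows that
    would share steps with another event raise :class:`WindowOverlap`.
    """
    nd_side = "L" if dominant_side == "R" else "R"
    hs = steps["hs_sample"].to_numpy()

    def anchor_index(ev):
        close = np.flatnonzero(np.abs(hs - ev.trigger_sample) <= trigger_tol)
        close = [i for i in close if steps["side"].iat[i] == nd_side]
        if not close:
            raise TriggerMisaligned(
                f"{ev.ptype} trigger at sample {ev.trigger_sample} does not coincide "
                f"with a non-dominant heel strike (tolerance +-{trigger_tol} samples)"
            )
        return int(close[0])

    p = anchor_index(event)
    if all_events is not None:
        for other in all_events:
            if other is event or other.trigger_sample == event.trigger_sample:
                continue
            try:
                q = anchor_index(other)
            except TriggerMisaligned:
                continue
            if abs(p - q) <= 2 * WINDOW_STEPS - 1:
                raise WindowOverlap(
                    f"windows of {event.ptype} (step {p}) and {other.ptype} (step {q}) share steps"
                )

    if p < WINDOW_STEPS - 1:
        raise IncompleteWindow(f"only {p + 1} steps before the trigger, need {WINDOW_STEPS}")
    if p + WINDOW_STEPS >= len(steps):
        raise IncompleteWindow(
            f"only {len(steps) - 1 - p} steps after the trigger, need {WINDOW_STEPS}"
        )

    pre = steps.iloc[p - WINDOW_STEPS + 1 : p + 1].copy()
    post = steps.iloc[p + 1 : p + 1 + WINDOW_STEPS].copy()
    if post["side"].iat[0] != dominant_side:
        raise TriggerMisaligned(
            f"first post-perturbation step lands on {post['side'].iat[0]}, "
            f"expected dominant side {dominant_side}"
        )
    pre["role"], post["role"] = "pre", "post"
    post["label"] = list(POST_LABELS)
    return PeriWindow(event=event, pre=pre, post=post, dominant_side=dominant_side)


def six_s(baseline: BaselineSummary, window: PeriWindow, parameter: str) -> float:
    """The 6S deviation-from-baseline for one parameter and one window."""
    post = window.post
    if len(post) != WINDOW_STEPS:
        raise IncompleteWindow(f"window has {len(post)} post steps, need {WINDOW_STEPS}")
    total = 0.0
    for i, side in ((1, "D"), (2, "ND")):
        b = baseline.mean(parameter, side)
        for j in (1, 2, 3):
            p_val = float(post[parameter].iat[i + (j - 1) * 2 - 1])
            total += abs(b - p_val)
    return total


def six_s_all(baseline: BaselineSummary, window: PeriWindow) -> dict:
    """6S for every gait parameter of one window."""
    return {p: six_s(baseline, window, p) for p in GAIT_PARAMETERS}


@dataclass
class SixSResult:
    """Per-parameter 6S values for one perturbation type."""

    ptype: str
    values: dict  # parameter -> 6S (units of the parameter)
    n_repetitions: int = 1
    warnings: list = field(default_factory=list)


def average_repetitions(results: list, keep_last: int = 3) -> SixSResult:
    """Average per-repetition :class:`SixSResult` over the last ``keep_last``.

    With fewer repetitions than requested, everything available is
    averaged and a warning is recorded on the result.
    """
    if not results:
        raise ValueError("no repetitions to average")
    ptype = results[0].ptype
    warnings = []
    if len(results) < keep_last:
        warnings.append(f"only {len(results)} repetitions available, requested last {keep_last}")
    kept = results[-keep_last:]
    values = {
        p: float(np.mean([r.values[p] for r in kept])) for p in kept[0].values
    }
    return SixSResult(ptype=ptype, values=values, n_repetitions=len(kept), warnings=warnings)


def peri_step_table(windows: list, baseline: BaselineSummary | None = None) -> pd.DataFrame:
    """Tidy per-label summary across windows.

    One row per (perturbation type, label, parameter) with the mean and
    SD across windows; labels are PD, NPD and 1D..6ND (8 per parameter).
    Suitable for export to external statistics software.
    """
    if not windows:
        raise ValueError("need at least one peri-perturbation window")
    cells = []
    for w in windows:
        for param in GAIT_PARAMETERS:
            cells.append((w.event.ptype, "PD", param, w.pre_mean(param, "D")))
            cells.append((w.event.ptype, "NPD", param, w.pre_mean(param, "ND")))
            for label in POST_LABELS:
                val = float(w.post.loc[w.post["label"] == label, param].iloc[0])
                cells.append((w.event.ptype, label, param, val))
    df = pd.DataFrame(cells, columns=["ptype", "label", "parameter", "value"])
    out = (
        df.groupby(["ptype", "label", "parameter"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return out


def analyze_perturbation_trial(
    steps: pd.DataFrame,
    events: list,
    baseline: BaselineSummary,
    keep_last: int = 3,
    trigger_tol: int = TRIGGER_TOLERANCE,
) -> tuple:
    """Windows, per-repetition 6S and the last-``keep_last`` average for one trial.

    Returns ``(windows, per_rep, averaged)`` where ``per_rep`` is a list
    of :class:`SixSResult` in repetition order.
    """
    windows = [
        extract_peri_window(steps, ev, baseline.dominant_side, all_events=events, trigger_tol=trigger_tol)
        for ev in events
    ]
    per_rep = [
        SixSResult(ptype=w.event.ptype, values=six_s_all(baseline, w)) for w in windows
    ]
    return windows, per_rep, average_repetitions(per_rep, keep_last=keep_last)
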