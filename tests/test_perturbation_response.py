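"""Peri-perturbation windows, the 6S statistic and repetition averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstab import average_repetitions, extract_peri_window, peri_step_table, six_s
from gaitstab.errors import IncompleteWindow, TriggerMisaligned, WindowOverlap
from gaitstab.perturbation_response import POST_LABELS, PeriWindow, SixSResult
from gaitstab.stability_metrics import GAIT_PARAMETERS, BaselineSummary
from gaitstab.trajectory_io import PerturbationEvent


def fake_baseline(means_d=None, means_nd=None):
    means_d = means_d or {}
    means_nd = means_nd or {}
    stats = pd.DataFrame(
        {
            "mean_D": [means_d.get(p, 0.0) for p in GAIT_PARAMETERS],
            "sd_D": 0.0,
            "mean_ND": [means_nd.get(p, 0.0) for p in GAIT_PARAMETERS],
            "sd_ND": 0.0,
        },
        index=pd.Index(GAIT_PARAMETERS, name="parameter"),
    )
    return BaselineSummary(stats=stats, n_steps={"D": 100, "ND": 100}, dominant_side="R")


def fake_steps(n=40, trigger_step=20, step_samples=55):
    """Alternating step table with the trigger landing on an ND (L) strike."""
    rows = []
    for k in range(n):
        side = "L" if k % 2 == 0 else "R"  # ND strikes on even indices
        rows.append(
            {
                "hs_sample": 100 + step_samples * k,
                "side": side,
                "step_time": 0.55,
                "step_length": 0.68,
                "step_width": 0.12,
                "mos_ml": 0.05,
                "mos_ap": 0.17,
            }
        )
    trigger_sample = 100 + step_samples * trigger_step
    return pd.DataFrame(rows), trigger_sample


def make_window(post_values, parameter="step_width", ptype="sway_contra"):
    """PeriWindow with the six post steps set to given parameter values."""
    steps, trigger = fake_steps()
    ev = PerturbationEvent(ptype, trigger / 100.0, trigger, 1)
    w = extract_peri_window(steps, ev, dominant_side="R")
    w.post = w.post.copy()
    w.post[parameter] = list(post_values)
    return w


class TestExtractPeriWindow:
    def test_labels_and_sides(self):
        steps, trigger = fake_steps()
        ev = PerturbationEvent("belt_dec", trigger / 100.0, trigger, 1)
        w = extract_peri_window(steps, ev, dominant_side="R")
        assert list(w.post["label"]) == list(POST_LABELS)
        assert list(w.post["side"]) == ["R", "L", "R", "L", "R", "L"]
        assert len(w.pre) == 6
        assert w.pre["side"].iat[-1] == "L"  # last pre step ends at the ND trigger

    def test_misaligned_trigger_rejected(self):
        steps, trigger = fake_steps()
        ev = PerturbationEvent("visual", 0.0, trigger - 10, 1)
        with pytest.raises(TriggerMisaligned):
            extract_peri_window(steps, ev, dominant_side="R")

    def test_trigger_on_dominant_strike_rejected(self):
        steps, trigger = fake_steps()
        ev = PerturbationEvent("visual", 0.0, trigger + 55, 1)  # a D strike
        with pytest.raises(TriggerMisaligned):
            extract_peri_window(steps, ev, dominant_side="R")

    def test_overlapping_windows_rejected(self):
        steps, trigger = fake_steps()
        e1 = PerturbationEvent("sway_ipsi", 0.0, trigger, 1)
        e2 = PerturbationEvent("sway_ipsi", 0.0, trigger + 4 * 55, 2)  # 4 steps later
        with pytest.raises(WindowOverlap):
            extract_peri_window(steps, e1, dominant_side="R", all_events=[e1, e2])

    def test_incomplete_window_rejected(self):
        steps, _ = fake_steps(n=24, trigger_step=20)  # only 3 post steps
        ev = PerturbationEvent("visual", 0.0, 100 + 55 * 20, 1)
        with pytest.raises(IncompleteWindow):
            extract_peri_window(steps, ev, dominant_side="R")


class TestSixS:
    def test_zero_when_posts_match_baseline(self):
        b = fake_baseline({"step_width": 0.12}, {"step_width": 0.12})
        w = make_window([0.12] * 6)
        assert six_s(b, w, "step_width") == 0.0

    def test_uniform_centimeter_deviation_sums_to_six(self):
        b = fake_baseline({"step_width": 0.12}, {"step_width": 0.12})
        w = make_window([0.13] * 6)
        assert six_s(b, w, "step_width") == pytest.approx(0.06, abs=1e-12)

    def test_frozen_mixed_deviation_example(self):
        """Deviations (+0.02, -0.01, 0, +0.03, -0.02, +0.01) give an L1 of 0.09."""
        devs = [0.02, -0.01, 0.0, 0.03, -0.02, 0.01]
        b = fake_baseline({"step_width": 0.12}, {"step_width": 0.12})
        w = make_window([0.12 + d for d in devs])
        assert six_s(b, w, "step_width") == pytest.approx(0.09, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        bd=st.floats(-1, 1),
        bnd=st.floats(-1, 1),
        posts=st.lists(st.floats(-1, 1), min_size=6, max_size=6),
    )
    def test_equals_brute_force_l1(self, bd, bnd, posts):
        """6S is the L1 norm of side-matched deviations, computed here by
        direct enumeration over the six steps."""
        b = fake_baseline({"step_width": bd}, {"step_width": bnd})
        w = make_window(posts)
        expected = sum(abs(bd - posts[k]) for k in (0, 2, 4)) + sum(
            abs(bnd - posts[k]) for k in (1, 3, 5)
        )
        assert six_s(b, w, "step_width") == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_same_side_permutation(self):
        b = fake_baseline({"step_width": 0.1}, {"step_width": 0.1})
        w1 = make_window([0.12, 0.08, 0.14, 0.11, 0.10, 0.09])
        w2 = make_window([0.10, 0.09, 0.14, 0.08, 0.12, 0.11])  # D and ND sets permuted
        assert six_s(b, w1, "step_width") == pytest.approx(six_s(b, w2, "step_width"), abs=1e-12)

    def test_scales_linearly_with_deviations(self):
        b = fake_baseline({"step_width": 0.1}, {"step_width": 0.1})
        devs = np.array([0.02, -0.01, 0.005, 0.03, -0.02, 0.01])
        w1 = make_window(0.1 + devs)
        w3 = make_window(0.1 + 3 * devs)
        assert six_s(b, w3, "step_width") == pytest.approx(3 * six_s(b, w1, "step_width"), abs=1e-12)


class TestAverageRepetitions:
    def _results(self, vals):
        return [
            SixSResult(ptype="belt_acc", values={p: v for p in GAIT_PARAMETERS}) for v in vals
        ]

    def test_last_three_kept(self):
        avg = average_repetitions(self._results([0.4, 0.2, 0.2, 0.2]), keep_last=3)
        assert avg.values["mos_ml"] == pytest.approx(0.2)
        assert avg.n_repetitions == 3
        assert not avg.warnings

    def test_exactly_three_all_used(self):
        avg = average_repetitions(self._results([0.1, 0.2, 0.3]), keep_last=3)
        assert avg.values["mos_ap"] == pytest.approx(0.2)

    def test_fewer_than_requested_warns(self):
        avg = average_repetitions(self._results([0.3, 0.1]), keep_last=3)
        assert avg.n_repetitions == 2
        assert avg.warnings
        assert avg.values["step_time"] == pytest.approx(0.2)


def test_scripted_cross_step_narrows_1d_width(session_analysis):
    """The contralateral-sway script's medial first recovery step shows up
    as a 1D step width well below the pre-perturbation (PD) width."""
    table = peri_step_table(session_analysis["windows"]["sway_contra"])
    width = table[table["parameter"] == "step_width"].set_index("label")["mean"]
    assert width["1D"] < width["PD"] - 0.05


class TestPeriStepTable:
    def test_shape_and_zero_sd_for_identical_windows(self):
        steps, trigger = fake_steps()
        windows = []
        for rep in range(3):
            ev = PerturbationEvent("auditory", trigger / 100.0, trigger, rep + 1)
            windows.append(extract_peri_window(steps, ev, dominant_side="R"))
        table = peri_step_table(windows)
        # 8 labels x 5 parameters for the single perturbation type
        assert len(table) == 8 * 5
        assert set(table["label"]) == {"PD", "NPD", *POST_LABELS}
        assert (table["sd"].abs() < 1e-12).all()
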