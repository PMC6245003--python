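"""XCoM, margins of stability, spatio-temporal parameters, baseline."""

import numpy as np
import pandas as pd
import pytest

from gaitstab import (
    GAIT_PARAMETERS,
    XcomParams,
    baseline_summary,
    com_velocity,
    compute_step_mos,
    compute_xcom,
    detect_heel_strikes,
    make_gait_trial,
)
from gaitstab.errors import InsufficientBaseline, NonFiniteInput
from gaitstab.preprocess import GaitEvents
from gaitstab.stability_metrics import step_table
from gaitstab.trajectory_io import Trial, TrialMeta

FS = 100.0
OMEGA0_134 = np.sqrt(9.81 / 1.34)  # 2.70571 1/s for the 1.34 m pendulum


def make_point_mass_trial(l=1.34, v_belt=1.2, heel_R_y=0.30, com_ml_vel=0.0, heel_R_x=0.06):
    """Trial with a constant (or linearly moving) CoM and fixed feet.

    Linear motion passes the zero-phase filter and the central
    difference exactly, so margins have closed-form values.
    """
    n = 400
    t = np.arange(n) / FS
    com = np.column_stack([com_ml_vel * t, np.zeros(n), np.full(n, 0.9)])
    zeros = np.zeros(n)

    def fixed(x, y, z):
        return np.tile(np.array([x, y, z]), (n, 1))

    markers = {
        "heel_R": fixed(heel_R_x, heel_R_y, 0.0),
        "heel_L": fixed(-heel_R_x, -0.10, 0.0),
        "malleolus_R": fixed(heel_R_x, heel_R_y, 0.07),
        "malleolus_L": fixed(-heel_R_x, -0.10, 0.07),
        "trochanter_L": fixed(-0.1, 0.0, l / 1.34),
        "trochanter_R": fixed(0.1, 0.0, l / 1.34),
        "pelvis": fixed(0.0, 0.0, 0.93),
        "trunk": fixed(0.0, 0.0, 1.23),
    }
    return Trial(
        fs=FS,
        t=t,
        markers=markers,
        com=com,
        belt_speed_L=np.full(n, v_belt),
        belt_speed_R=np.full(n, v_belt),
        platform_ml=zeros,
        meta=TrialMeta(comfortable_speed=v_belt),
    )


def manual_events():
    return GaitEvents(
        samples=np.array([100, 200, 300]), sides=np.array(["L", "R", "L"]), fs=FS
    )


class TestXcom:
    def test_zero_velocity_identity(self):
        com = np.random.default_rng(0).normal(size=(50, 3))
        out = compute_xcom(com, np.zeros_like(com), XcomParams(l=1.34))
        np.testing.assert_allclose(out, com[:, :2])

    def test_closed_form_value(self):
        """v = 0.270571 m/s with omega0 = 2.70571 1/s puts the XCoM 0.100 m out."""
        com = np.zeros((10, 3))
        vel = np.zeros((10, 3))
        vel[:, 0] = 0.270571
        out = compute_xcom(com, vel, XcomParams(l=1.34))
        np.testing.assert_allclose(out[:, 0], 0.100, atol=1e-6)

    def test_linear_in_velocity(self):
        rng = np.random.default_rng(1)
        com, vel = rng.normal(size=(30, 3)), rng.normal(size=(30, 3))
        p = XcomParams(l=1.2)
        d1 = compute_xcom(com, vel, p) - com[:, :2]
        d2 = compute_xcom(com, 2 * vel, p) - com[:, :2]
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-12)

    @pytest.mark.parametrize("scale", [0.8, 1.0, 1.2, 1.5])
    def test_velocity_sensitivity_matches_closed_form(self, scale):
        """d(XCoM - CoM)/dv equals 1/omega0 across pendulum lengths."""
        p = XcomParams(l=1.34 * scale)
        com = np.zeros((5, 3))
        vel = np.ones((5, 3))
        gain = (compute_xcom(com, vel, p) - com[:, :2])[0, 0]
        assert gain == pytest.approx(np.sqrt(1.34 * scale / 9.81), rel=1e-12)

    def test_non_finite_rejected(self):
        com = np.zeros((5, 3))
        com[2, 1] = np.nan
        with pytest.raises(NonFiniteInput):
            compute_xcom(com, np.zeros_like(com), XcomParams(l=1.34))

    def test_params_from_trial_trochanter_height(self):
        trial = make_point_mass_trial(l=1.34)
        p = XcomParams.from_trial(trial)
        assert p.l == pytest.approx(1.34, rel=1e-9)
        assert p.omega0 == pytest.approx(OMEGA0_134, rel=1e-9)


class TestComVelocity:
    def test_belt_frame_adds_stance_belt_speed(self):
        trial = make_point_mass_trial(v_belt=1.2)
        vel = com_velocity(trial, frame="belt", events=manual_events())
        np.testing.assert_allclose(vel[:, 1], 1.2, atol=1e-12)

    def test_lab_frame_static_com_is_zero(self):
        trial = make_point_mass_trial(v_belt=1.2)
        vel = com_velocity(trial, frame="lab", events=manual_events())
        np.testing.assert_allclose(vel, 0.0, atol=1e-12)

    def test_central_difference_exact_on_ramps(self):
        trial = make_point_mass_trial(com_ml_vel=0.37)
        vel = com_velocity(trial, frame="lab", events=manual_events())
        np.testing.assert_allclose(vel[:, 0], 0.37, atol=1e-9)


class TestStepMos:
    def test_ap_closed_form(self):
        """Static CoM on a 1.2 m/s belt, heel landing 0.30 m ahead:
        mos_ap = 1.2 / 2.70571 - 0.30 = 0.1435 m."""
        trial = make_point_mass_trial(l=1.34, v_belt=1.2, heel_R_y=0.30)
        mos = compute_step_mos(trial, manual_events(), XcomParams(l=1.34))
        r_step = mos[mos["side"] == "R"].iloc[0]
        assert r_step["mos_ap"] == pytest.approx(1.2 / OMEGA0_134 - 0.30, abs=1e-9)
        assert r_step["mos_ap"] == pytest.approx(0.1435, abs=1e-4)

    def test_ml_zero_at_coincidence_and_sign(self):
        """XCoM under the leading malleolus gives 0; medial XCoM is positive."""
        p = XcomParams(l=1.34)
        trial0 = make_point_mass_trial(heel_R_x=0.0)
        mos0 = compute_step_mos(trial0, manual_events(), p)
        assert mos0[mos0["side"] == "R"]["mos_ml"].iloc[0] == pytest.approx(0.0, abs=1e-12)

        trial1 = make_point_mass_trial(heel_R_x=0.05)  # malleolus lateral to the XCoM
        mos1 = compute_step_mos(trial1, manual_events(), p)
        assert mos1[mos1["side"] == "R"]["mos_ml"].iloc[0] == pytest.approx(0.05, abs=1e-12)

    def test_moving_heel_forward_reduces_ap_margin(self):
        p = XcomParams(l=1.34)
        delta = 0.04
        m0 = compute_step_mos(make_point_mass_trial(heel_R_y=0.30), manual_events(), p)
        m1 = compute_step_mos(make_point_mass_trial(heel_R_y=0.30 + delta), manual_events(), p)
        d = m0[m0["side"] == "R"]["mos_ap"].iloc[0] - m1[m1["side"] == "R"]["mos_ap"].iloc[0]
        assert d == pytest.approx(delta, abs=1e-12)


def mirror_trial(trial, swap_labels):
    """Reflect all ML coordinates; optionally also swap L/R identities."""
    out = trial.copy()
    for name in list(out.markers):
        out.markers[name][:, 0] *= -1
    out.com[:, 0] *= -1
    out.platform_ml *= -1
    if swap_labels:
        m = out.markers
        for base in ("heel", "malleolus", "trochanter"):
            m[f"{base}_L"], m[f"{base}_R"] = m[f"{base}_R"], m[f"{base}_L"]
        out.belt_speed_L, out.belt_speed_R = out.belt_speed_R, out.belt_speed_L
        out.meta.dominant_side = "L" if out.meta.dominant_side == "R" else "R"
    return out


@pytest.fixture(scope="module")
def short_syn():
    return make_gait_trial(duration=30.0, seed=6)


class TestMirrorSymmetry:
    def test_reflection_negates_ml_margin(self, short_syn):
        """Mirroring ML coordinates alone flips the sign of every ML margin."""
        st = step_table(short_syn.trial)
        st_m = step_table(mirror_trial(short_syn.trial, swap_labels=False))
        merged = st.merge(st_m, on="hs_sample", suffixes=("", "_m"))
        assert len(merged) == len(st)
        np.testing.assert_allclose(merged["mos_ml_m"], -merged["mos_ml"], atol=1e-9)
        np.testing.assert_allclose(merged["mos_ap_m"], merged["mos_ap"], atol=1e-9)

    def test_reflection_with_relabel_preserves_metrics(self, short_syn):
        """A mirrored walker with swapped feet is physically identical:
        all step metrics (including signed ML margins) are unchanged."""
        st = step_table(short_syn.trial)
        st_m = step_table(mirror_trial(short_syn.trial, swap_labels=True))
        merged = st.merge(st_m, on="hs_sample", suffixes=("", "_m"))
        assert len(merged) == len(st)
        assert (merged["side"] != merged["side_m"]).all()
        for col in ("mos_ml", "mos_ap", "step_width", "step_length", "step_time"):
            np.testing.assert_allclose(merged[f"{col}_m"], merged[col], atol=1e-9)


class TestSpatiotemporalRoundTrip:
    def test_programmed_parameters_recovered(self, base_syn, base_steps):
        """Noiseless synthetic gait returns the programmed step time,
        length and width within 1 sample / 1 mm."""
        p = base_syn.params
        interior = base_steps.iloc[3:-3]
        assert np.abs(interior["step_time"] - p.step_time).max() <= 1 / FS + 1e-12
        assert np.abs(interior["step_length"] - p.step_length).max() < 1e-3
        assert np.abs(interior["step_width"] - p.step_width).max() < 1e-3

    def test_wide_steps_recovered(self):
        syn = make_gait_trial(duration=30.0, seed=9, step_width=0.20)
        st = step_table(syn.trial).iloc[3:-3]
        assert np.abs(st["step_width"] - 0.20).max() < 1e-3

    def test_matches_ground_truth_step_for_step(self, base_syn, base_steps):
        truth = base_syn.truth["steps"]
        merged = base_steps.merge(truth, on="hs_sample", suffixes=("", "_t"))
        assert len(merged) > 200
        np.testing.assert_allclose(merged["step_length"], merged["step_length_t"], atol=1e-3)
        np.testing.assert_allclose(merged["mos_ml"], merged["mos_ml_t"], atol=5e-4)
        np.testing.assert_allclose(merged["mos_ap"], merged["mos_ap_t"], atol=5e-4)


class TestBaselineSummary:
    def test_uses_exactly_100_steps_per_side(self, base_summary):
        assert base_summary.n_steps == {"D": 100, "ND": 100}

    def test_identical_steps_have_zero_sd(self):
        rows = []
        for k in range(240):
            rows.append(
                {
                    "hs_sample": 100 + 55 * k,
                    "side": "R" if k % 2 else "L",
                    "step_time": 0.55,
                    "step_length": 0.68,
                    "step_width": 0.12,
                    "mos_ml": 0.05,
                    "mos_ap": 0.17,
                }
            )
        bs = baseline_summary(pd.DataFrame(rows), dominant_side="R")
        for p in GAIT_PARAMETERS:
            assert bs.sd(p, "D") == pytest.approx(0.0, abs=1e-12)
            assert bs.sd(p, "ND") == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_steps_raise(self):
        syn = make_gait_trial(duration=60.0, seed=3)  # ~54 strides only
        st = step_table(syn.trial)
        with pytest.raises(InsufficientBaseline):
            baseline_summary(st, dominant_side="R")
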