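"""Synthetic dual-belt treadmill walking with programmable perturbations.

A purely kinematic template model of steady treadmill gait: no forces,
no balance dynamics — just smooth marker trajectories with known
ground truth, so every analysis stage of the pipeline has an exact
oracle.  The template walks at a comfortable speed with alternating
steps of programmable time, length and width, a medio-lateral CoM sway
locked to the step cycle, and feet that drift backward with the belt
during stance and swing forward to their next landing.

Six perturbation types can be injected, all triggered at a
non-dominant heel strike:

* ``sway_ipsi`` / ``sway_contra`` — a 5 cm lateral platform translation
  in ~0.7 s (trapezoidal velocity, peak acceleration 2.04 m/s^2) toward
  the non-dominant / dominant side, added to every marker, the CoM and
  the platform channel;
* ``belt_acc`` / ``belt_dec`` — the non-dominant belt ramps to 160 % /
  40 % of the comfortable speed in ~0.4 s (minimum-jerk profile), holds
  one step, and ramps back; the stance foot follows the belt;
* ``visual`` / ``auditory`` — event metadata only (a 5 s blackout or a
  0.5 s 82 dB horn leave the kinematics untouched by default).

Recovery behaviour is scripted, not emergent: a :class:`ResponseScript`
prescribes per-step deviations for the six post-perturbation steps
(step-time shifts and ML/AP margin-of-stability deviation targets,
realized through compensated foot placement), so the deviations the
pipeline should measure are known exactly.

Trajectory smoothness matters: analyses low-pass filter markers at
6 Hz with a zero-phase filter, which preserves polynomials up to cubic
exactly (its combined impulse response has zero mean and zero second
central moment) but distorts kinks.  Each heel-strike neighbourhood is
therefore an exact symmetric parabola over +-``cap_halfwidth`` seconds,
so the filtered heel position at the strike sample equals the
programmed landing to well under a millimeter and the peak of the
anterior heel excursion stays exactly at the strike sample.  The
parabola's drift deficit relative to the stance line (half the cap
width times the drift speed) is absorbed into the effective stance
drift speed, so programmed step lengths are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BPoly

from .errors import (
    ExcursionExceeded,
    InfeasibleProfile,
    ValidationError,
)
from .trajectory_io import PerturbationEvent, Trial, TrialMeta

#: Platform hardware bound: maximum excursion to each side (m).
MAX_PLATFORM_EXCURSION = 0.15

#: Fraction of the stride a foot spends in stance.
STANCE_FRACTION = 0.60

#: Peak-rate constant of the minimum-jerk ramp: max |ds/du| of
#: 10u^3 - 15u^4 + 6u^5 on [0, 1].
MINJERK_PEAK_RATE = 1.875


def _minjerk(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.asarray(u, float), 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


@dataclass
class GaitParams:
    """Parameters of the synthetic walker.

    Defaults give a comfortable-speed treadmill gait with the baseline
    magnitudes typical of healthy adults (step time 0.55 s, length
    0.68 m, width 0.12 m).  ``landing_lead`` sets how far ahead of the
    pelvis the heel lands, which together with the belt-frame CoM
    velocity fixes the AP margin of stability near 0.17 m.
    """

    comfortable_speed: float = 1.2  # m/s, belt speed
    step_time: float = 0.55  # s
    step_length: float = 0.68  # m
    step_width: float = 0.12  # m
    com_sway_amp: float = 0.02  # m, ML CoM sway amplitude
    trunk_noise_sd: float = 0.0  # m, smooth trunk variability
    marker_noise_sd: float = 0.0  # m, white measurement noise
    dominant_side: str = "R"
    duration: float = 60.0  # s
    seed: int = 0
    fs: float = 100.0  # Hz
    landing_lead: float = 0.27  # m, heel ahead of pelvis at strike
    com_ap_amp: float = 0.01  # m, AP CoM oscillation
    com_vt_amp: float = 0.02  # m, VT CoM oscillation (double bump)
    com_height: float = 0.95  # m
    pelvis_height: float = 0.93  # m
    trochanter_height: float = 1.0  # m -> pendulum length 1.34 m
    trochanter_ml_offset: float = 0.10  # m from pelvis
    trunk_offset: float = 0.30  # m above pelvis
    swing_lift: float = 0.05  # m, heel lift during swing
    malleolus_rise: float = 0.07  # m above heel

    def validate(self) -> None:
        positive = (
            "comfortable_speed",
            "step_time",
            "step_length",
            "step_width",
            "duration",
            "fs",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.duration < 10 * self.step_time:
            raise ValidationError(
                f"duration {self.duration} s too short, need >= 10 steps ({10 * self.step_time} s)"
            )
        if self.dominant_side not in ("L", "R"):
            raise ValidationError(f"dominant_side must be 'L' or 'R', got {self.dominant_side!r}")
        for name in ("com_sway_amp", "trunk_noise_sd", "marker_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def cap_halfwidth(self) -> float:
        """Half-width (s) of the parabolic cap around each heel strike."""
        return min(0.15, 0.3 * 2.0 * self.step_time)

    @property
    def drift_speed(self) -> float:
        """Effective backward stance drift (m/s) that makes the measured
        step length equal the programmed one.

        The parabolic strike cap drifts ``cap_halfwidth / 2`` seconds'
        worth less than the stance line would, so the line runs at
        ``step_length / (step_time - cap_halfwidth / 2)``.
        """
        return self.step_length / (self.step_time - self.cap_halfwidth / 2.0)


@dataclass
class ResponseScript:
    """Scripted deviations for the six post-perturbation steps.

    ``d_step_time`` shifts each post step's duration (s); ``d_mos_ml``
    and ``d_mos_ap`` are deviation *targets* for the margins of
    stability (m), realized through foot placement compensated for the
    perturbation-induced XCoM shift at the strike; ``dx``/``dy`` are
    raw additional ML/AP landing offsets (m).  All sequences have
    length 6 (steps 1D..6ND).
    """

    d_step_time: tuple = (0.0,) * 6
    d_mos_ml: tuple = (0.0,) * 6
    d_mos_ap: tuple = (0.0,) * 6
    dx: tuple = (0.0,) * 6
    dy: tuple = (0.0,) * 6

    def __post_init__(self):
        for name in ("d_step_time", "d_mos_ml", "d_mos_ap", "dx", "dy"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != 6 or not all(np.isfinite(vals)):
                raise ValidationError(f"script field {name} must hold 6 finite values")
            setattr(self, name, vals)

    def l1(self, field_name: str) -> float:
        return float(np.sum(np.abs(getattr(self, field_name))))


#: Default response templates per perturbation type, shaped to the
#: qualitative recovery patterns of lateral-sway and belt perturbation
#: experiments: a narrow cross-step then widening recovery for the
#: contralateral sway, backward instability at the second post step for
#: the deceleration, and no kinematic response to sensory events.
DEFAULT_SCRIPTS = {
    "sway_contra": ResponseScript(
        d_step_time=(0.0, -0.02, -0.03, -0.02, -0.01, 0.0),
        d_mos_ml=(-0.09, -0.04, 0.03, 0.03, 0.02, 0.01),
        d_mos_ap=(0.0, 0.01, 0.02, 0.02, 0.015, 0.01),
    ),
    "sway_ipsi": ResponseScript(
        d_step_time=(0.0, -0.01, -0.01, 0.0, 0.0, 0.0),
        d_mos_ml=(-0.03, -0.02, 0.015, 0.01, 0.005, 0.0),
        d_mos_ap=(0.0, 0.005, 0.01, 0.005, 0.0, 0.0),
    ),
    "belt_dec": ResponseScript(
        d_step_time=(0.0, -0.02, -0.04, -0.03, -0.01, 0.0),
        d_mos_ml=(0.0, 0.01, 0.015, 0.01, 0.005, 0.0),
        d_mos_ap=(-0.08, -0.20, 0.10, 0.07, 0.04, 0.03),
    ),
    "belt_acc": ResponseScript(
        d_step_time=(0.0, -0.01, -0.02, -0.01, 0.0, 0.0),
        d_mos_ml=(0.0, 0.005, 0.01, 0.005, 0.0, 0.0),
        d_mos_ap=(-0.06, 0.04, 0.02, 0.01, 0.0, 0.0),
    ),
    "visual": ResponseScript(),
    "auditory": ResponseScript(),
}


@dataclass
class PerturbationProfileSpec:
    """Profile constants of one perturbation type.

    For sways: ``displacement`` (m), ``duration`` (s), ``a_max``
    (m/s^2) and ``direction`` (+1 toward the participant's right).  For
    belts: ``factor`` (peak/floor speed as a fraction of comfortable
    speed) and ``ramp`` (s).  Sensory types carry descriptive metadata
    only.
    """

    ptype: str
    params: dict = field(default_factory=dict)


def default_spec(ptype: str, dominant_side: str = "R") -> PerturbationProfileSpec:
    """The protocol's profile constants for ``ptype``.

    Sway direction is resolved from dominance: ipsilateral means toward
    the non-dominant side, contralateral toward the dominant side.
    """
    d_sign = 1.0 if dominant_side == "R" else -1.0
    if ptype == "sway_ipsi":
        return PerturbationProfileSpec(ptype, {"displacement": 0.05, "duration": 0.7, "a_max": 2.04, "direction": -d_sign})
    if ptype == "sway_contra":
        return PerturbationProfileSpec(ptype, {"displacement": 0.05, "duration": 0.7, "a_max": 2.04, "direction": d_sign})
    if ptype == "belt_acc":
        return PerturbationProfileSpec(ptype, {"factor": 1.6, "ramp": 0.4})
    if ptype == "belt_dec":
        return PerturbationProfileSpec(ptype, {"factor": 0.4, "ramp": 0.4})
    if ptype == "visual":
        return PerturbationProfileSpec(ptype, {"blackout_s": 5.0, "lux": 1.0})
    if ptype == "auditory":
        return PerturbationProfileSpec(ptype, {"duration_s": 0.5, "level_db": 82.0})
    raise ValidationError(f"unknown perturbation type {ptype!r}")


def make_platform_profile(
    displacement: float = 0.05,
    duration: float = 0.7,
    a_max: float = 2.04,
    direction: float = 1.0,
    fs: float = 100.0,
) -> np.ndarray:
    """Trapezoidal-velocity platform translation sampled at ``fs``.

    Accelerate at ``a_max`` for ``t_a``, coast, decelerate at ``a_max``,
    where ``t_a`` is the smaller root of ``a_max*t_a*(duration-t_a) =
    displacement``; the net displacement is exactly
    ``displacement * direction`` with zero start/end velocity.
    """
    d, T, a = float(displacement), float(duration), float(a_max)
    if d <= 0 or T <= 0 or a <= 0:
        raise InfeasibleProfile("displacement, duration and a_max must be positive")
    disc = T * T - 4.0 * d / a
    if disc < 0:
        raise InfeasibleProfile(
            f"cannot move {d} m in {T} s with peak acceleration {a} m/s^2 "
            f"(need d <= a*(T/2)^2 = {a * (T / 2) ** 2:.4g} m)"
        )
    t_a = 0.5 * (T - np.sqrt(disc))
    v_p = a * t_a
    t = np.arange(int(round(T * fs)) + 1) / fs
    pos = np.where(
        t < t_a,
        0.5 * a * t**2,
        np.where(t < T - t_a, 0.5 * a * t_a**2 + v_p * (t - t_a), d - 0.5 * a * np.maximum(T - t, 0.0) ** 2),
    )
    pos[-1] = d  # exact terminal displacement regardless of grid
    return float(np.sign(direction) if direction else 1.0) * pos


def make_belt_profile(
    v_c: float,
    factor: float,
    ramp: float = 0.4,
    fs: float = 100.0,
    hold: float = 0.55,
) -> np.ndarray:
    """Belt-speed profile: minimum-jerk ramp to ``factor * v_c``, hold, return.

    The extremum speed is exactly ``factor * v_c`` and the peak
    acceleration is ``1.875 * |factor - 1| * v_c / ramp``.
    """
    if factor <= 0:
        raise InfeasibleProfile(f"speed factor must be positive, got {factor}")
    dv = (factor - 1.0) * v_c
    n_ramp = int(round(ramp * fs))
    n_hold = int(round(hold * fs))
    u = np.arange(n_ramp + 1) / n_ramp if n_ramp else np.array([1.0])
    up = v_c + dv * _minjerk(u)
    down = v_c + dv * _minjerk(u[::-1])
    return np.concatenate([up, np.full(n_hold, factor * v_c), down])


def _slow_return_profile(displacement: float, duration: float, fs: float) -> np.ndarray:
    """Minimum-jerk displacement ramp used to re-centre the platform."""
    n = int(round(duration * fs))
    return displacement * _minjerk(np.arange(n + 1) / n)


# ---------------------------------------------------------------------------
# Plan and rendering


@dataclass
class _Plan:
    """Everything needed to render a trial: the strike schedule, landing
    modifiers and perturbation segments."""

    times: np.ndarray  # strike times (s), snapped to the sample grid
    sides: np.ndarray  # '<U1'
    ox: np.ndarray  # extra ML landing offset per strike (m)
    oy: np.ndarray  # extra AP landing offset per strike (m)
    m_ml: np.ndarray  # ML MoS deviation target per strike (nan = none)
    m_ap: np.ndarray  # AP MoS deviation target per strike (nan = none)
    ref: np.ndarray  # reference strike index for compensation (-1 = none)
    platform_segments: list = field(default_factory=list)  # (start_sample, array)
    belt_segments: list = field(default_factory=list)  # (side, start_sample, array)
    events: list = field(default_factory=list)  # PerturbationEvent
    scripts: list = field(default_factory=list)  # (trigger_strike_idx, ResponseScript)

    def copy(self) -> "_Plan":
        return _Plan(
            times=self.times.copy(),
            sides=self.sides.copy(),
            ox=self.ox.copy(),
            oy=self.oy.copy(),
            m_ml=self.m_ml.copy(),
            m_ap=self.m_ap.copy(),
            ref=self.ref.copy(),
            platform_segments=[(s, a.copy()) for s, a in self.platform_segments],
            belt_segments=[(sd, s, a.copy()) for sd, s, a in self.belt_segments],
            events=[replace(e, profile_params=dict(e.profile_params)) for e in self.events],
            scripts=list(self.scripts),
        )


@dataclass
class SyntheticTrial:
    """A rendered trial plus its generation plan and ground truth.

    ``truth`` holds ``strikes`` (DataFrame: sample, time, side),
    ``steps`` (per-step true parameters read from the noiseless
    trajectories) and ``events`` (one dict per injected perturbation
    with its spec, script and trigger strike index).
    """

    params: GaitParams
    plan: _Plan
    trial: Trial
    truth: dict


def _snap(t: float, fs: float) -> float:
    return round(t * fs) / fs


def _base_schedule(params: GaitParams) -> tuple:
    """Nominal alternating strike schedule, first strike at t = 1 s.

    The schedule extends one stride beyond the trial so trajectories
    are defined up to the last sample; strikes outside the recorded
    window are virtual.
    """
    fs, ts = params.fs, params.step_time
    times, sides = [], []
    k = -4  # virtual strikes before t=0 keep early trajectories defined
    while True:
        t = 1.0 + k * ts
        times.append(_snap(t, fs))
        sides.append("L" if k % 2 == 0 else "R")
        if t > params.duration + 2 * ts:
            break
        k += 1
    times = np.array(times)
    sides = np.array(sides)
    n = len(times)
    return times, sides, np.zeros(n), np.zeros(n), np.full(n, np.nan), np.full(n, np.nan), np.full(n, -1, int)


def _platform_channel(plan: _Plan, n: int) -> np.ndarray:
    plat = np.zeros(n)
    for s0, prof in plan.platform_segments:
        s1 = min(s0 + len(prof), n)
        if s0 < n:
            plat[s0:s1] += prof[: s1 - s0]
        if s0 + len(prof) < n:
            plat[s0 + len(prof):] += prof[-1]
        elif s0 >= n:
            continue
    return plat


def _belt_channels(plan: _Plan, params: GaitParams, n: int) -> dict:
    belts = {s: np.full(n, params.comfortable_speed) for s in "LR"}
    for side, s0, prof in plan.belt_segments:
        s1 = min(s0 + len(prof), n)
        if s0 < n:
            belts[side][s0:s1] = prof[: s1 - s0]
    return belts


def _phase(t: np.ndarray, plan: _Plan, params: GaitParams) -> np.ndarray:
    """Step phase theta(t): piecewise linear, k*pi at the k-th strike."""
    knots = plan.times
    vals = np.arange(len(knots)) * np.pi
    rate = np.pi / params.step_time
    pad_t = np.concatenate([[knots[0] - 1e4], knots, [knots[-1] + 1e4]])
    pad_v = np.concatenate([[vals[0] - 1e4 * rate], vals, [vals[-1] + 1e4 * rate]])
    return np.interp(t, pad_t, pad_v)


def _render(params: GaitParams, plan: _Plan) -> SyntheticTrial:
    import pandas as pd

    fs = params.fs
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    v_eff = params.drift_speed
    delta = params.cap_halfwidth
    omega0 = np.sqrt(9.81 / (params.trochanter_height * 1.34))

    plat = _platform_channel(plan, n)
    if np.max(np.abs(plat)) > MAX_PLATFORM_EXCURSION + 1e-9:
        raise ExcursionExceeded(
            f"platform excursion {np.max(np.abs(plat)):.3f} m exceeds "
            f"+-{MAX_PLATFORM_EXCURSION} m"
        )
    belts = _belt_channels(plan, params, n)

    theta = _phase(t, plan, params)
    s1 = 1.0 if plan.sides[0] == "R" else -1.0
    com = np.empty((n, 3))
    com[:, 0] = s1 * params.com_sway_amp * np.sin(theta) + plat
    com[:, 1] = params.com_ap_amp * np.cos(2.0 * theta)
    com[:, 2] = params.com_height + params.com_vt_amp * np.cos(2.0 * theta)

    # XCoM exactly as the pipeline computes it (central differences,
    # stance-side belt speed added to AP), used to compensate scripted
    # foot placement so MoS deviation targets are met exactly.
    vel = np.gradient(com, 1.0 / fs, axis=0)
    strike_samples_all = np.round(plan.times * fs).astype(int)
    idx = np.searchsorted(strike_samples_all, np.arange(n), side="right") - 1
    stance_sides = np.where(
        idx < 0,
        "L" if plan.sides[0] == "R" else "R",
        plan.sides[np.clip(idx, 0, len(plan.sides) - 1)],
    )
    belt_at = np.where(stance_sides == "L", belts["L"], belts["R"])
    xcom_ml = com[:, 0] + vel[:, 0] / omega0
    xcom_ap = com[:, 1] + (vel[:, 1] + belt_at) / omega0

    # Landing positions per strike, with scripted compensation.
    n_strikes = len(plan.times)
    x_land = np.empty(n_strikes)
    y_land = np.empty(n_strikes)
    for k in range(n_strikes):
        sgn = 1.0 if plan.sides[k] == "R" else -1.0
        x = sgn * params.step_width / 2.0 + plan.ox[k]
        y = params.landing_lead + plan.oy[k]
        sk = strike_samples_all[k]
        rk = plan.ref[k]
        if rk >= 0 and 0 <= sk < n:
            sr = strike_samples_all[rk]
            if np.isfinite(plan.m_ml[k]):
                x += sgn * plan.m_ml[k] + (xcom_ml[sk] - plat[sk]) - (xcom_ml[sr] - plat[sr])
            if np.isfinite(plan.m_ap[k]):
                y += -plan.m_ap[k] + (xcom_ap[sk] - xcom_ap[sr])
        x_land[k] = x
        y_land[k] = y

    # Belt "extra drift" per side, integrated for stance trajectories.
    extra_cum = {
        s: np.concatenate([[0.0], np.cumsum(belts[s] - params.comfortable_speed)]) / fs for s in "LR"
    }

    heel = {}
    for side in "LR":
        mask = plan.sides == side
        heel[side] = _foot_track(
            plan.times[mask], x_land[mask], y_land[mask], params, extra_cum[side], n
        )

    markers = {}
    for side in "LR":
        hx, hy, hz = heel[side]
        heel_xyz = np.column_stack([hx + plat, hy, hz])
        markers[f"heel_{side}"] = heel_xyz
        markers[f"malleolus_{side}"] = heel_xyz + np.array([0.0, 0.0, params.malleolus_rise])

    pelvis = np.column_stack(
        [com[:, 0], com[:, 1], params.pelvis_height + params.com_vt_amp * np.cos(2.0 * theta)]
    )
    markers["pelvis"] = pelvis
    off = params.trochanter_ml_offset
    markers["trochanter_L"] = pelvis + np.array([-off, 0.0, params.trochanter_height - params.pelvis_height])
    markers["trochanter_R"] = pelvis + np.array([off, 0.0, params.trochanter_height - params.pelvis_height])

    rng = np.random.default_rng(params.seed)
    trunk = pelvis + np.array([0.0, 0.0, params.trunk_offset])
    if params.trunk_noise_sd > 0:
        trunk = trunk + _smooth_noise(rng, (n, 3), params.trunk_noise_sd, fs)
    markers["trunk"] = trunk

    # Ground truth from the noiseless channels.
    in_window = (strike_samples_all >= 0) & (strike_samples_all <= n - 2)
    tr_samples = strike_samples_all[in_window]
    tr_sides = plan.sides[in_window]
    tr_index = np.flatnonzero(in_window)
    strikes = pd.DataFrame({"strike": tr_index, "sample": tr_samples, "time": tr_samples / fs, "side": tr_sides})

    step_rows = []
    for a, b in zip(tr_index[:-1], tr_index[1:]):
        sb = strike_samples_all[b]
        side = plan.sides[b]
        lead, trail = heel[side], heel["L" if side == "R" else "R"]
        d_s = 1.0 if side == "R" else -1.0
        step_rows.append(
            {
                "hs_sample": int(sb),
                "side": side,
                "step_time": (strike_samples_all[b] - strike_samples_all[a]) / fs,
                "step_length": lead[1][sb] - trail[1][sb],
                "step_width": abs(lead[0][sb] - trail[0][sb]),
                "mos_ml": d_s * (lead[0][sb] + plat[sb] + 0.0 - xcom_ml[sb]),
                "mos_ap": xcom_ap[sb] - lead[1][sb],
            }
        )
    steps = pd.DataFrame(step_rows)

    if params.marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(0.0, params.marker_noise_sd, markers[name].shape)

    trial = Trial(
        fs=fs,
        t=t,
        markers=markers,
        com=com,
        belt_speed_L=belts["L"],
        belt_speed_R=belts["R"],
        platform_ml=plat,
        meta=TrialMeta(
            dominant_side=params.dominant_side,
            comfortable_speed=params.comfortable_speed,
            subject_id=f"synthetic-{params.seed}",
            group="synthetic",
        ),
        events_log=[replace(e, profile_params=dict(e.profile_params)) for e in plan.events],
    )
    truth = {
        "strikes": strikes,
        "steps": steps,
        "events": [
            {"event": e, "trigger_strike": trig, "script": script}
            for e, (trig, script) in zip(plan.events, plan.scripts)
        ],
        "omega0": float(omega0),
    }
    return SyntheticTrial(params=params, plan=plan, trial=trial, truth=truth)


def _foot_track(
    times: np.ndarray,
    x_land: np.ndarray,
    y_land: np.ndarray,
    params: GaitParams,
    extra_cum: np.ndarray,
    n: int,
) -> tuple:
    """Render one foot's (ML, AP, VT) heel trajectory from its strike
    schedule and landing positions."""
    fs = params.fs
    v = params.drift_speed
    delta = params.cap_halfwidth
    x = np.zeros(n)
    y = np.zeros(n)
    z = np.zeros(n)

    def sample_range(t0, t1):
        a = max(int(np.ceil(t0 * fs - 1e-9)), 0)
        b = min(int(np.ceil(t1 * fs - 1e-9)), n)
        return a, b

    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        stride = t1 - t0
        t_lift = STANCE_FRACTION * stride
        t_app = stride - delta
        a, b = sample_range(t0, t1)
        if a >= b:
            continue
        tt = np.arange(a, b) / fs - t0  # phase within the segment

        yy = np.empty(b - a)
        xx = np.empty(b - a)
        zz = np.zeros(b - a)

        cap1 = tt < delta
        stance = (tt >= delta) & (tt < t_lift)
        swing = (tt >= t_lift) & (tt < t_app)
        cap2 = tt >= t_app

        # symmetric parabola over +-delta around the strike: the 6 Hz
        # zero-phase filter passes it without peak loss or shift
        yy[cap1] = y_land[i] - (v / (2.0 * delta)) * tt[cap1] ** 2
        # belt-induced extra drift, measured from the end of the cap
        s_cap = min(max(int(np.ceil((t0 + delta) * fs - 1e-9)), 0), n)
        e_ref = extra_cum[s_cap]
        e_here = extra_cum[np.arange(a, b)]
        yy[stance] = y_land[i] + v * delta / 2.0 - v * tt[stance] - (e_here[stance] - e_ref)

        s_lift = min(max(int(round((t0 + t_lift) * fs)), 0), n)
        e_lift = extra_cum[s_lift] - e_ref
        belt_extra_rate = (extra_cum[min(s_lift + 1, n)] - extra_cum[max(s_lift - 1, 0)]) * fs / 2.0
        y_lift = y_land[i] + v * delta / 2.0 - v * t_lift - e_lift
        y_app = y_land[i + 1] - v * delta / 2.0
        poly_y = BPoly.from_derivatives(
            [t_lift, t_app],
            [[y_lift, -v - belt_extra_rate, 0.0, 0.0], [y_app, v, -v / delta, 0.0]],
        )
        yy[swing] = poly_y(tt[swing])
        yy[cap2] = y_land[i + 1] - (v / (2.0 * delta)) * (stride - tt[cap2]) ** 2

        xx[cap1 | stance] = x_land[i]
        poly_x = BPoly.from_derivatives(
            [t_lift, t_app],
            [[x_land[i], 0.0, 0.0, 0.0], [x_land[i + 1], 0.0, 0.0, 0.0]],
        )
        xx[swing] = poly_x(tt[swing])
        xx[cap2] = x_land[i + 1]

        u = (tt[swing] - t_lift) / (t_app - t_lift)
        zz[swing] = params.swing_lift * np.sin(np.pi * u) ** 2

        x[a:b], y[a:b], z[a:b] = xx, yy, zz
    return x, y, z


def _smooth_noise(rng: np.random.Generator, shape: tuple, sd: float, fs: float, fc: float = 3.0) -> np.ndarray:
    """Band-limited Gaussian noise emulating slow physiological
    variability (white noise low-passed at ``fc`` and rescaled)."""
    from scipy import signal as sps

    white = rng.normal(0.0, 1.0, shape)
    b, a = sps.butter(4, fc / (fs / 2.0), btype="low")
    smooth = sps.filtfilt(b, a, white, axis=0)
    std = smooth.std(axis=0, keepdims=True)
    std[std == 0] = 1.0
    return smooth / std * sd


# ---------------------------------------------------------------------------
# Public generator API


def make_gait_trial(params: GaitParams | None = None, **overrides) -> SyntheticTrial:
    """Generate an unperturbed treadmill walking trial with ground truth."""
    if params is None:
        params = GaitParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    params.validate()
    plan = _Plan(*_base_schedule(params))
    return _render(params, plan)


def inject_perturbation(
    syn: SyntheticTrial,
    spec: PerturbationProfileSpec,
    script: ResponseScript | None = None,
    at_stride: int = 10,
    repetition_index: int = 1,
    auto_return: bool = True,
) -> SyntheticTrial:
    """Inject one perturbation at the non-dominant heel strike of
    ``at_stride`` and re-render the trial.

    Sways add a platform translation to every marker, the CoM and the
    platform channel (and, with ``auto_return``, schedule a slow
    re-centring ramp after the response window); belt perturbations
    replace the non-dominant belt-speed profile, which the stance foot
    follows.  The script's deviations are applied to the six
    post-perturbation steps.  Raises :class:`ExcursionExceeded` when
    the platform bound would be violated.
    """
    params = syn.params
    fs = params.fs
    plan = syn.plan.copy()
    if script is None:
        script = DEFAULT_SCRIPTS.get(spec.ptype, ResponseScript())

    nd = "L" if params.dominant_side == "R" else "R"
    cands = np.flatnonzero(plan.sides == nd)
    cands = cands[cands >= 2 * at_stride]
    if cands.size == 0 or plan.times[cands[0]] > params.duration - 8 * params.step_time:
        raise ValidationError(f"no usable non-dominant heel strike at stride {at_stride}")
    trig = int(cands[0])
    if trig + 6 >= len(plan.times):
        raise ValidationError("trial too short for six post-perturbation steps")
    t_trig = plan.times[trig]
    s_trig = int(round(t_trig * fs))

    # Step-time script: shift subsequent strikes cumulatively.
    shift = 0.0
    for k, dt in enumerate(script.d_step_time, start=1):
        shift += dt
        if trig + k < len(plan.times):
            plan.times[trig + k] = _snap(plan.times[trig + k] + shift, fs)
    if shift:
        for k in range(trig + 7, len(plan.times)):
            plan.times[k] = _snap(plan.times[k] + shift, fs)
    if np.any(np.diff(plan.times) <= 0):
        raise ValidationError("scripted step times make the strike schedule non-monotonic")

    # Foot-placement script with XCoM compensation references; zero
    # deviations are skipped so empty scripts leave the plan untouched.
    for k in range(1, 7):
        j = trig + k
        plan.ox[j] += script.dx[k - 1]
        plan.oy[j] += script.dy[k - 1]
        if script.d_mos_ml[k - 1] != 0.0:
            plan.m_ml[j] = script.d_mos_ml[k - 1]
        if script.d_mos_ap[k - 1] != 0.0:
            plan.m_ap[j] = script.d_mos_ap[k - 1]
        if script.d_mos_ml[k - 1] != 0.0 or script.d_mos_ap[k - 1] != 0.0:
            plan.ref[j] = trig if plan.sides[j] == nd else trig - 1

    if spec.ptype in ("sway_ipsi", "sway_contra"):
        p = spec.params
        prof = make_platform_profile(p["displacement"], p["duration"], p["a_max"], p["direction"], fs)
        plan.platform_segments.append((s_trig, prof))
        if auto_return:
            ret = _slow_return_profile(-p["displacement"] * np.sign(p["direction"]), 3.0, fs)
            plan.platform_segments.append((s_trig + int(round(8 * params.step_time * fs)), ret))
        # hardware bound, checked on the scheduled segments
        n = int(round(params.duration * fs))
        test = _platform_channel(plan, n)
        if np.max(np.abs(test)) > MAX_PLATFORM_EXCURSION + 1e-9:
            raise ExcursionExceeded(
                f"scheduled platform excursion {np.max(np.abs(test)):.3f} m exceeds "
                f"+-{MAX_PLATFORM_EXCURSION} m"
            )
    elif spec.ptype in ("belt_acc", "belt_dec"):
        p = spec.params
        prof = make_belt_profile(params.comfortable_speed, p["factor"], p["ramp"], fs, hold=params.step_time)
        plan.belt_segments.append((nd, s_trig, prof))
    elif spec.ptype not in ("visual", "auditory"):
        raise ValidationError(f"unknown perturbation type {spec.ptype!r}")

    plan.events.append(
        PerturbationEvent(
            ptype=spec.ptype,
            trigger_time=t_trig,
            trigger_sample=s_trig,
            repetition_index=repetition_index,
            profile_params=dict(spec.params),
        )
    )
    plan.scripts.append((trig, script))
    return _render(params, plan)


def make_session(
    seed: int = 0,
    params: GaitParams | None = None,
    scripts: dict | None = None,
    ptypes: tuple = ("sway_ipsi", "sway_contra", "belt_acc", "belt_dec", "visual", "auditory"),
    n_repetitions: int = 4,
    first_stride: int = 8,
    spacing_strides: int = 21,
    baseline_strides: int = 112,
) -> dict:
    """One experimental session: a baseline trial plus one trial per
    perturbation type with ``n_repetitions`` triggers each.

    Trials are returned in a seed-determined pseudo-random order
    (mapping ptype -> :class:`SyntheticTrial`, plus ``"baseline"``;
    the presentation order is recorded under ``"order"``).  Repetition
    triggers are spaced ``spacing_strides`` strides apart, leaving at
    least 15 washout strides between response windows, and sway trials
    re-centre the platform after each response so the 15 cm excursion
    bound is respected.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = GaitParams(seed=seed)
    scripts = dict(DEFAULT_SCRIPTS, **(scripts or {}))

    baseline_duration = 2.0 + baseline_strides * 2 * params.step_time
    baseline = make_gait_trial(replace(params, duration=baseline_duration, seed=int(rng.integers(2**31 - 1))))

    last_stride = first_stride + (n_repetitions - 1) * spacing_strides
    trial_duration = 2.0 + (last_stride + 10) * 2 * params.step_time

    session = {"baseline": baseline}
    order = list(ptypes)
    rng.shuffle(order)
    for ptype in order:
        syn = make_gait_trial(replace(params, duration=trial_duration, seed=int(rng.integers(2**31 - 1))))
        spec = default_spec(ptype, params.dominant_side)
        for rep in range(n_repetitions):
            syn = inject_perturbation(
                syn,
                spec,
                script=scripts.get(ptype),
                at_stride=first_stride + rep * spacing_strides,
                repetition_index=rep + 1,
            )
        session[ptype] = syn
    session["order"] = order
    return session
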