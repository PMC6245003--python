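"""Margins of stability and spatio-temporal gait parameters.

The extrapolated centre of mass (XCoM) is the CoM position plus its
horizontal velocity divided by the inverted-pendulum eigenfrequency
``omega0 = sqrt(g / l)``, with pendulum length ``l`` taken as the mean
greater-trochanter marker height times 1.34.  Margins of stability
(MoS) are signed distances from the XCoM to the base-of-support border
of the leading foot at heel strike:

* ML MoS: lateral-malleolus ML position minus XCoM ML, signed so that
  positive means the malleolus lies lateral to the XCoM;
* AP MoS: XCoM AP minus the leading heel AP, so that stepping further
  behind the XCoM gives a larger (more backward-stable) margin.

Negative values indicate instability laterally / backward.

On a treadmill the lab-frame CoM velocity averages ~0, which would make
AP margins meaningless, so CoM velocity is expressed in the belt frame
by default: the stance-side belt speed is added to the AP component
(the stance side is the side of the most recent heel strike).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientBaseline, NonFiniteInput
from .preprocess import DEFAULT_CUTOFF, GaitEvents, detect_heel_strikes, lowpass_filter, segment_steps
from .trajectory_io import Trial

#: Gravitational acceleration (m/s^2).
GRAVITY = 9.81

#: Ratio of equivalent pendulum length to trochanter height.
PENDULUM_LENGTH_FACTOR = 1.34

#: Gait parameters carried per step throughout the pipeline.
GAIT_PARAMETERS = ("step_time", "step_length", "step_width", "mos_ml", "mos_ap")


@dataclass
class XcomParams:
    """Inverted-pendulum constants for the XCoM estimate."""

    l: float  # pendulum length (m)
    g: float = GRAVITY

    @property
    def omega0(self) -> float:
        """Pendulum eigenfrequency sqrt(g/l) (1/s)."""
        return float(np.sqrt(self.g / self.l))

    @classmethod
    def from_trial(cls, trial: Trial, g: float = GRAVITY) -> "XcomParams":
        """Pendulum length from the time-averaged height of both trochanter markers."""
        height = 0.5 * (
            float(np.mean(trial.marker("trochanter_L")[:, 2]))
            + float(np.mean(trial.marker("trochanter_R")[:, 2]))
        )
        return cls(l=height * PENDULUM_LENGTH_FACTOR, g=g)


@dataclass
class StepRecord:
    """One step: timing, geometry, margins and peri-perturbation label."""

    side: str
    hs_sample: int
    step_time: float
    step_length: float
    step_width: float
    mos_ml: float
    mos_ap: float
    role: str = "other"  # {baseline, pre, post, other}
    label: str = "none"  # {BD, BND, PD, NPD, 1D..6ND, none}


def stance_side_samples(events: GaitEvents, n_samples: int) -> np.ndarray:
    """Side ('L'/'R') of the most recent heel strike, per sample.

    Samples before the first strike are assigned the opposite of the
    first striking side (that foot must have been in stance).
    """
    idx = np.searchsorted(events.samples, np.arange(n_samples), side="right") - 1
    sides = np.empty(n_samples, dtype="<U1")
    first = str(events.sides[0])
    sides[idx < 0] = "L" if first == "R" else "R"
    valid = idx >= 0
    sides[valid] = events.sides[idx[valid]]
    return sides


def com_velocity(
    trial: Trial,
    frame: str = "belt",
    events: GaitEvents | None = None,
    com: np.ndarray | None = None,
) -> np.ndarray:
    """Central-difference CoM velocity, in the lab or belt frame.

    In the belt frame (default) the stance-side belt speed is added to
    the AP component at every sample, mimicking overground progression.
    ``com`` may supply an already-filtered CoM series; otherwise the raw
    trial channel is differentiated.
    """
    if frame not in ("belt", "lab"):
        raise ValueError(f"frame must be 'belt' or 'lab', got {frame!r}")
    com = trial.com if com is None else np.asarray(com, float)
    vel = np.gradient(com, 1.0 / trial.fs, axis=0)
    if frame == "belt":
        if events is None:
            events = detect_heel_strikes(trial)
        stance = stance_side_samples(events, trial.n_samples)
        belt = np.where(stance == "L", trial.belt_speed_L, trial.belt_speed_R)
        vel = vel.copy()
        vel[:, 1] += belt
    return vel


def compute_xcom(com_position: np.ndarray, com_velocity: np.ndarray, params: XcomParams) -> np.ndarray:
    """XCoM horizontal series: ``com + v / omega0`` for the ML and AP axes.

    Returns an (N, 2) array with columns (ML, AP).
    """
    pos = np.asarray(com_position, float)
    vel = np.asarray(com_velocity, float)
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel))):
        raise NonFiniteInput("CoM position/velocity contain non-finite values")
    if pos.shape != vel.shape:
        raise ValueError(f"position {pos.shape} and velocity {vel.shape} shapes differ")
    return pos[:, :2] + vel[:, :2] / params.omega0


def compute_step_mos(
    trial: Trial,
    events: GaitEvents,
    params: XcomParams | None = None,
    frame: str = "belt",
    fc: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Per-step ML and AP margins of stability at the terminating heel strike.

    The leading foot is the striking foot.  Marker and CoM channels are
    low-pass filtered internally at ``fc``.  Returns one row per step
    (N-1 rows for N heel strikes) with columns ``hs_sample, side,
    mos_ml, mos_ap``.
    """
    if params is None:
        params = XcomParams.from_trial(trial)
    fs = trial.fs
    com_f = lowpass_filter(trial.com, fs, fc)
    vel = com_velocity(trial, frame=frame, events=events, com=com_f)
    xcom = compute_xcom(com_f, vel, params)
    mall_x = {s: lowpass_filter(trial.marker(f"malleolus_{s}")[:, 0], fs, fc) for s in "LR"}
    heel_y = {s: lowpass_filter(trial.marker(f"heel_{s}")[:, 1], fs, fc) for s in "LR"}

    rows = []
    for start, end, side in segment_steps(events):
        d_s = 1.0 if side == "R" else -1.0
        rows.append(
            {
                "hs_sample": end,
                "side": side,
                "mos_ml": d_s * (mall_x[side][end] - xcom[end, 0]),
                "mos_ap": xcom[end, 1] - heel_y[side][end],
            }
        )
    return pd.DataFrame(rows, columns=["hs_sample", "side", "mos_ml", "mos_ap"])


def spatiotemporal(trial: Trial, events: GaitEvents, fc: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Per-step step time, length and width.

    Step time is the interval between consecutive heel strikes; step
    length (AP) and width (ML) are the distances between the two heel
    markers evaluated at the instant of the terminating heel strike
    (same-instant convention — on a treadmill the between-event lab
    displacement would be near zero).
    """
    fs = trial.fs
    heel = {s: lowpass_filter(trial.marker(f"heel_{s}")[:, :2], fs, fc) for s in "LR"}
    rows = []
    for start, end, side in segment_steps(events):
        lead, trail = (heel[side], heel["L" if side == "R" else "R"])
        rows.append(
            {
                "hs_sample": end,
                "side": side,
                "step_time": (end - start) / fs,
                "step_length": lead[end, 1] - trail[end, 1],
                "step_width": abs(lead[end, 0] - trail[end, 0]),
            }
        )
    return pd.DataFrame(rows, columns=["hs_sample", "side", "step_time", "step_length", "step_width"])


def step_table(
    trial: Trial,
    events: GaitEvents | None = None,
    params: XcomParams | None = None,
    frame: str = "belt",
    fc: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Tidy per-step table: spatio-temporal parameters joined with margins.

    Columns: ``hs_sample, side, step_time, step_length, step_width,
    mos_ml, mos_ap``, one row per step in temporal order.
    """
    if events is None:
        events = detect_heel_strikes(trial)
    st = spatiotemporal(trial, events, fc=fc)
    mos = compute_step_mos(trial, events, params=params, frame=frame, fc=fc)
    return st.merge(mos, on=["hs_sample", "side"], validate="one_to_one")


def step_records(steps: pd.DataFrame) -> list:
    """Convert a step table to a list of :class:`StepRecord`."""
    return [
        StepRecord(
            side=row.side,
            hs_sample=int(row.hs_sample),
            step_time=row.step_time,
            step_length=row.step_length,
            step_width=row.step_width,
            mos_ml=row.mos_ml,
            mos_ap=row.mos_ap,
            role=getattr(row, "role", "other"),
            label=getattr(row, "label", "none"),
        )
        for row in steps.itertuples()
    ]


@dataclass
class BaselineSummary:
    """Mean and SD of each gait parameter over baseline steps per side.

    ``stats`` is indexed by parameter with columns ``mean_D, sd_D,
    mean_ND, sd_ND``; BD denotes dominant, BND non-dominant baseline
    steps.
    """

    stats: pd.DataFrame
    n_steps: dict  # side label ('D'/'ND') -> count used
    dominant_side: str

    def mean(self, parameter: str, side: str) -> float:
        """Baseline mean; ``side`` is 'D' or 'ND'."""
        return float(self.stats.loc[parameter, f"mean_{side}"])

    def sd(self, parameter: str, side: str) -> float:
        return float(self.stats.loc[parameter, f"sd_{side}"])


def baseline_summary(
    steps: pd.DataFrame,
    dominant_side: str,
    n_per_side: int = 100,
    warmup_strides: int = 5,
) -> BaselineSummary:
    """Average gait parameters over the first ``n_per_side`` consecutive
    steps of each side, after skipping a warm-up of ``warmup_strides``
    strides (2 steps per stride).

    Raises :class:`InsufficientBaseline` when either side has fewer
    than ``n_per_side`` steps after the warm-up.
    """
    usable = steps.iloc[2 * warmup_strides:]
    nd_side = "L" if dominant_side == "R" else "R"
    out = {}
    counts = {}
    for label, side in (("D", dominant_side), ("ND", nd_side)):
        sel = usable[usable["side"] == side].iloc[:n_per_side]
        if len(sel) < n_per_side:
            raise InsufficientBaseline(
                f"only {len(sel)} {label} steps after warm-up, need {n_per_side}"
            )
        counts[label] = len(sel)
        out[f"mean_{label}"] = sel[list(GAIT_PARAMETERS)].mean()
        out[f"sd_{label}"] = sel[list(GAIT_PARAMETERS)].std(ddof=1)
    stats = pd.DataFrame(out)
    stats.index.name = "parameter"
    return BaselineSummary(stats=stats, n_steps=counts, dominant_side=dominant_side)
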