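"""Local dynamic stability of trunk velocity.

Quantifies how fast infinitesimally close trunk-velocity states diverge
during steady walking: lower divergence exponents imply gait that is
more resistant to the small internal perturbations of neuromuscular
control.  The procedure is the nearest-neighbour divergence method:

1. trunk marker velocity per axis (ML, AP, VT) over 100 strides,
2. time normalization of the whole segment to a fixed 10,000 samples
   (total-duration normalization: stride-to-stride temporal variability
   is preserved in sample space),
3. delay embedding into a 5-dimensional state space (delay 10 samples),
4. for every state, the nearest Euclidean neighbour at least a Theiler
   window away in time; the mean log separation of these pairs is
   tracked forward to form the divergence curve,
5. the exponent is the least-squares slope of the curve over 0-0.5
   stride, rescaled to divergence per stride.

The embedding dimension, delay, Theiler window and fit range are
conventions of the gait literature rather than uniquely determined
quantities; they are configurable and the defaults are documented in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .errors import InsufficientStrides, MissingChannel, NoNeighbours, TooShort
from .preprocess import DEFAULT_CUTOFF, GaitEvents, lowpass_filter
from .trajectory_io import Trial

#: Numerical floor for separations before taking the log (perfectly
#: periodic synthetic signals can produce exactly coincident states).
_LOG_FLOOR = 1e-15

AXIS_NAMES = ("ML", "AP", "VT")


@dataclass
class LdsConfig:
    """Tuning constants of the divergence-exponent estimate."""

    n_strides: int = 100
    samples_per_stride: int = 100
    embed_dim: int = 5
    embed_delay: int = 10  # samples (normalized time base)
    theiler_window: int = 50  # half a normalized stride
    fit_start: int = 0  # normalized samples
    fit_stop: int = 50  # 0.5 stride
    horizon: int = 100  # curve length, one stride

    @property
    def n_samples(self) -> int:
        return self.n_strides * self.samples_per_stride


@dataclass
class LdsResult:
    """Divergence exponent per axis (per stride) plus the raw curves."""

    lam: dict  # axis -> exponent (1/stride)
    curves: dict = field(default_factory=dict)  # axis -> (horizon+1,) mean log divergence
    n_strides: int = 0


def trunk_velocity(trial: Trial, fc: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Central-difference velocity of the trunk marker, (N, 3).

    The trunk channel receives the global marker low-pass only; no
    further smoothing is applied to the velocity.
    """
    if "trunk" not in trial.markers:
        raise MissingChannel("trial has no trunk marker")
    pos = lowpass_filter(trial.markers["trunk"], trial.fs, fc)
    return np.gradient(pos, 1.0 / trial.fs, axis=0)


def time_normalize(series: np.ndarray, events: GaitEvents, cfg: LdsConfig) -> np.ndarray:
    """Resample the first ``n_strides`` strides to ``n_strides * samples_per_stride``.

    The segment runs from the first heel strike to the heel strike
    2*n_strides events later (a stride is two steps) and is resampled
    as a whole by cubic interpolation, so strides keep their unequal
    durations in the normalized series.
    """
    series = np.asarray(series, float)
    need = 2 * cfg.n_strides
    if events.n_events < need + 1:
        raise InsufficientStrides(
            f"{(events.n_events - 1) // 2} strides available, need {cfg.n_strides}"
        )
    s0, s1 = int(events.samples[0]), int(events.samples[need])
    seg = series[s0 : s1 + 1]
    x_old = np.arange(seg.shape[0], dtype=float)
    x_new = np.linspace(0.0, x_old[-1], cfg.n_samples)
    return CubicSpline(x_old, seg, axis=0)(x_new)


def delay_embed(series: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Time-delay embedding: state[t] = (x[t], x[t+tau], ..., x[t+(m-1)tau])."""
    series = np.asarray(series, float).ravel()
    n = series.size - (dim - 1) * delay
    if n <= 0:
        raise TooShort(
            f"series of length {series.size} too short for dim={dim}, delay={delay}"
        )
    return np.column_stack([series[k * delay : k * delay + n] for k in range(dim)])


def divergence_curve(states: np.ndarray, theiler: int, horizon: int) -> np.ndarray:
    """Mean log separation of nearest-neighbour pairs versus look-ahead time.

    For each state the nearest Euclidean neighbour with index separation
    greater than ``theiler`` is found; ``curve[dt]`` is the mean over
    pairs of ``ln || s[i+dt] - s[j+dt] ||``, pairs running past the end
    of the series being dropped from the mean at that ``dt``.
    """
    states = np.asarray(states, float)
    n = states.shape[0]
    if n <= 2 * theiler:
        raise NoNeighbours(f"{n} states cannot contain pairs separated by > {theiler}")
    tree = cKDTree(states)
    # Enough candidates to guarantee at least one outside the Theiler window.
    k = min(2 * theiler + 2, n)
    dist, idx = tree.query(states, k=k)
    anchors = np.arange(n)
    neigh = np.full(n, -1)
    for col in range(1, k):
        unset = neigh < 0
        ok = unset & (np.abs(idx[:, col] - anchors) > theiler)
        neigh[ok] = idx[ok, col]
    valid = neigh >= 0
    if not np.any(valid):
        raise NoNeighbours("no admissible neighbour outside the Theiler window")
    i, j = anchors[valid], neigh[valid]

    curve = np.empty(horizon + 1)
    for dt in range(horizon + 1):
        keep = (i + dt < n) & (j + dt < n)
        if not np.any(keep):
            curve[dt] = np.nan
            continue
        sep = np.linalg.norm(states[i[keep] + dt] - states[j[keep] + dt], axis=1)
        curve[dt] = float(np.mean(np.log(np.maximum(sep, _LOG_FLOOR))))
    return curve


def lds(trial: Trial, events: GaitEvents, cfg: LdsConfig | None = None) -> LdsResult:
    """Divergence exponent of trunk velocity per axis over ``cfg.n_strides`` strides.

    The exponent is the least-squares slope of the divergence curve over
    ``[fit_start, fit_stop]`` normalized samples, times
    ``samples_per_stride`` (units: divergence per stride).
    """
    if cfg is None:
        cfg = LdsConfig()
    vel = trunk_velocity(trial)
    lam, curves = {}, {}
    for ax, name in enumerate(AXIS_NAMES):
        norm = time_normalize(vel[:, ax], events, cfg)
        states = delay_embed(norm, cfg.embed_dim, cfg.embed_delay)
        curve = divergence_curve(states, cfg.theiler_window, cfg.horizon)
        span = np.arange(cfg.fit_start, cfg.fit_stop + 1)
        slope = np.polyfit(span, curve[span], 1)[0]
        lam[name] = float(slope * cfg.samples_per_stride)
        curves[name] = curve
    return LdsResult(lam=lam, curves=curves, n_strides=cfg.n_strides)
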