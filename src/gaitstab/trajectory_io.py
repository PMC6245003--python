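"""Trial container and tabular I/O.

A :class:`Trial` bundles the synchronized kinematic channels of one
treadmill walking trial: 3-D marker trajectories, a whole-body
centre-of-mass (CoM) channel, the two belt-speed channels, the
medio-lateral platform displacement and a perturbation event log.

Axis convention (internal to this package, fixed everywhere):

* X = medio-lateral (ML), positive toward the participant's right,
* Y = anterior-posterior (AP), positive in the progression direction,
* Z = vertical (VT), positive up.

All positions are in meters, speeds in m/s, sampling in Hz.  A positive
belt speed means the belt surface moves backward under the participant.

The native on-disk format is a plain TSV (one row per sample, one column
per channel-axis) with two sidecars: ``<stem>.events.tsv`` for the
perturbation log and ``<stem>.meta.json`` for trial metadata.  C3D
ingest is optional and requires the ``ezc3d`` extra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BadTimeBase, MissingChannel

#: Marker names every trial must provide.
REQUIRED_MARKERS = (
    "heel_L",
    "heel_R",
    "malleolus_L",
    "malleolus_R",
    "trochanter_L",
    "trochanter_R",
    "pelvis",
    "trunk",
)

AXES = ("x", "y", "z")

#: Recognised perturbation types.
PERTURBATION_TYPES = (
    "sway_ipsi",
    "sway_contra",
    "belt_acc",
    "belt_dec",
    "visual",
    "auditory",
)


@dataclass
class PerturbationEvent:
    """One perturbation trigger within a trial.

    ``trigger_sample`` is authoritative; ``trigger_time`` is kept for
    readability.  ``repetition_index`` counts 1..4 within a trial.
    """

    ptype: str
    trigger_time: float
    trigger_sample: int
    repetition_index: int
    profile_params: dict = field(default_factory=dict)


@dataclass
class TrialMeta:
    dominant_side: str = "R"  # "L" or "R"
    comfortable_speed: float = 1.2  # m/s
    subject_id: str = "synthetic"
    group: str = "synthetic"  # {young, older, synthetic}

    @property
    def nondominant_side(self) -> str:
        return "L" if self.dominant_side == "R" else "R"


@dataclass
class Trial:
    """Synchronized multichannel recording of one treadmill trial."""

    fs: float
    t: np.ndarray  # (N,) seconds
    markers: dict  # name -> (N, 3) meters
    com: np.ndarray  # (N, 3) meters
    belt_speed_L: np.ndarray  # (N,) m/s
    belt_speed_R: np.ndarray  # (N,) m/s
    platform_ml: np.ndarray  # (N,) meters
    meta: TrialMeta = field(default_factory=TrialMeta)
    events_log: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    def marker(self, name: str) -> np.ndarray:
        try:
            return self.markers[name]
        except KeyError:
            raise MissingChannel(f"marker {name!r} not present in trial")

    def copy(self) -> "Trial":
        return replace(
            self,
            t=self.t.copy(),
            markers={k: v.copy() for k, v in self.markers.items()},
            com=self.com.copy(),
            belt_speed_L=self.belt_speed_L.copy(),
            belt_speed_R=self.belt_speed_R.copy(),
            platform_ml=self.platform_ml.copy(),
            meta=replace(self.meta),
            events_log=[replace(e, profile_params=dict(e.profile_params)) for e in self.events_log],
        )


def validate_trial(trial: Trial) -> list:
    """Check trial invariants; return a list of human-readable violations.

    An empty list means the trial is valid.  This never raises: it is a
    reporting operation used by tests and by ``read_trial``.
    """
    report = []
    if not trial.fs > 0:
        report.append(f"fs must be positive, got {trial.fs}")
    n = trial.n_samples
    if n >= 2 and trial.fs > 0:
        dt = np.diff(trial.t)
        if np.any(dt <= 0):
            report.append("t must be strictly increasing")
        elif not np.allclose(dt, 1.0 / trial.fs, rtol=0, atol=1e-6 / trial.fs):
            report.append(f"t must advance in steps of 1/fs = {1.0 / trial.fs:.6g} s")
    for name in REQUIRED_MARKERS:
        if name not in trial.markers:
            report.append(f"missing marker channel {name!r}")
        elif trial.markers[name].shape != (n, 3):
            report.append(f"marker {name!r} has shape {trial.markers[name].shape}, expected {(n, 3)}")
    if trial.com.shape != (n, 3):
        report.append(f"com has shape {trial.com.shape}, expected {(n, 3)}")
    for ch in ("belt_speed_L", "belt_speed_R", "platform_ml"):
        arr = getattr(trial, ch)
        if arr.shape != (n,):
            report.append(f"channel {ch} has shape {arr.shape}, expected {(n,)}")
    if not trial.meta.comfortable_speed > 0:
        report.append(f"comfortable_speed must be positive, got {trial.meta.comfortable_speed}")
    if trial.meta.dominant_side not in ("L", "R"):
        report.append(f"dominant_side must be 'L' or 'R', got {trial.meta.dominant_side!r}")
    for k, ev in enumerate(trial.events_log):
        if not 0 <= ev.trigger_sample < n:
            report.append(f"event {k} ({ev.ptype}): trigger_sample {ev.trigger_sample} outside trial")
        if ev.ptype not in PERTURBATION_TYPES:
            report.append(f"event {k}: unknown ptype {ev.ptype!r}")
        if not 1 <= ev.repetition_index <= 4:
            report.append(f"event {k}: repetition_index {ev.repetition_index} outside 1..4")
    return report


def _trial_frame(trial: Trial) -> pd.DataFrame:
    cols = {"t": trial.t}
    for name in REQUIRED_MARKERS:
        for j, ax in enumerate(AXES):
            cols[f"{name}_{ax}"] = trial.markers[name][:, j]
    for j, ax in enumerate(AXES):
        cols[f"com_{ax}"] = trial.com[:, j]
    cols["belt_speed_L"] = trial.belt_speed_L
    cols["belt_speed_R"] = trial.belt_speed_R
    cols["platform_ml"] = trial.platform_ml
    return pd.DataFrame(cols)


def write_trial(trial: Trial, path) -> None:
    """Write a trial as TSV plus ``.events.tsv`` and ``.meta.json`` sidecars."""
    path = Path(path)
    _trial_frame(trial).to_csv(path, sep="\t", index=False, float_format="%.9g")
    stem = path.with_suffix("")
    ev_rows = [
        {
            "ptype": e.ptype,
            "trigger_time": e.trigger_time,
            "trigger_sample": e.trigger_sample,
            "repetition_index": e.repetition_index,
            "params_json": json.dumps(e.profile_params, sort_keys=True),
        }
        for e in trial.events_log
    ]
    pd.DataFrame(
        ev_rows,
        columns=["ptype", "trigger_time", "trigger_sample", "repetition_index", "params_json"],
    ).to_csv(stem.with_suffix(".events.tsv"), sep="\t", index=False)
    meta = {
        "fs": trial.fs,
        "dominant_side": trial.meta.dominant_side,
        "comfortable_speed": trial.meta.comfortable_speed,
        "subject_id": trial.meta.subject_id,
        "group": trial.meta.group,
    }
    stem.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_trial(path, dialect: str = "tsv") -> Trial:
    """Read a trial written by :func:`write_trial` (or a C3D file).

    Unknown TSV columns are preserved-but-ignored; a missing required
    channel raises :class:`~gaitstab.errors.MissingChannel` and a
    non-uniform time base raises :class:`~gaitstab.errors.BadTimeBase`.
    """
    path = Path(path)
    if dialect == "c3d":
        return _read_c3d(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    required = ["t"]
    for name in REQUIRED_MARKERS:
        required += [f"{name}_{ax}" for ax in AXES]
    required += [f"com_{ax}" for ax in AXES] + ["belt_speed_L", "belt_speed_R", "platform_ml"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingChannel(f"TSV {path} lacks required columns: {missing}")

    t = df["t"].to_numpy(float)
    stem = path.with_suffix("")
    meta_path = stem.with_suffix(".meta.json")
    if meta_path.exists():
        m = json.loads(meta_path.read_text())
        fs = float(m.get("fs", _infer_fs(t)))
        meta = TrialMeta(
            dominant_side=m.get("dominant_side", "R"),
            comfortable_speed=float(m.get("comfortable_speed", 1.2)),
            subject_id=m.get("subject_id", stem.name),
            group=m.get("group", "synthetic"),
        )
    else:
        fs = _infer_fs(t)
        meta = TrialMeta(subject_id=stem.name)

    dt = np.diff(t)
    if t.size >= 2 and not np.allclose(dt, 1.0 / fs, rtol=0, atol=1e-6 / fs):
        raise BadTimeBase(f"time vector of {path} is not uniform at fs={fs}")

    markers = {
        name: np.column_stack([df[f"{name}_{ax}"].to_numpy(float) for ax in AXES])
        for name in REQUIRED_MARKERS
    }
    com = np.column_stack([df[f"com_{ax}"].to_numpy(float) for ax in AXES])

    events = []
    ev_path = stem.with_suffix(".events.tsv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path, sep="\t")
        for _, row in ev.iterrows():
            events.append(
                PerturbationEvent(
                    ptype=str(row["ptype"]),
                    trigger_time=float(row["trigger_time"]),
                    trigger_sample=int(row["trigger_sample"]),
                    repetition_index=int(row["repetition_index"]),
                    profile_params=json.loads(row["params_json"]) if isinstance(row.get("params_json"), str) else {},
                )
            )

    return Trial(
        fs=fs,
        t=t,
        markers=markers,
        com=com,
        belt_speed_L=df["belt_speed_L"].to_numpy(float),
        belt_speed_R=df["belt_speed_R"].to_numpy(float),
        platform_ml=df["platform_ml"].to_numpy(float),
        meta=meta,
        events_log=events,
    )


def _infer_fs(t: np.ndarray) -> float:
    if t.size < 2:
        raise BadTimeBase("cannot infer sampling rate from fewer than 2 samples")
    return float(round(1.0 / np.median(np.diff(t)), 6))


# Default marker-label mapping and axis rotation for C3D ingest.  C3D
# files carry lab-specific labels and axis conventions; both must be
# declared explicitly because no universal convention exists.
DEFAULT_C3D_CONFIG = {
    "labels": {name: name for name in REQUIRED_MARKERS},
    "com_label": "com",
    # rows of the rotation matrix mapping file axes -> (ML, AP, VT)
    "rotation": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
    "unit_scale": 0.001,  # C3D positions are commonly in mm
}


def _read_c3d(path: Path, config: dict | None = None) -> Trial:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional dependency ezc3d "
            "(pip install gaitstab[c3d])"
        ) from exc
    cfg = dict(DEFAULT_C3D_CONFIG, **(config or {}))
    c3d = ezc3d.c3d(str(path))
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    fs = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    points = c3d["data"]["points"]  # (4, n_markers, n_frames)
    rot = np.asarray(cfg["rotation"], float)
    scale = float(cfg["unit_scale"])

    def extract(label):
        if label not in labels:
            raise MissingChannel(f"C3D file lacks point {label!r}")
        xyz = points[:3, labels.index(label), :].T * scale  # (N, 3)
        return xyz @ rot.T

    markers = {name: extract(lbl) for name, lbl in cfg["labels"].items()}
    com = extract(cfg["com_label"])
    n = com.shape[0]
    zeros = np.zeros(n)
    return Trial(
        fs=fs,
        t=np.arange(n) / fs,
        markers=markers,
        com=com,
        belt_speed_L=zeros.copy(),
        belt_speed_R=zeros.copy(),
        platform_ml=zeros.copy(),
        meta=TrialMeta(subject_id=path.stem),
    )
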