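"""Core containers for wearable magneto-inertial recordings.

A :class:`SensorRecording` holds one sensor's 3-axis angular-velocity and
3-axis acceleration time series, sampled on a uniform grid, together with
the metadata needed downstream (sampling rate, anatomical location, subject,
medication state, motor task).  A :class:`SpeedProfile` is the scalar,
non-negative angular-speed trace v(t) that segmentation and smoothness
analysis operate on.

Recordings round-trip through a plain-text format: a CSV with columns
``t,gx,gy,gz,ax,ay,az`` plus a JSON sidecar carrying the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Anatomical sensor locations, distal to proximal.
LOCATIONS = ("index", "thumb", "metacarpus", "wrist", "arm")

#: Medication / group states.
CONDITIONS = ("OFF", "ON", "HS")

#: Motor tasks (UPDRS part III items 23, 25 and 22 respectively).
TASKS = ("finger_tapping", "pronosupination", "rigidity")

#: Gyroscope axis carrying the task's dominant rotation.  Finger tapping
#: rotates the finger about the sensor y-axis; prono-supination rotates the
#: forearm about the sensor x-axis (aligned with the radius); the passive
#: elbow flexion-extension of the rigidity exam is likewise strongest on x
#: for a wrist-worn sensor.
TASK_AXIS = {"finger_tapping": 1, "pronosupination": 0, "rigidity": 0}

AXIS_NAMES = ("x", "y", "z")

_CSV_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]


def task_axis_index(task: str) -> int:
    """Return the gyroscope axis index (0=x, 1=y, 2=z) dominant for *task*."""
    try:
        return TASK_AXIS[task]
    except KeyError:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}") from None


@dataclass
class SensorRecording:
    """One sensor's 6-axis inertial time series plus metadata.

    Attributes
    ----------
    sample_rate : float
        Sampling frequency in Hz; the time grid is uniform.
    t : ndarray, shape (N,)
        Sample times in seconds.
    gyro : ndarray, shape (3, N)
        Angular velocity in deg/s; rows are the x, y, z sensor axes.
    accel : ndarray, shape (3, N)
        Acceleration in m/s^2; carried along but unused by the kinematic
        indexes.
    location, subject_id, condition, task : str
        Metadata identifying the recording.
    meta : dict
        Free-form provenance (simulation parameters, warnings, ...).
    """

    sample_rate: float
    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    location: str = "index"
    subject_id: str = "S0"
    condition: str = "HS"
    task: str = "finger_tapping"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        if self.gyro.shape != (3, self.t.size):
            raise ValueError(f"gyro must be (3, {self.t.size}), got {self.gyro.shape}")
        if self.accel.shape != (3, self.t.size):
            raise ValueError(f"accel must be (3, {self.t.size}), got {self.accel.shape}")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.max(np.abs(dt - 1.0 / self.sample_rate)) > 1e-6:
                raise ValueError("non-uniform time grid (|dt - 1/fs| > 1e-6 s)")
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def copy_with(self, **changes) -> "SensorRecording":
        """Return a copy with selected fields replaced (arrays are copied)."""
        kwargs = dict(
            sample_rate=self.sample_rate,
            t=self.t.copy(),
            gyro=self.gyro.copy(),
            accel=self.accel.copy(),
            location=self.location,
            subject_id=self.subject_id,
            condition=self.condition,
            task=self.task,
            meta=dict(self.meta),
        )
        kwargs.update(changes)
        return SensorRecording(**kwargs)

    # ------------------------------------------------------------------ I/O

    def write(self, csv_path: str | Path) -> Path:
        """Write the CSV data file and its JSON metadata sidecar.

        The sidecar path is the CSV path with a ``.json`` suffix appended
        (``rec.csv`` -> ``rec.csv.json``).  Returns the CSV path.
        """
        csv_path = Path(csv_path)
        frame = pd.DataFrame(
            {
                "t": self.t,
                "gx": self.gyro[0],
                "gy": self.gyro[1],
                "gz": self.gyro[2],
                "ax": self.accel[0],
                "ay": self.accel[1],
                "az": self.accel[2],
            }
        )
        frame.to_csv(csv_path, index=False, float_format="%.6f")
        sidecar = {
            "sample_rate": self.sample_rate,
            "n_samples": int(self.n_samples),
            "units": {"gyro": "deg/s", "accel": "m/s^2", "t": "s"},
            "location": self.location,
            "subject_id": self.subject_id,
            "condition": self.condition,
            "task": self.task,
            "meta": self.meta,
        }
        sidecar_path = csv_path.with_suffix(csv_path.suffix + ".json")
        sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return csv_path

    @classmethod
    def read(cls, csv_path: str | Path) -> "SensorRecording":
        """Load a recording from its CSV file and JSON sidecar."""
        csv_path = Path(csv_path)
        sidecar_path = csv_path.with_suffix(csv_path.suffix + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
        side = json.loads(sidecar_path.read_text())
        for key in ("sample_rate", "units", "location", "subject_id", "condition", "task"):
            if key not in side:
                raise ValueError(f"sidecar {sidecar_path} lacks mandatory field {key!r}")
        frame = pd.read_csv(csv_path)
        missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{csv_path}: missing columns {missing}")
        if "n_samples" in side and len(frame) != side["n_samples"]:
            raise ValueError(
                f"{csv_path}: row count {len(frame)} does not match sidecar "
                f"n_samples {side['n_samples']}"
            )
        return cls(
            sample_rate=float(side["sample_rate"]),
            t=frame["t"].to_numpy(),
            gyro=frame[["gx", "gy", "gz"]].to_numpy().T,
            accel=frame[["ax", "ay", "az"]].to_numpy().T,
            location=side["location"],
            subject_id=side["subject_id"],
            condition=side["condition"],
            task=side["task"],
            meta=side.get("meta", {}),
        )


@dataclass
class SpeedProfile:
    """Scalar angular-speed trace v(t) >= 0 derived from a recording."""

    t: np.ndarray
    v: np.ndarray
    sample_rate: float
    provenance: str = "gyro_norm"  # task_axis_abs | gyro_norm
    band: str = "raw"  # raw | bradykinesia_1_4 | tremor_4_8 | rigidity_0_20

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have equal length")
        if self.v.size and self.v.min() < 0:
            raise ValueError("speed profile must be non-negative")

    def __len__(self) -> int:
        return self.v.size

    def slice(self, start_idx: int, end_idx: int) -> "SpeedProfile":
        """Half-open slice [start_idx, end_idx) preserving metadata."""
        return SpeedProfile(
            t=self.t[start_idx:end_idx],
            v=self.v[start_idx:end_idx],
            sample_rate=self.sample_rate,
            provenance=self.provenance,
            band=self.band,
        )
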