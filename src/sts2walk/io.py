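"""Reading and writing IMU recordings, segmentations, and cohort tables.

Recordings are plain CSV with ``# key=value`` comment headers followed by a
single column-header line ``t,ax,ay,az,gx,gy,gz``.  Canonical units are
g for acceleration and deg/s for angular velocity; files recorded in m/s²
or rad/s declare it via ``acc_unit`` / ``gyro_unit`` header keys and are
converted on read.  Time is seconds from recording start.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IMURecording",
    "FormatError",
    "IntegrityError",
    "DurationWarning",
    "read_recording",
    "write_recording",
    "read_cohort",
    "write_cohort",
    "read_segmentation",
    "write_segmentation",
]

#: standard gravity, m/s² per g
G_STANDARD = 9.80665

REQUIRED_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")

#: duration bounds (s) for a valid one-minute test recording
DURATION_BOUNDS = (55.0, 75.0)

ACC_UNITS = {"g": 1.0, "m/s2": 1.0 / G_STANDARD, "m/s^2": 1.0 / G_STANDARD}
GYRO_UNITS = {"deg/s": 1.0, "rad/s": 180.0 / np.pi}


class FormatError(ValueError):
    """Raised when a file does not conform to the recording format."""


class IntegrityError(ValueError):
    """Raised when a recording has too many missing samples."""


class DurationWarning(UserWarning):
    """Issued when a recording's duration is outside the valid test window."""


@dataclass
class IMURecording:
    """A validated 6-channel inertial time series.

    Attributes
    ----------
    subject_id : str
        Opaque identifier of the subject/test.
    t : ndarray
        Seconds since recording start, strictly increasing.
    acc : ndarray, shape (n, 3)
        Triaxial acceleration in g-units.
    gyro : ndarray, shape (n, 3)
        Triaxial angular velocity in deg/s.
    fs : float
        Nominal sampling rate, Hz.
    """

    subject_id: str
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.t.shape[0]
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise FormatError("acc and gyro must be (n, 3) arrays matching t")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise FormatError("time must be strictly increasing")
            med = float(np.median(dt))
            if abs(med - 1.0 / self.fs) > 0.1 / self.fs:
                raise FormatError(
                    f"median sample interval {med:.4f}s deviates >10% from 1/fs"
                )

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        """Time span (s) from first to last sample."""
        if self.n_samples < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])


def _parse_header(path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_recording(
    path: str,
    *,
    duration_policy: str = "warn",
    max_missing: float = 0.01,
) -> IMURecording:
    """Read and validate a recording CSV.

    Isolated missing samples (gaps of one sample period) are filled by linear
    interpolation; recordings missing more than ``max_missing`` of their
    samples are rejected with :class:`IntegrityError`.  Unit conversion to
    g / deg/s is applied according to the declared-unit header keys.

    Parameters
    ----------
    duration_policy : {"warn", "error", "ignore"}
        What to do when the duration falls outside the 55–75 s test window.
    """
    if duration_policy not in ("warn", "error", "ignore"):
        raise ValueError(f"unknown duration_policy {duration_policy!r}")
    meta = _parse_header(path)
    df = pd.read_csv(path, comment="#")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"missing required column(s): {', '.join(missing_cols)}")

    fs = float(meta.get("fs", 100.0))
    acc_unit = meta.get("acc_unit", "g")
    gyro_unit = meta.get("gyro_unit", "deg/s")
    if acc_unit not in ACC_UNITS:
        raise FormatError(f"unknown acc_unit {acc_unit!r}")
    if gyro_unit not in GYRO_UNITS:
        raise FormatError(f"unknown gyro_unit {gyro_unit!r}")

    t = df["t"].to_numpy(dtype=float)
    acc = df[["ax", "ay", "az"]].to_numpy(dtype=float) * ACC_UNITS[acc_unit]
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float) * GYRO_UNITS[gyro_unit]
    if np.isnan(t).any() or np.isnan(acc).any() or np.isnan(gyro).any():
        raise IntegrityError("recording contains NaN samples")

    step = 1.0 / fs
    expected = int(round((t[-1] - t[0]) / step)) + 1
    n_missing = expected - t.shape[0]
    if n_missing < 0:
        raise FormatError("more samples than the time span allows at the stated fs")
    if n_missing > 0:
        if n_missing / expected > max_missing:
            raise IntegrityError(
                f"{n_missing}/{expected} samples missing "
                f"(> {max_missing:.0%} threshold)"
            )
        # gap-fill onto the uniform grid
        grid = t[0] + step * np.arange(expected)
        acc = np.column_stack([np.interp(grid, t, acc[:, k]) for k in range(3)])
        gyro = np.column_stack([np.interp(grid, t, gyro[:, k]) for k in range(3)])
        t = grid

    duration = t[-1] - t[0] + step
    lo, hi = DURATION_BOUNDS
    if not lo <= duration <= hi and duration_policy != "ignore":
        msg = f"recording duration {duration:.2f}s outside [{lo}, {hi}]s"
        if duration_policy == "error":
            raise IntegrityError(msg)
        warnings.warn(msg, DurationWarning)

    return IMURecording(
        subject_id=meta.get("subject_id", ""), t=t, acc=acc, gyro=gyro, fs=fs
    )


def write_recording(rec: IMURecording, path: str) -> None:
    """Write a recording in the canonical CSV format (g, deg/s)."""
    with open(path, "w") as fh:
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write("# acc_unit=g\n")
        fh.write("# gyro_unit=deg/s\n")
        fh.write(",".join(REQUIRED_COLUMNS) + "\n")
        data = np.column_stack([rec.t, rec.acc, rec.gyro])
        np.savetxt(fh, data, delimiter=",", fmt="%.9g")


def read_cohort(path: str) -> pd.DataFrame:
    """Read a cohort feature table; one row per subject, ``distance`` in metres."""
    df = pd.read_csv(path, comment="#")
    if "subject_id" in df.columns and df["subject_id"].duplicated().any():
        raise IntegrityError("duplicated subject_id in cohort table")
    if "distance" in df.columns and (df["distance"] <= 0).any():
        raise IntegrityError("non-positive 6MWD in cohort table")
    return df


def write_cohort(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def write_segmentation(result, path: str) -> None:
    """Serialize a :class:`~sts2walk.segmentation.SegmentationResult` as JSON.

    Refuses results whose cycles overlap or are out of order; times are kept
    at full float precision so the file round-trips losslessly.
    """
    result.validate()
    payload = {
        "count": result.count,
        "cycles": [
            {
                "stand_start": c.stand_start,
                "stand_end": c.stand_end,
                "sit_start": c.sit_start,
                "sit_end": c.sit_end,
            }
            for c in result.cycles
        ],
        "rejected": result.rejected_extrema,
        "trailing_stand_up": result.trailing_stand_up,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_segmentation(path: str):
    from .segmentation import SegmentationResult, STSCycle

    with open(path) as fh:
        payload = json.load(fh)
    cycles = [
        STSCycle(
            stand_start=c["stand_start"],
            stand_end=c["stand_end"],
            sit_start=c["sit_start"],
            sit_end=c["sit_end"],
        )
        for c in payload["cycles"]
    ]
    return SegmentationResult(
        cycles=cycles,
        rejected_extrema=payload.get("rejected", 0),
        trailing_stand_up=bool(payload.get("trailing_stand_up", False)),
    )
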