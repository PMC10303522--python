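"""Delimited-text readers and writers for the pipeline's interchange files.

All stages exchange plain CSV: EMG as a ``time_s`` column plus one column
per channel (millivolts); poses as ``timestamp, qw, qx, qy, qz``; angles
as ``timestamp, hip_deg, knee_deg``.  Readers validate schema, finiteness
and time monotonicity, reporting offending line numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decomposition import Signal
from .kinematics import PoseStream

__all__ = [
    "write_emg_csv",
    "read_emg_csv",
    "write_pose_csv",
    "read_pose_csv",
    "write_angles_csv",
    "read_angles_csv",
    "read_feature_csv",
]

POSE_COLUMNS = ["timestamp", "qw", "qx", "qy", "qz"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _check_finite(df: pd.DataFrame, path) -> None:
    values = df.to_numpy(dtype=np.float64)
    bad = ~np.isfinite(values)
    if bad.any():
        row, col = np.argwhere(bad)[0]
        # +2: header line plus 1-based numbering
        raise ValueError(
            f"{path}: non-finite value in column {df.columns[col]!r} "
            f"at line {row + 2}")


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: file has no data rows")
    return df


def write_emg_csv(path, timestamps: np.ndarray, channels: np.ndarray,
                  channel_names) -> None:
    data = {"time_s": np.asarray(timestamps, dtype=np.float64)}
    for name, ch in zip(channel_names, np.atleast_2d(channels)):
        data[name] = ch
    pd.DataFrame(data).to_csv(path, index=False)


def read_emg_csv(path, fs: float | None = None):
    """Read a multichannel EMG CSV.

    Returns (timestamps, list of Signal, channel_names); the sampling rate
    is inferred from the time column unless given.
    """
    df = _read_csv(path)
    _require_columns(df, ["time_s"], path)
    _check_finite(df, path)
    t = df["time_s"].to_numpy(dtype=np.float64)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ValueError(f"{path}: non-monotone time at line {bad + 3}")
    if fs is None:
        if t.size < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from one row")
        fs = 1.0 / float(np.median(np.diff(t)))
    names = [c for c in df.columns if c != "time_s"]
    if not names:
        raise ValueError(f"{path}: no channel columns")
    signals = [Signal(df[c].to_numpy(dtype=np.float64), fs) for c in names]
    return t, signals, names


def write_pose_csv(path, stream: PoseStream) -> None:
    q = stream.quaternions
    pd.DataFrame({
        "timestamp": stream.timestamps,
        "qw": q[:, 0], "qx": q[:, 1], "qy": q[:, 2], "qz": q[:, 3],
    }).to_csv(path, index=False)


def read_pose_csv(path, sensor_id: str) -> PoseStream:
    df = _read_csv(path)
    _require_columns(df, POSE_COLUMNS, path)
    _check_finite(df[POSE_COLUMNS], path)
    t = df["timestamp"].to_numpy(dtype=np.float64)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ValueError(f"{path}: non-monotone timestamp at line {bad + 3}")
    q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=np.float64)
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        bad = int(np.flatnonzero(np.abs(norms - 1.0) > 1e-3)[0])
        raise ValueError(f"{path}: non-unit quaternion at line {bad + 2}")
    q = q / norms[:, None]
    return PoseStream(sensor_id=sensor_id, timestamps=t, quaternions=q)


def write_angles_csv(path, timestamps, hip_deg, knee_deg) -> None:
    pd.DataFrame({"timestamp": timestamps, "hip_deg": hip_deg,
                  "knee_deg": knee_deg}).to_csv(path, index=False)


def read_angles_csv(path):
    df = _read_csv(path)
    _require_columns(df, ["timestamp", "hip_deg", "knee_deg"], path)
    _check_finite(df, path)
    return (df["timestamp"].to_numpy(np.float64),
            df["hip_deg"].to_numpy(np.float64),
            df["knee_deg"].to_numpy(np.float64))


def read_feature_csv(path):
    """Read a feature matrix CSV; returns (values, feature_names, targets,
    target_names, cycle_ids) with absent blocks as None."""
    df = _read_csv(path)
    _check_finite(df, path)
    cycle_ids = None
    if "cycle_id" in df.columns:
        cycle_ids = df.pop("cycle_id").to_numpy(np.int64)
    target_names = [c for c in df.columns if c in ("hip_deg", "knee_deg")
                    or c.startswith("target")]
    targets = df[target_names].to_numpy(np.float64) if target_names else None
    feat_names = [c for c in df.columns if c not in target_names]
    return (df[feat_names].to_numpy(np.float64), feat_names, targets,
            target_names, cycle_ids)
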