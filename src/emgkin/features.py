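"""Sliding-window time-domain features of surface EMG.

Each channel is segmented into windows (default 10 ms, non-overlapping) and
four time-domain descriptors are computed per window:

* RMS  — root mean square, sqrt(mean(x_i^2))
* VAR  — sample variance with the N-1 denominator
* WL   — waveform length, sum(|x_{i+1} - x_i|)
* MAV  — mean absolute value

Six channels yield the 24-column feature matrix the angle model consumes;
joint-angle targets are window means of the angle series over the same
windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import Signal

__all__ = [
    "WindowSpec",
    "FeatureMatrix",
    "FEATURE_NAMES",
    "sliding_windows",
    "time_domain_features",
    "build_feature_matrix",
    "window_average_targets",
    "window_cycle_ids",
]

FEATURE_NAMES = ("RMS", "VAR", "WL", "MAV")


@dataclass(frozen=True)
class WindowSpec:
    """Window length and hop in milliseconds (hop defaults to the length,
    i.e. non-overlapping windows)."""

    width_ms: float = 10.0
    step_ms: float | None = None

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")
        if self.step_ms is None:
            object.__setattr__(self, "step_ms", self.width_ms)
        if self.step_ms <= 0:
            raise ValueError("step_ms must be > 0")

    def width_samples(self, fs: float) -> int:
        w = int(round(self.width_ms * fs / 1000.0))
        if w < 2:
            raise ValueError("window must span at least 2 samples (VAR needs N >= 2)")
        return w

    def step_samples(self, fs: float) -> int:
        s = int(round(self.step_ms * fs / 1000.0))
        if s < 1:
            raise ValueError("step must span at least 1 sample")
        return s

    def n_windows(self, length: int, fs: float) -> int:
        w, s = self.width_samples(fs), self.step_samples(fs)
        if length < w:
            raise ValueError("signal shorter than one window")
        return (length - w) // s + 1


@dataclass
class FeatureMatrix:
    """Per-window feature rows in channel-major (RMS, VAR, WL, MAV) order,
    optionally carrying aligned joint-angle targets and gait-cycle ids."""

    values: np.ndarray  # (n_windows, 4 * n_channels)
    channel_names: list
    targets: np.ndarray | None = None  # (n_windows,) or (n_windows, n_joints)
    target_names: list | None = None
    cycle_ids: np.ndarray | None = None

    @property
    def column_names(self) -> list:
        return [f"{ch}_{feat}" for ch in self.channel_names for feat in FEATURE_NAMES]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        if self.targets is not None:
            t = np.atleast_2d(self.targets.T).T
            names = self.target_names or [f"target{j}" for j in range(t.shape[1])]
            for j, name in enumerate(names):
                df[name] = t[:, j]
        if self.cycle_ids is not None:
            df["cycle_id"] = self.cycle_ids
        return df


def sliding_windows(signal: Signal | np.ndarray, spec: WindowSpec,
                    fs: float | None = None) -> np.ndarray:
    """Segment a series into windows; returns an (n_windows, width) view.

    Window i covers samples [i*step, i*step + width); a trailing partial
    window is discarded.
    """
    if isinstance(signal, Signal):
        x, fs = signal.samples, signal.fs
    else:
        x = np.asarray(signal, dtype=np.float64)
        if fs is None:
            raise ValueError("fs required for a bare array")
    w = spec.width_samples(fs)
    s = spec.step_samples(fs)
    if x.size < w:
        raise ValueError("signal shorter than one window")
    n = (x.size - w) // s + 1
    idx = np.arange(w)[None, :] + s * np.arange(n)[:, None]
    return x[idx]


def time_domain_features(window: np.ndarray) -> tuple[float, float, float, float]:
    """(RMS, VAR, WL, MAV) of one window of at least two samples."""
    x = np.asarray(window, dtype=np.float64)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    rms = float(np.sqrt(np.mean(x**2)))
    var = float(np.sum((x - x.mean()) ** 2) / (x.size - 1))
    wl = float(np.sum(np.abs(np.diff(x))))
    mav = float(np.mean(np.abs(x)))
    return rms, var, wl, mav


def _features_block(windows: np.ndarray) -> np.ndarray:
    """Vectorised (n_windows, 4) feature block for one channel."""
    rms = np.sqrt(np.mean(windows**2, axis=1))
    var = np.var(windows, axis=1, ddof=1)
    wl = np.sum(np.abs(np.diff(windows, axis=1)), axis=1)
    mav = np.mean(np.abs(windows), axis=1)
    return np.column_stack([rms, var, wl, mav])


def build_feature_matrix(channels: list, spec: WindowSpec | None = None,
                         channel_names: list | None = None) -> FeatureMatrix:
    """Windowed time-domain features of all channels, channel-major.

    ``channels`` is a list of :class:`Signal` of equal length and rate.
    """
    if spec is None:
        spec = WindowSpec()
    if not channels:
        raise ValueError("no channels given")
    length = len(channels[0])
    fs = channels[0].fs
    for ch in channels:
        if len(ch) != length or ch.fs != fs:
            raise ValueError("channels must share length and sampling rate")
    blocks = [_features_block(sliding_windows(ch, spec)) for ch in channels]
    names = channel_names or [f"ch{j + 1}" for j in range(len(channels))]
    return FeatureMatrix(values=np.hstack(blocks), channel_names=list(names))


def window_average_targets(angles: np.ndarray, spec: WindowSpec, fs: float) -> np.ndarray:
    """Per-window mean of an angle series aligned with the EMG channels."""
    a = np.asarray(angles, dtype=np.float64)
    return sliding_windows(a, spec, fs=fs).mean(axis=1)


def window_cycle_ids(cycle_ids: np.ndarray, spec: WindowSpec, fs: float) -> np.ndarray:
    """Gait-cycle id per window, taken at the window's first sample."""
    ids = np.asarray(cycle_ids)
    w = spec.width_samples(fs)
    s = spec.step_samples(fs)
    n = (ids.size - w) // s + 1
    return ids[s * np.arange(n)]
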