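"""Empirical mode decomposition (EMD) and its complete-ensemble variant (CEEMDAN).

EMD iteratively *sifts* a series into intrinsic mode functions (IMFs):
oscillatory components whose extrema and zero-crossing counts differ by at
most one and whose local mean (average of the upper and lower cubic-spline
envelopes through the extrema) is near zero.  CEEMDAN stabilises the
decomposition of noisy broadband signals such as surface EMG by averaging,
at every stage, the first EMD mode over an ensemble of white-noise-assisted
copies of the running residual; the added noise cancels in the average while
suppressing mode mixing, and the decomposition remains exactly complete
(modes plus residual reconstruct the input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "Signal",
    "IMFSet",
    "CeemdanConfig",
    "find_extrema",
    "sift_once",
    "emd",
    "emd_mode_j",
    "ceemdan",
    "NoiseEnsemble",
]

# Cauchy-type sifting stop: SD = sum((h_prev-h_new)^2)/sum(h_prev^2) < SD_TOL
SD_TOL = 0.2
MAX_SIFT = 100


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled single-channel series.

    Parameters
    ----------
    samples : array-like
        Signal values (mV or arbitrary units).  Must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("Signal.samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Signal.samples must be finite")
        if not self.fs > 0:
            raise ValueError("Signal.fs must be > 0")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class IMFSet:
    """An ordered set of intrinsic mode functions plus the final residual.

    ``imfs[0]`` is the highest-frequency mode.  By construction
    ``imfs.sum(axis=0) + residual`` reconstructs the decomposed signal.
    """

    imfs: np.ndarray  # shape (n_modes, n_samples); may have 0 rows
    residual: np.ndarray  # shape (n_samples,)
    source_length: int

    def __post_init__(self) -> None:
        self.imfs = np.atleast_2d(np.asarray(self.imfs, dtype=np.float64))
        if self.imfs.size == 0:
            self.imfs = self.imfs.reshape(0, self.source_length)
        self.residual = np.asarray(self.residual, dtype=np.float64)
        if self.residual.size != self.source_length:
            raise ValueError("residual length does not match source_length")
        if self.imfs.shape[1] != self.source_length:
            raise ValueError("IMF length does not match source_length")

    @property
    def n_modes(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"IMF{i + 1}": self.imfs[i] for i in range(self.n_modes)}
        cols["residual"] = self.residual
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        """Export as delimited text: one column per mode plus the residual."""
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class CeemdanConfig:
    """Configuration of the noise-assisted ensemble decomposition.

    Parameters
    ----------
    k : int
        Ensemble size (number of white-noise realizations), >= 1.
    eps0 : float
        Noise amplitude as a ratio of the signal standard deviation.
    eps_schedule : tuple of float, optional
        Per-stage noise ratios; when absent every stage uses ``eps0``.
    max_imfs : int, optional
        Cap on the number of extracted modes; default
        ``floor(log2(n)) - 1`` for an n-sample signal.
    seed : int
        Seed for the noise generator; the output is a deterministic
        function of (signal, config).
    """

    k: int = 100
    eps0: float = 0.2
    eps_schedule: tuple = ()
    max_imfs: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("ensemble size k must be >= 1")
        if self.eps0 < 0:
            raise ValueError("eps0 must be >= 0")
        if any(e < 0 for e in self.eps_schedule):
            raise ValueError("eps_schedule entries must be >= 0")
        if self.max_imfs is not None and self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")

    def eps_at(self, stage: int) -> float:
        """Noise ratio for stage ``stage`` (1-based)."""
        if stage - 1 < len(self.eps_schedule):
            return float(self.eps_schedule[stage - 1])
        return float(self.eps0)


def default_max_imfs(n: int) -> int:
    return max(1, int(np.floor(np.log2(n))) - 1)


def find_extrema(x: np.ndarray):
    """Strict local maxima and minima of a series, in index order.

    Plateaus (runs of equal values) contribute their midpoint index.
    A monotone or constant series yields empty extrema sets.

    Returns
    -------
    (max_idx, max_val, min_idx, min_val) : arrays
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 3:
        empty = np.array([], dtype=np.intp)
        return empty, np.array([]), empty.copy(), np.array([])
    # compress runs of equal values so plateaus count once
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))  # inclusive end of each run
    vals = x[starts]
    if vals.size < 3:
        empty = np.array([], dtype=np.intp)
        return empty, np.array([]), empty.copy(), np.array([])
    d = np.sign(np.diff(vals))
    max_runs = np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1
    min_runs = np.flatnonzero((d[:-1] < 0) & (d[1:] > 0)) + 1
    max_idx = (starts[max_runs] + ends[max_runs]) // 2
    min_idx = (starts[min_runs] + ends[min_runs]) // 2
    return max_idx, x[max_idx], min_idx, x[min_idx]


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int):
    """Mirror two extrema beyond each end to suppress the endpoint effect."""
    left_i = (-idx[:2])[::-1]
    left_v = (val[:2])[::-1]
    right_i = 2 * (n - 1) - idx[-2:][::-1]
    right_v = val[-2:][::-1]
    ext_i = np.concatenate((left_i, idx, right_i))
    ext_v = np.concatenate((left_v, val, right_v))
    # guard against duplicated knots when an extremum sits on an endpoint
    ext_i, keep = np.unique(ext_i, return_index=True)
    return ext_i, ext_v[keep]


def _envelope_mean(x: np.ndarray):
    """Mean of the upper/lower natural-cubic-spline envelopes, or ``None``
    when fewer than two maxima or two minima exist (sifting impossible)."""
    n = x.size
    max_i, max_v, min_i, min_v = find_extrema(x)
    if max_i.size < 2 or min_i.size < 2:
        return None
    t = np.arange(n)
    ui, uv = _mirror_extend(max_i, max_v, n)
    li, lv = _mirror_extend(min_i, min_v, n)
    upper = CubicSpline(ui, uv, bc_type="natural")(t)
    lower = CubicSpline(li, lv, bc_type="natural")(t)
    return 0.5 * (upper + lower)


def sift_once(series: np.ndarray) -> np.ndarray:
    """One sifting step: subtract the mean of the spline envelopes.

    Raises
    ------
    ValueError
        If the series has fewer than two maxima or two minima, i.e. the
        residual is final and cannot be sifted further.
    """
    x = np.asarray(series, dtype=np.float64)
    m = _envelope_mean(x)
    if m is None:
        raise ValueError("insufficient extrema to sift: residual is final")
    return x - m


def _extract_imf(r: np.ndarray) -> np.ndarray | None:
    """Extract the first IMF of ``r`` by repeated sifting (the E1 operator).

    Returns ``None`` when ``r`` cannot be sifted (final residual).
    """
    m = _envelope_mean(r)
    if m is None:
        return None
    h = r - m
    for _ in range(MAX_SIFT - 1):
        m = _envelope_mean(h)
        if m is None:
            break
        h_new = h - m
        denom = np.sum(h * h)
        if denom == 0.0:
            h = h_new
            break
        sd = np.sum((h - h_new) ** 2) / denom
        h = h_new
        if sd < SD_TOL:
            break
    return h


def emd(signal: Signal | np.ndarray, max_imfs: int | None = None,
        fs: float = 1.0) -> IMFSet:
    """Plain empirical mode decomposition.

    Modes are extracted until the running residual has fewer than three
    extrema (monotone or trend-like) or ``max_imfs`` is reached.  The
    residual is the running remainder, so modes + residual reconstruct the
    input to floating-point accuracy.
    """
    if isinstance(signal, Signal):
        x = signal.samples
    else:
        x = np.asarray(signal, dtype=np.float64)
        if not np.all(np.isfinite(x)):
            raise ValueError("signal must be finite")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples to decompose")
    if max_imfs is None:
        max_imfs = default_max_imfs(n)
    imfs = []
    r = x.copy()
    while len(imfs) < max_imfs:
        imf = _extract_imf(r)
        if imf is None:
            break
        imfs.append(imf)
        r = r - imf
    return IMFSet(imfs=np.array(imfs).reshape(len(imfs), n),
                  residual=r, source_length=n)


def emd_mode_j(series: np.ndarray, j: int, max_imfs: int | None = None) -> np.ndarray:
    """The j-th EMD mode (1-based) of ``series``; zeros if fewer modes exist."""
    if j < 1:
        raise ValueError("mode index j must be >= 1")
    x = np.asarray(series, dtype=np.float64)
    dec = emd(x, max_imfs=max_imfs if max_imfs is not None else j)
    if dec.n_modes < j:
        return np.zeros_like(x)
    return dec.imfs[j - 1]


class NoiseEnsemble:
    """Seeded white-noise realizations with lazily computed EMD modes.

    CEEMDAN needs the j-th EMD mode of every noise realization at stage j.
    Decomposing the noise is independent of the signal being analysed, so
    one ensemble can be shared across equal-length channels.
    """

    def __init__(self, k: int, n: int, seed: int = 0,
                 bank: np.ndarray | None = None) -> None:
        if bank is None:
            rng = np.random.default_rng(seed)
            bank = rng.standard_normal((k, n))
        elif bank.shape != (k, n):
            raise ValueError("noise bank shape must be (k, n)")
        self.bank = bank
        self._residuals = [g.copy() for g in bank]
        self._modes: list[list[np.ndarray]] = [[] for _ in range(k)]
        self._done = [False] * k

    @property
    def k(self) -> int:
        return self.bank.shape[0]

    def mode(self, i: int, j: int) -> np.ndarray | None:
        """E_j(G_i), or ``None`` when realization i has fewer than j modes."""
        while len(self._modes[i]) < j and not self._done[i]:
            imf = _extract_imf(self._residuals[i])
            if imf is None:
                self._done[i] = True
                break
            self._modes[i].append(imf)
            self._residuals[i] = self._residuals[i] - imf
        if len(self._modes[i]) >= j:
            return self._modes[i][j - 1]
        return None


def ceemdan(signal: Signal | np.ndarray, config: CeemdanConfig | None = None,
            *, noise: "NoiseEnsemble | None" = None) -> IMFSet:
    """Complete ensemble EMD with adaptive noise.

    Stage 1 averages the first EMD mode of ``x + eps0*std(x)*G_i`` over the
    ensemble; stage j+1 averages the first mode of
    ``r_j + eps_j*std(x)*E_j(G_i)`` where ``E_j(G_i)`` is the j-th EMD mode
    of the i-th noise realization (the same realization reused across
    stages).  The residual is defined as input minus the summed modes, so
    reconstruction is exact.

    Parameters
    ----------
    signal : Signal or array
    config : CeemdanConfig
    noise : NoiseEnsemble, optional
        Pre-built noise ensemble, allowing the (signal-independent) noise
        decompositions to be reused across channels of equal length; when
        given it overrides ``config.seed``.
    """
    if config is None:
        config = CeemdanConfig()
    if isinstance(signal, Signal):
        x = signal.samples
    else:
        x = np.asarray(signal, dtype=np.float64)
        if not np.all(np.isfinite(x)):
            raise ValueError("signal must be finite")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples to decompose")
    max_imfs = config.max_imfs or default_max_imfs(n)
    std_x = float(np.std(x))

    noise_free = config.eps0 == 0 and all(e == 0 for e in config.eps_schedule)
    if noise_free:
        # degenerate case: exactly plain EMD regardless of k
        return emd(x, max_imfs=max_imfs)

    if noise is None:
        noise = NoiseEnsemble(config.k, n, seed=config.seed)
    elif noise.bank.shape != (config.k, n):
        raise ValueError("noise ensemble shape must be (k, n)")
    noise_bank = noise.bank

    imfs: list[np.ndarray] = []
    r = x.copy()

    # stage 1: x + eps0 * std * G_i
    eps1 = config.eps_at(1) * std_x
    acc = np.zeros(n)
    extracted = 0
    for i in range(config.k):
        imf = _extract_imf(x + eps1 * noise_bank[i])
        if imf is not None:
            acc += imf
            extracted += 1
    if extracted == 0:
        return IMFSet(imfs=np.zeros((0, n)), residual=x.copy(), source_length=n)
    imfs.append(acc / extracted)
    r = r - imfs[-1]

    stage = 1
    while len(imfs) < max_imfs:
        if _envelope_mean(r) is None:
            break  # residual no longer decomposable
        eps = config.eps_at(stage + 1) * std_x
        acc = np.zeros(n)
        extracted = 0
        for i in range(config.k):
            gm = noise.mode(i, stage)
            probe = r if gm is None or eps == 0 else r + eps * gm
            imf = _extract_imf(probe)
            if imf is not None:
                acc += imf
                extracted += 1
        if extracted == 0:
            break
        imfs.append(acc / extracted)
        r = r - imfs[-1]
        stage += 1

    modes = np.array(imfs).reshape(len(imfs), n)
    residual = x - modes.sum(axis=0)
    return IMFSet(imfs=modes, residual=residual, source_length=n)
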