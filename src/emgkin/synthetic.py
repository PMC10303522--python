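"""Synthetic gait data with the statistical structure the pipeline assumes.

The generator produces, from a seed:

* hip/knee angle trajectories — periodic waveforms in gait-cycle phase
  (hip roughly ±30° sinusoid-like, knee a non-negative double-bump peaking
  near 60°), with optional small cycle-to-cycle amplitude variability;
* sensor orientation quaternions for waist, thigh and shank realizing
  those angles in the sagittal plane, composed with fixed unknown mounting
  rotations and preceded by a static neutral calibration interval;
* six channels of surface EMG: a band-limited (20–450 Hz) Gaussian
  carrier, amplitude-modulated by muscle activation envelopes phased to
  the gait cycle (knee extensors in early stance, hamstrings in late
  swing, gastrocnemius at push-off, tibialis anterior during swing), then
  contaminated with powerline interference, sub-5 Hz baseline drift,
  broadband white noise and sparse impulsive motion artifacts.

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .kinematics import PoseStream, q_from_axis_angle, q_multiply, q_normalize

__all__ = [
    "GaitProfile",
    "EmgNoiseConfig",
    "GaitAngles",
    "SyntheticTrial",
    "MUSCLES",
    "default_activation_map",
    "gen_angles",
    "gen_pose_streams",
    "gen_emg",
    "gen_trial",
    "random_mounting",
]

MUSCLES = (
    "rectus_femoris",
    "vastus_lateralis",
    "semitendinosus",
    "biceps_femoris",
    "lateral_gastrocnemius",
    "tibialis_anterior",
)

# mediolateral (east) axis: sagittal-plane flexion is a rotation about it
_FLEXION_AXIS = np.array([0.0, 1.0, 0.0])


def _circular_bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian bump in circular phase, period 1, peak value 1."""
    d = phase - center
    d = d - np.round(d)
    return np.exp(-0.5 * (d / width) ** 2)


def _default_hip(phase: np.ndarray) -> np.ndarray:
    return np.sin(2.0 * np.pi * phase)


def _default_knee(phase: np.ndarray) -> np.ndarray:
    raw = 0.28 * _circular_bump(phase, 0.15, 0.07) + _circular_bump(phase, 0.72, 0.10)
    return raw / 1.0000000017913209  # peak of the double bump, so max == 1


@dataclass(frozen=True)
class GaitProfile:
    """Shape of the synthetic gait.

    ``hip_waveform``/``knee_waveform`` map cycle phase in [0, 1) to a
    dimensionless shape scaled by ``hip_amplitude_deg``/``knee_max_deg``;
    the defaults resemble level walking (hip sinusoid-like, knee stance
    and swing bumps).  ``amplitude_variability`` is the relative standard
    deviation of per-cycle amplitude jitter.
    """

    cycle_duration_s: float = 1.0
    n_cycles: int = 200
    fs: float = 1000.0
    hip_amplitude_deg: float = 30.0
    knee_max_deg: float = 60.0
    amplitude_variability: float = 0.05
    hip_waveform: object = _default_hip
    knee_waveform: object = _default_knee

    def __post_init__(self) -> None:
        if self.cycle_duration_s <= 0 or self.fs <= 0 or self.n_cycles < 1:
            raise ValueError("invalid gait profile")
        if self.knee_max_deg < 0 or self.amplitude_variability < 0:
            raise ValueError("invalid gait profile")


@dataclass(frozen=True)
class EmgNoiseConfig:
    """Amplitudes (mV) and rates of the contaminating noise sources."""

    powerline_hz: float = 50.0
    powerline_amplitude: float = 0.3
    drift_amplitude: float = 0.5
    drift_bandwidth_hz: float = 1.0
    white_noise_sigma: float = 0.1
    artifact_rate: float = 0.5  # impulses per second
    artifact_amplitude: float = 2.0

    def __post_init__(self) -> None:
        for name in ("powerline_amplitude", "drift_amplitude",
                     "white_noise_sigma", "artifact_rate", "artifact_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def silent(self) -> "EmgNoiseConfig":
        return replace(self, powerline_amplitude=0.0, drift_amplitude=0.0,
                       white_noise_sigma=0.0, artifact_rate=0.0)


@dataclass
class GaitAngles:
    timestamps: np.ndarray
    hip_deg: np.ndarray
    knee_deg: np.ndarray
    cycle_ids: np.ndarray
    phase: np.ndarray
    fs: float


@dataclass
class SyntheticTrial:
    """One generated recording: aligned EMG, poses and ground-truth angles.

    Pose streams include a static calibration prefix of ``calib_duration_s``
    seconds; the EMG and angle series cover the gait portion, which starts
    at ``gait_start_s`` on the pose-stream clock.
    """

    fs: float
    angles: GaitAngles
    clean_emg: np.ndarray  # (6, N)
    noisy_emg: np.ndarray  # (6, N)
    envelopes: np.ndarray  # (6, N) activation ground truth
    channel_names: tuple
    poses: dict  # sensor_id -> PoseStream
    mountings: dict
    calib_interval: tuple
    gait_start_s: float
    seed: int


def default_activation_map() -> list:
    """(muscle, phase center, phase width, baseline) per channel.

    Flexors and extensors are active in opposing phases of the cycle:
    knee extensors load in early stance, plantarflexors at push-off,
    dorsiflexors through swing, hamstrings in late swing.
    """
    return [
        ("rectus_femoris", 0.05, 0.10, 0.10),
        ("vastus_lateralis", 0.08, 0.10, 0.10),
        ("semitendinosus", 0.90, 0.10, 0.10),
        ("biceps_femoris", 0.92, 0.10, 0.10),
        ("lateral_gastrocnemius", 0.40, 0.12, 0.10),
        ("tibialis_anterior", 0.65, 0.15, 0.10),
    ]


def gen_angles(profile: GaitProfile | None = None, seed: int = 0) -> GaitAngles:
    """Phase-sampled hip/knee trajectories with per-cycle amplitude jitter."""
    if profile is None:
        profile = GaitProfile()
    rng = np.random.default_rng(seed)
    spc = int(round(profile.cycle_duration_s * profile.fs))  # samples per cycle
    n = spc * profile.n_cycles
    t = np.arange(n) / profile.fs
    phase = (t / profile.cycle_duration_s) % 1.0
    cycle_ids = (np.arange(n) // spc).astype(np.int64)
    hip_shape = np.asarray(profile.hip_waveform(phase), dtype=np.float64)
    knee_shape = np.asarray(profile.knee_waveform(phase), dtype=np.float64)
    if profile.amplitude_variability > 0:
        hip_gain = 1.0 + profile.amplitude_variability * rng.standard_normal(profile.n_cycles)
        knee_gain = 1.0 + profile.amplitude_variability * rng.standard_normal(profile.n_cycles)
        hip_gain = np.clip(hip_gain, 0.5, 1.5)[cycle_ids]
        knee_gain = np.clip(knee_gain, 0.5, 1.5)[cycle_ids]
    else:
        hip_gain = knee_gain = 1.0
    hip = profile.hip_amplitude_deg * hip_gain * hip_shape
    knee = np.maximum(profile.knee_max_deg * knee_gain * knee_shape, 0.0)
    return GaitAngles(timestamps=t, hip_deg=hip, knee_deg=knee,
                      cycle_ids=cycle_ids, phase=phase, fs=profile.fs)


def random_mounting(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random unit quaternion (unknown sensor mounting)."""
    q = rng.standard_normal(4)
    return q_normalize(q)


def gen_pose_streams(angles: GaitAngles, mountings: dict | None = None,
                     orientation_noise_deg: float = 0.0, seed: int = 0,
                     calib_duration_s: float = 2.0):
    """Sensor pose streams realizing the given angles in the sagittal plane.

    The waist stays at the neutral orientation; the thigh flexes by the hip
    angle about the mediolateral axis; the shank additionally extends back
    by the knee angle.  Each segment orientation is composed with the
    sensor's fixed mounting rotation, and a static neutral calibration
    interval is prepended.  ``orientation_noise_deg`` perturbs every sample
    with a small random rotation of that angular scale (degrees).

    Returns
    -------
    (poses, mountings, calib_interval) where poses maps sensor id to
    :class:`PoseStream`.
    """
    rng = np.random.default_rng(seed)
    if mountings is None:
        mountings = {name: random_mounting(rng) for name in ("waist", "thigh", "shank")}
    fs = angles.fs
    n_cal = int(round(calib_duration_s * fs))
    n = angles.hip_deg.size
    total = n_cal + n
    t = np.arange(total) / fs

    hip = np.concatenate([np.zeros(n_cal), np.radians(angles.hip_deg)])
    knee = np.concatenate([np.zeros(n_cal), np.radians(angles.knee_deg)])
    body = {
        "waist": np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (total, 1)),
        "thigh": q_from_axis_angle(_FLEXION_AXIS, hip),
        "shank": q_from_axis_angle(_FLEXION_AXIS, hip - knee),
    }
    poses = {}
    for name, qb in body.items():
        qs = q_multiply(qb, np.broadcast_to(mountings[name], (total, 4)))
        if orientation_noise_deg > 0:
            axes = rng.standard_normal((total, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            angs = np.radians(orientation_noise_deg) * rng.standard_normal(total)
            half = angs / 2.0
            dq = np.concatenate([np.cos(half)[:, None],
                                 np.sin(half)[:, None] * axes], axis=1)
            qs = q_normalize(q_multiply(qs, dq))
        poses[name] = PoseStream(sensor_id=name, timestamps=t, quaternions=qs)
    return poses, mountings, (0.0, calib_duration_s)


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator,
                         low_hz: float = 20.0, high_hz: float = 450.0) -> np.ndarray:
    high = min(high_hz, 0.45 * fs)
    sos = butter(4, [low_hz, high], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


def gen_emg(angles: GaitAngles, activation_map: list | None = None,
            noise: EmgNoiseConfig | None = None, seed: int = 0,
            amplitude_mv: float = 1.0):
    """Six channels of clean and contaminated surface EMG.

    clean = activation envelope × band-limited Gaussian carrier;
    noisy = clean + powerline + drift + white noise + sparse impulses.

    Returns
    -------
    (clean (6, N), noisy (6, N), envelopes (6, N), channel_names)
    """
    if activation_map is None:
        activation_map = default_activation_map()
    if noise is None:
        noise = EmgNoiseConfig()
    rng = np.random.default_rng(seed)
    n = angles.phase.size
    fs = angles.fs
    t = angles.timestamps
    clean = np.empty((len(activation_map), n))
    noisy = np.empty_like(clean)
    envs = np.empty_like(clean)
    names = []
    for c, (name, center, width, base) in enumerate(activation_map):
        names.append(name)
        env = base + (1.0 - base) * _circular_bump(angles.phase, center, width)
        carrier = _bandlimited_carrier(n, fs, rng)
        clean[c] = amplitude_mv * env * carrier
        envs[c] = env
        contaminated = clean[c].copy()
        if noise.powerline_amplitude > 0:
            contaminated += noise.powerline_amplitude * np.sin(
                2.0 * np.pi * noise.powerline_hz * t + rng.uniform(0, 2 * np.pi))
        if noise.drift_amplitude > 0:
            sos = butter(2, noise.drift_bandwidth_hz, btype="lowpass", fs=fs,
                         output="sos")
            drift = sosfiltfilt(sos, rng.standard_normal(n))
            drift_std = np.std(drift)
            if drift_std > 0:
                contaminated += noise.drift_amplitude * drift / drift_std
        if noise.white_noise_sigma > 0:
            contaminated += noise.white_noise_sigma * rng.standard_normal(n)
        if noise.artifact_rate > 0:
            n_events = rng.poisson(noise.artifact_rate * n / fs)
            pulse = np.exp(-np.arange(5) / 1.5)  # short decaying transient
            for _ in range(n_events):
                pos = rng.integers(0, n)
                amp = noise.artifact_amplitude * (0.5 + rng.exponential(1.0))
                amp *= rng.choice([-1.0, 1.0])
                stop = min(n, pos + pulse.size)
                contaminated[pos:stop] += amp * pulse[: stop - pos]
        noisy[c] = contaminated
    return clean, noisy, envs, tuple(names)


def gen_trial(profile: GaitProfile | None = None,
              noise: EmgNoiseConfig | None = None, seed: int = 0,
              orientation_noise_deg: float = 0.0,
              calib_duration_s: float = 2.0) -> SyntheticTrial:
    """Bundle angles, poses and EMG into one reproducible trial."""
    if profile is None:
        profile = GaitProfile()
    if noise is None:
        noise = EmgNoiseConfig()
    rng = np.random.default_rng(seed)
    s_angles, s_pose, s_emg = rng.integers(0, 2**31 - 1, size=3)
    angles = gen_angles(profile, seed=int(s_angles))
    poses, mountings, calib = gen_pose_streams(
        angles, orientation_noise_deg=orientation_noise_deg,
        seed=int(s_pose), calib_duration_s=calib_duration_s)
    clean, noisy, envs, names = gen_emg(angles, noise=noise, seed=int(s_emg))
    return SyntheticTrial(
        fs=profile.fs, angles=angles, clean_emg=clean, noisy_emg=noisy,
        envelopes=envs, channel_names=names, poses=poses,
        mountings=mountings, calib_interval=calib,
        gait_start_s=calib_duration_s, seed=seed)
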