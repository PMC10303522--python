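"""Quaternion sensor-to-segment calibration and hip/knee angle computation.

Three right-handed frames are used: the global frame G (X north, Y east,
Z down toward the Earth's centre), a body frame B fixed to each limb
segment, and each inertial sensor's own frame S.  Quaternions are Hamilton
convention, scalar-first; q_S^G rotates sensor-frame vectors into the
global frame via q ⊗ v ⊗ q*.

Calibration: the subject stands still facing north so B and G coincide;
the constant mounting rotation is then q_B^S = (q_{S,init}^G)*, the
conjugate of the sensor's time-averaged static orientation.  Afterwards
each segment's orientation is q_{B,t}^G = q_{S,t}^G ⊗ q_B^S.

Angles: the thigh, shank and trunk axes (unit vectors pointing distally —
hip→knee, knee→ankle, cranial→caudal) are rotated into G; the hip angle is
the angle between thigh and trunk axes, signed so flexion (thigh anterior)
is positive; the knee angle is the angle between thigh and shank axes,
which is 0° for a straight leg and positive in flexion only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PoseStream",
    "SegmentModel",
    "JointAngleSeries",
    "q_multiply",
    "q_conjugate",
    "q_normalize",
    "q_canonical",
    "q_rotate",
    "q_from_axis_angle",
    "quaternion_angle_deg",
    "calibrate_mounting",
    "body_orientation",
    "vector_angle",
    "joint_angles",
]

UNIT_TOL = 1e-6


def _check_unit(q: np.ndarray) -> None:
    norms = np.linalg.norm(np.atleast_2d(q), axis=-1)
    if np.any(np.abs(norms - 1.0) > UNIT_TOL):
        raise ValueError("quaternion is not unit-norm within tolerance")


def q_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b; accepts (4,) or (N, 4) arrays."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    aw, ax, ay, az = np.moveaxis(np.atleast_2d(a), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.atleast_2d(b), -1, 0)
    out = np.stack([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ], axis=-1)
    if a.ndim == 1 and b.ndim == 1:
        return out[0]
    return out


def q_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def q_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("zero quaternion cannot be normalized")
    return q / n


def q_canonical(q: np.ndarray) -> np.ndarray:
    """Resolve the q / -q ambiguity by making the scalar part >= 0."""
    q = np.asarray(q, dtype=np.float64)
    w = np.atleast_2d(q)[..., :1]
    sign = np.where(w < 0, -1.0, 1.0)
    out = np.atleast_2d(q) * sign
    return out[0] if q.ndim == 1 else out


def q_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by quaternion(s) q: q ⊗ v ⊗ q*."""
    q = np.asarray(q, dtype=np.float64)
    _check_unit(q)
    v = np.asarray(v, dtype=np.float64)
    v4 = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    out = q_multiply(q_multiply(q, v4), q_conjugate(q))
    return out[..., 1:]


def q_from_axis_angle(axis: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    """Unit quaternion(s) for rotation about a fixed unit axis."""
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    angle = np.asarray(angle_rad, dtype=np.float64)
    half = angle / 2.0
    w = np.cos(half)
    xyz = np.sin(half)[..., None] * axis
    return np.concatenate([w[..., None], xyz], axis=-1)


def quaternion_angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation angle between two orientations, in degrees."""
    d = q_multiply(q_conjugate(a), b)
    w = np.clip(np.abs(np.atleast_2d(d)[..., 0]), -1.0, 1.0)
    ang = np.degrees(2.0 * np.arccos(w))
    return ang[0] if np.asarray(a).ndim == 1 and np.asarray(b).ndim == 1 else ang


@dataclass
class PoseStream:
    """Orientation samples of one body-worn sensor in the global frame."""

    sensor_id: str
    timestamps: np.ndarray
    quaternions: np.ndarray  # (N, 4), scalar-first, unit

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.quaternions = np.asarray(self.quaternions, dtype=np.float64)
        if self.quaternions.ndim != 2 or self.quaternions.shape[1] != 4:
            raise ValueError("quaternions must be (N, 4)")
        if self.timestamps.size != self.quaternions.shape[0]:
            raise ValueError("timestamps and quaternions lengths differ")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        _check_unit(self.quaternions)

    def __len__(self) -> int:
        return self.timestamps.size

    def slice_time(self, t0: float, t1: float) -> "PoseStream":
        """Samples with t0 <= t < t1 (half-open, so an interval ending at
        the first moving sample does not leak it into calibration)."""
        m = (self.timestamps >= t0) & (self.timestamps < t1)
        return PoseStream(self.sensor_id, self.timestamps[m], self.quaternions[m])


@dataclass(frozen=True)
class SegmentModel:
    """Distally-pointing unit axes of thigh (U), shank (L) and trunk (W) in
    the body frame.  Defaults point down (+Z) in the neutral stance, so all
    angles are zero when the subject stands straight."""

    U_B: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    L_B: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    W_B: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    mediolateral_B: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        for name in ("U_B", "L_B", "W_B", "mediolateral_B"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} must be nonzero")
            object.__setattr__(self, name, v / n)


@dataclass
class JointAngleSeries:
    timestamps: np.ndarray
    hip_deg: np.ndarray  # signed, flexion positive
    knee_deg: np.ndarray  # flexion only, >= 0


def calibrate_mounting(q_init: np.ndarray, spread_warn_deg: float = 2.0) -> np.ndarray:
    """Constant sensor-to-body mounting rotation from the static stance.

    ``q_init`` is either a single quaternion or an (N, 4) block of samples
    over the static interval; samples are averaged with the chordal mean
    (sign-aligned, normalized component-wise mean).  Returns the conjugate
    of the mean orientation.  A non-static interval (orientation spread
    beyond ``spread_warn_deg``) triggers a warning.
    """
    q = np.asarray(q_init, dtype=np.float64)
    if q.ndim == 1:
        _check_unit(q)
        return q_conjugate(q)
    _check_unit(q)
    ref = q[0]
    signs = np.where(q @ ref < 0, -1.0, 1.0)
    mean = q_normalize((q * signs[:, None]).mean(axis=0))
    spread = quaternion_angle_deg(np.broadcast_to(mean, q.shape), q * signs[:, None])
    if np.max(spread) > spread_warn_deg:
        warnings.warn(
            f"calibration interval not static: orientation spread "
            f"{np.max(spread):.2f} deg exceeds {spread_warn_deg} deg")
    return q_conjugate(mean)


def body_orientation(q_sensor_t: np.ndarray, mounting: np.ndarray) -> np.ndarray:
    """Segment orientation in the global frame: q_{B,t}^G = q_{S,t}^G ⊗ q_B^S."""
    return q_multiply(q_sensor_t, mounting)


def vector_angle(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Unsigned angle between vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    nu = np.linalg.norm(u, axis=-1)
    nw = np.linalg.norm(w, axis=-1)
    if np.any(nu == 0) or np.any(nw == 0):
        raise ValueError("zero vector has no direction")
    c = np.clip(np.sum(u * w, axis=-1) / (nu * nw), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def _common_window(streams) -> tuple[float, float]:
    t0 = max(s.timestamps[0] for s in streams)
    t1 = min(s.timestamps[-1] for s in streams)
    return t0, t1


def joint_angles(waist: PoseStream, thigh: PoseStream, shank: PoseStream,
                 model: SegmentModel | None = None,
                 calib_interval: tuple[float, float] = (0.0, 2.0)) -> JointAngleSeries:
    """Hip and knee angle series from three time-aligned pose streams.

    The mounting rotation of each sensor is identified over
    ``calib_interval`` (neutral static stance), segment axes are rotated
    into the global frame, and per sample:

    * hip = angle(thigh axis, trunk axis), signed positive when the thigh
      points anteriorly of the trunk line (flexion), negative in extension;
    * knee = angle(thigh axis, shank axis), flexion only (straight leg 0°).
    """
    if model is None:
        model = SegmentModel()
    streams = {"waist": waist, "thigh": thigh, "shank": shank}
    n = len(waist)
    for s in streams.values():
        if len(s) != n or not np.allclose(s.timestamps, waist.timestamps):
            raise ValueError("pose streams must share identical timestamps")
    t0, t1 = calib_interval
    mountings = {}
    for name, s in streams.items():
        calib = s.slice_time(t0, t1)
        if len(calib) == 0:
            raise ValueError(f"no {name} samples inside the calibration interval")
        mountings[name] = calibrate_mounting(calib.quaternions)
    qb = {name: body_orientation(s.quaternions, mountings[name])
          for name, s in streams.items()}
    U_G = q_rotate(qb["thigh"], model.U_B)
    L_G = q_rotate(qb["shank"], model.L_B)
    W_G = q_rotate(qb["waist"], model.W_B)
    m_G = q_rotate(qb["waist"], model.mediolateral_B)
    hip = vector_angle(U_G, W_G)
    # anterior axis: mediolateral x trunk axis (right-handed, trunk points down)
    anterior = np.cross(m_G, W_G)
    sign = np.where(np.sum(U_G * anterior, axis=-1) < 0, -1.0, 1.0)
    hip = sign * hip
    knee = vector_angle(U_G, L_G)
    return JointAngleSeries(timestamps=waist.timestamps.copy(),
                            hip_deg=hip, knee_deg=knee)
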