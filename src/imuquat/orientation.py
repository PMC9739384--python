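"""Orientation estimation from raw 6-axis IMU streams.

The estimator initializes the body orientation from the gravity
direction measured by the accelerometer at rest and then propagates it
by integrating the gyroscope, one first-order step per sample:

* the initial inclination is ``θ(0) = arccos(acc_z(0) / ‖acc(0)‖)``,
  the tilt of the sensor's up-axis away from vertical;
* the initial rotation axis is the horizontal vector
  ``V(0) = (-acc_y(0), acc_x(0), 0)``;
* the initial quaternion is
  ``q(0) = [cos(θ(0)/2), sin(θ(0)/2) · V(0)/‖V(0)‖]``;
* each step maps the measured rate into the reference frame,
  ``Ω(t) = q(t-1) ⊗ (ω(t)/f) ⊗ q(t-1)^{-1}``, forms the incremental
  rotation ``Φ(t) = [1, Ω(t)/2]`` and composes
  ``q(t) = Φ(t) ⊗ q(t-1)``, renormalized.

The first-order increment assumes the sampling frequency ``f`` is high
relative to the angular rates; at low rates (e.g. 1 Hz collars) the
integration still runs but accrues discretization drift, which this
module measures rather than corrects — there is no accelerometer or
magnetometer feedback after the initial sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import quaternions as quat
from .exceptions import InvalidInputError

__all__ = [
    "ImuSample",
    "ImuTrace",
    "OrientationTrack",
    "initial_inclination",
    "initial_rotation_axis",
    "initial_quaternion",
    "integrate_step",
    "estimate_orientation",
]

# Below this inclination the rotation axis is numerically undefined and
# the initial quaternion degenerates to identity (or, at the antipode,
# to a half-turn about a fixed fallback axis).
_DEGENERATE_ANGLE = 1e-9


@dataclass(frozen=True)
class ImuSample:
    """One 6-axis reading: timestamp (s), acceleration (g), rate (rad/s)."""

    t: float
    acc: np.ndarray
    gyro: np.ndarray


@dataclass
class ImuTrace:
    """A time-ordered 6-axis recording at fixed sampling frequency.

    Parameters
    ----------
    t : array, shape (n,)
        Timestamps in seconds, strictly increasing, uniformly spaced.
    acc : array, shape (n, 3)
        Accelerometer readings in units of g.
    gyro : array, shape (n, 3)
        Gyroscope readings in rad/s.
    f : float
        Sampling frequency in Hz; sample spacing must agree with
        ``1/f`` within 1%.
    label : str, optional
        Behavior class of the whole trace, if known.
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    f: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        n = len(self.t)
        if n == 0:
            raise InvalidInputError("empty trace")
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise InvalidInputError(
                f"acc/gyro must have shape ({n}, 3); got {self.acc.shape} and {self.gyro.shape}"
            )
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.acc)) and np.all(np.isfinite(self.gyro))):
            raise InvalidInputError("trace contains non-finite values")
        if self.f <= 0:
            raise InvalidInputError("sampling frequency must be positive")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise InvalidInputError("timestamps must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.f) > 0.01 / self.f):
                raise InvalidInputError("sample spacing inconsistent with sampling frequency")

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i: int) -> ImuSample:
        return ImuSample(t=float(self.t[i]), acc=self.acc[i], gyro=self.gyro[i])


@dataclass
class OrientationTrack:
    """Per-sample orientation quaternions plus the initial inclination."""

    quaternions: np.ndarray
    theta0: float = 0.0

    def __post_init__(self) -> None:
        self.quaternions = np.atleast_2d(np.asarray(self.quaternions, dtype=float))
        if self.quaternions.shape[-1] != 4:
            raise InvalidInputError("quaternions must have 4 components")

    def __len__(self) -> int:
        return len(self.quaternions)


def initial_inclination(acc0: np.ndarray) -> float:
    """Tilt angle (rad) of the at-rest gravity reading away from vertical.

    The accelerometer vector is unit-normalized and its z-component
    clamped to ``[-1, 1]`` before the arccos, so slightly noisy or
    miscalibrated readings stay in the valid domain. Result in
    ``[0, π]``.
    """
    acc0 = np.asarray(acc0, dtype=float)
    n = np.linalg.norm(acc0)
    if n == 0.0:
        raise InvalidInputError("zero accelerometer vector has no inclination")
    return float(np.arccos(np.clip(acc0[2] / n, -1.0, 1.0)))


def initial_rotation_axis(acc0: np.ndarray) -> np.ndarray:
    """Horizontal axis ``(-acc_y, acc_x, 0)`` aligning vertical with z.

    This is ``-acc(0) × z``; its z-component is always zero. The
    degenerate all-zero result (gravity already along ±z) is left to
    the caller.
    """
    acc0 = np.asarray(acc0, dtype=float)
    return np.array([-acc0[1], acc0[0], 0.0])


def initial_quaternion(acc0: np.ndarray) -> np.ndarray:
    """Orientation at rest from the first accelerometer sample.

    Returns the unit quaternion
    ``[cos(θ(0)/2), sin(θ(0)/2) · V(0)/‖V(0)‖]`` that rotates the
    vertical axis onto the measured gravity direction; equivalently,
    ``rotate_vector(inverse(q0), acc0/‖acc0‖) == (0, 0, 1)``.

    Degenerate cases: gravity along +z gives the identity; gravity
    along -z (upside-down sensor) gives a half-turn about the x-axis,
    a fixed convention since every horizontal axis is equivalent there.
    """
    theta = initial_inclination(acc0)
    axis = initial_rotation_axis(acc0)
    axis_norm = np.linalg.norm(axis)
    if axis_norm < _DEGENERATE_ANGLE or theta < _DEGENERATE_ANGLE:
        if theta > np.pi / 2:
            return np.array([0.0, 1.0, 0.0, 0.0])  # half-turn about x
        return quat.IDENTITY.copy()
    return np.concatenate(
        [[np.cos(theta / 2.0)], np.sin(theta / 2.0) * axis / axis_norm]
    )


def integrate_step(q_prev: np.ndarray, omega: np.ndarray, f: float) -> np.ndarray:
    """Advance the orientation by one gyroscope sample.

    ``Ω = q_prev ⊗ (ω/f) ⊗ q_prev^{-1}`` maps the body-frame rate into
    the reference frame; the first-order increment ``Φ = [1, Ω/2]`` is
    composed on the left and the product renormalized (the raw
    increment is non-unit, so without renormalization the norm would
    grow monotonically).
    """
    if f <= 0:
        raise InvalidInputError("sampling frequency must be positive")
    omega = np.asarray(omega, dtype=float)
    if not omega.any():  # zero rate: exact fixed point, no renormalization
        return np.asarray(q_prev, dtype=float)
    big_omega = quat.rotate_vector(q_prev, omega / f)
    phi = np.concatenate([[1.0], big_omega / 2.0])
    return quat.normalize(quat.multiply(phi, q_prev))


def estimate_orientation(trace: ImuTrace, rest_samples: int = 1) -> OrientationTrack:
    """Estimate the per-sample orientation of a 6-axis trace.

    The initial quaternion comes from the accelerometer (averaged over
    the first ``rest_samples`` readings, assumed taken at rest; the
    default uses the single first sample); every subsequent quaternion
    comes from :func:`integrate_step` applied to that sample's
    gyroscope reading. Output has one unit quaternion per input sample.
    """
    if not isinstance(trace, ImuTrace):
        raise InvalidInputError("estimate_orientation expects an ImuTrace")
    if rest_samples < 1:
        raise InvalidInputError("rest_samples must be >= 1")
    n = len(trace)
    acc0 = trace.acc[: min(rest_samples, n)].mean(axis=0)
    q = initial_quaternion(acc0)
    out = np.empty((n, 4))
    out[0] = q
    inv_f = 1.0 / trace.f
    # Unrolled integrate_step: the per-step work is identical but avoids
    # redundant unit-norm checks inside a long sequential loop.
    for k in range(1, n):
        if not trace.gyro[k].any():  # zero rate: exact fixed point
            out[k] = q
            continue
        w, x, y, z = q
        gx, gy, gz = trace.gyro[k] * inv_f
        # Ω = q (ω/f) q⁻¹ via the unit-quaternion Rodrigues expansion
        tx = 2.0 * (y * gz - z * gy)
        ty = 2.0 * (z * gx - x * gz)
        tz = 2.0 * (x * gy - y * gx)
        ox = gx + w * tx + (y * tz - z * ty)
        oy = gy + w * ty + (z * tx - x * tz)
        oz = gz + w * tz + (x * ty - y * tx)
        hx, hy, hz = ox / 2.0, oy / 2.0, oz / 2.0
        # Φ ⊗ q with Φ = (1, hx, hy, hz)
        nw = w - hx * x - hy * y - hz * z
        nx = x + hx * w + hy * z - hz * y
        ny = y - hx * z + hy * w + hz * x
        nz = z + hx * y - hy * x + hz * w
        s = 1.0 / np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
        q = np.array([nw * s, nx * s, ny * s, nz * s])
        out[k] = q
    return OrientationTrack(quaternions=out, theta0=initial_inclination(acc0))
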