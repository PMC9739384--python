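"""Quaternion algebra for rigid-body orientation.

Conventions used throughout the package:

* quaternions are stored scalar-first, ``(w, x, y, z)``;
* the product is the Hamilton product in right-handed frames;
* a unit quaternion ``q`` acts on a 3-vector ``v`` by conjugation,
  ``q [0, v] q^{-1}``, equivalent to applying the corresponding
  rotation matrix.

All functions accept batches: an argument of shape ``(..., 4)`` (or
``(..., 3)`` for vectors) is processed element-wise over the leading
axes, so a whole orientation track can be rotated in one call.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "IDENTITY",
    "norm",
    "normalize",
    "multiply",
    "conjugate",
    "inverse",
    "rotate_vector",
    "from_axis_angle",
    "geodesic_distance",
]

#: The identity rotation, (1, 0, 0, 0).
IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

_UNIT_TOL = 1e-6


def norm(q: np.ndarray) -> np.ndarray:
    """Euclidean norm over the last axis."""
    return np.linalg.norm(np.asarray(q, dtype=float), axis=-1)


def normalize(q: np.ndarray) -> np.ndarray:
    """Scale ``q`` to unit norm.

    Raises
    ------
    InvalidInputError
        If any quaternion in the batch has zero norm.
    """
    q = np.asarray(q, dtype=float)
    n = norm(q)
    if np.any(n == 0.0) or not np.all(np.isfinite(n)):
        raise InvalidInputError("cannot normalize a zero or non-finite quaternion")
    return q / n[..., np.newaxis]


def multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` (scalar-first, non-commutative)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    """Conjugate ``(w, -x, -y, -z)``; the inverse for unit quaternions."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def inverse(q: np.ndarray) -> np.ndarray:
    """Multiplicative inverse, ``conjugate(q) / |q|^2``.

    Raises
    ------
    InvalidInputError
        If ``q`` has zero norm.
    """
    q = np.asarray(q, dtype=float)
    n2 = np.sum(q * q, axis=-1)
    if np.any(n2 == 0.0):
        raise InvalidInputError("zero quaternion has no inverse")
    return conjugate(q) / n2[..., np.newaxis]


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q``.

    Computes the vector part of ``q ⊗ [0, v] ⊗ q^{-1}``; the Euclidean
    length of ``v`` is preserved.

    Raises
    ------
    InvalidInputError
        If ``q`` deviates from unit norm by more than ``1e-6``.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(np.abs(norm(q) - 1.0) > _UNIT_TOL):
        raise InvalidInputError("rotate_vector requires unit quaternions")
    w = q[..., 0:1]
    u = q[..., 1:]
    # Rodrigues-style expansion of the conjugation, valid for unit q.
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle`` radians about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis, axis=-1)
    if np.any(n == 0.0):
        raise InvalidInputError("rotation axis must be non-zero")
    angle = np.asarray(angle, dtype=float)
    half = angle / 2.0
    return np.concatenate(
        [
            np.cos(half)[..., np.newaxis],
            np.sin(half)[..., np.newaxis] * axis / n[..., np.newaxis],
        ],
        axis=-1,
    )


def geodesic_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle (rad) of the relative rotation between unit quaternions.

    Antipodal quaternions represent the same rotation, so the distance
    is computed on the absolute inner product and lies in ``[0, π]``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = np.abs(np.sum(a * b, axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))
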