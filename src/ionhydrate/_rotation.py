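"""Rotation-vector (exponential-map) utilities for rigid-body poses.

Orientations are stored as rotation vectors p = theta * axis ("angle-axis").
``scipy.spatial.transform.Rotation`` handles conversion to matrices and
quaternions; the analytic derivative of the rotation matrix with respect to
the rotation-vector components is implemented here because scipy does not
expose it.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

_SMALL_ANGLE = 1e-10


def rotation_matrices(rotvecs: np.ndarray) -> np.ndarray:
    """Batch of rotation matrices, shape (M, 3, 3), from rotvecs (M, 3)."""
    return Rotation.from_rotvec(np.atleast_2d(rotvecs)).as_matrix()


def _skew(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric cross-product matrices for vectors of shape (..., 3)."""
    z = np.zeros(v.shape[:-1])
    return np.stack(
        [
            np.stack([z, -v[..., 2], v[..., 1]], axis=-1),
            np.stack([v[..., 2], z, -v[..., 0]], axis=-1),
            np.stack([-v[..., 1], v[..., 0], z], axis=-1),
        ],
        axis=-2,
    )


def rotation_matrix_derivatives(rotvecs: np.ndarray) -> np.ndarray:
    """d R / d p_k for a batch of rotation vectors.

    Returns an array of shape (M, 3, 3, 3) whose [m, k] entry is the 3x3
    derivative of R(p_m) with respect to component p_k.  Uses the compact
    closed form

        dR/dp_k = ( p_k [p]x + [ p x (I - R) e_k ]x ) / |p|^2  .  R

    with the limit dR/dp_k -> [e_k]x as p -> 0.
    """
    P = np.atleast_2d(rotvecs)
    M = P.shape[0]
    R = rotation_matrices(P)
    out = np.empty((M, 3, 3, 3))
    theta2 = np.einsum("mi,mi->m", P, P)
    small = theta2 < _SMALL_ANGLE**2

    eye = np.eye(3)
    if np.any(small):
        for k in range(3):
            out[small, k] = _skew(eye[k])
    big = ~small
    if np.any(big):
        Pb = P[big]
        Rb = R[big]
        t2 = theta2[big][:, None, None]
        Px = _skew(Pb)
        # columns of (I - R): (I - R) e_k
        ImR = eye[None, :, :] - Rb
        for k in range(3):
            v = ImR[:, :, k]  # (I - R) e_k
            cross = np.cross(Pb, v)
            A = (Pb[:, k, None, None] * Px + _skew(cross)) / t2
            out[big, k] = A @ Rb
    return out


def wrap_rotvec(rotvecs: np.ndarray) -> np.ndarray:
    """Wrap rotation vectors to the canonical ball |p| <= pi."""
    P = np.array(np.atleast_2d(rotvecs), dtype=float)
    theta = np.linalg.norm(P, axis=1)
    mask = theta > np.pi
    if np.any(mask):
        t = theta[mask]
        # equivalent angle in (-pi, pi]
        t_new = np.mod(t + np.pi, 2 * np.pi) - np.pi
        P[mask] *= (t_new / t)[:, None]
    return P


def random_rotvec(rng: np.random.Generator, max_angle: float, size: int) -> np.ndarray:
    """Uniform random rotation axes with angles uniform in [0, max_angle]."""
    axes = rng.normal(size=(size, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.uniform(0.0, max_angle, size=size)
    return axes * angles[:, None]


def compose_rotvec(delta: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Rotation vector of R(delta) @ R(base), batched."""
    r = Rotation.from_rotvec(np.atleast_2d(delta)) * Rotation.from_rotvec(
        np.atleast_2d(base)
    )
    return r.as_rotvec()


def minimal_rotation_between(u: np.ndarray, v: np.ndarray) -> Rotation:
    """Smallest-angle rotation taking unit vector u onto unit vector v."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        # antiparallel: rotate by pi about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp)
    axis = axis / s
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * axis)
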