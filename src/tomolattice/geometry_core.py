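"""Rotation and frame arithmetic shared by all pipeline stages.

Conventions (fixed once, used everywhere):

* Rotations act on column vectors: ``v_world = R @ v_local``.
* Euler triples ``(z1, x, z2)`` are *intrinsic* rotations composed
  left-to-right, i.e. ``R = Rz(z1) @ Rmid(x) @ Rz(z2)`` where the middle
  axis is x for the ``"zxz-dynamo"`` dialect and y for ``"zyz-relion"``.
  Positive angles are counter-clockwise looking down the axis toward the
  origin (right-hand rule).
* The tilt angle x lies in [0, 180]; z1, z2 in [0, 360). At gimbal lock
  (tilt 0 or 180) the decomposition is degenerate and canonicalized to
  z2 = 0.

A worked example: ``euler_to_matrix((90, 0, 0), "zxz-dynamo")`` rotates by
90 deg about z and maps unit-x to unit-y.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation

from .models import FilamentPath

__all__ = [
    "EULER_CONVENTIONS",
    "euler_to_matrix",
    "matrix_to_euler",
    "angle_between_deg",
    "build_local_frames",
    "validate_rotation",
]

# convention tag -> scipy intrinsic axis sequence
EULER_CONVENTIONS = {
    "zxz-dynamo": "ZXZ",
    "zyz-relion": "ZYZ",
}

_ORTHO_TOL = 1e-9


def _seq_for(convention: str) -> str:
    try:
        return EULER_CONVENTIONS[convention]
    except KeyError:
        raise ValueError(
            f"unknown Euler convention {convention!r}; "
            f"supported: {sorted(EULER_CONVENTIONS)}"
        ) from None


def validate_rotation(m: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Check that ``m`` is a proper rotation (orthonormal, det +1)."""
    m = np.asarray(m, dtype=float).reshape(3, 3)
    if not np.allclose(m.T @ m, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if abs(np.linalg.det(m) - 1.0) > tol:
        raise ValueError("matrix determinant is not +1 (improper rotation)")
    return m


def euler_to_matrix(euler: tuple, convention: str = "zxz-dynamo") -> np.ndarray:
    """Convert an Euler triple (z1, x, z2) in degrees to a rotation matrix."""
    seq = _seq_for(convention)
    z1, x, z2 = (float(a) for a in euler)
    return Rotation.from_euler(seq, [z1, x, z2], degrees=True).as_matrix()


def matrix_to_euler(m: np.ndarray, convention: str = "zxz-dynamo") -> tuple:
    """Decompose a proper rotation into (z1, x, z2) degrees.

    z1 and z2 are reduced to [0, 360), x to [0, 180]. Gimbal-locked
    matrices return the canonical form z2 = 0.
    """
    m = validate_rotation(m)
    seq = _seq_for(convention)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at gimbal lock
        z1, x, z2 = Rotation.from_matrix(m).as_euler(seq, degrees=True)
    # scipy already parks the degenerate freedom in the third angle = 0
    z1 %= 360.0
    z2 %= 360.0
    x = float(np.clip(x, 0.0, 180.0))
    # exact canonical form at lock
    if x < 1e-9 or x > 180.0 - 1e-9:
        z1 = (z1 + z2) % 360.0 if x < 90.0 else (z1 - z2) % 360.0
        z2 = 0.0
    return (float(z1), float(x), float(z2))


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two nonzero vectors, degrees in [0, 180]."""
    u = np.asarray(u, dtype=float).reshape(3)
    v = np.asarray(v, dtype=float).reshape(3)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("angle undefined for zero vector")
    c = np.dot(u, v) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def tangents_central_diff(nodes: np.ndarray) -> np.ndarray:
    """Unit tangents from central differences (one-sided at the ends)."""
    nodes = np.asarray(nodes, dtype=float)
    n = len(nodes)
    if n < 2:
        raise ValueError("need >= 2 nodes for tangents")
    t = np.empty_like(nodes)
    t[0] = nodes[1] - nodes[0]
    t[-1] = nodes[-1] - nodes[-2]
    if n > 2:
        t[1:-1] = nodes[2:] - nodes[:-2]
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def build_local_frames(path: FilamentPath) -> np.ndarray:
    """Per-node orthonormal frames (tangent, normal, binormal).

    Returns an (n, 3, 3) array; ``frames[i] = [t, n, b]`` rows. Normals are
    propagated by parallel transport (rotation carrying tangent i-1 onto
    tangent i), so frames never flip between consecutive nodes. For a
    straight path all frames are identical.
    """
    if path.nodes is None or len(path.nodes) < 2:
        raise ValueError("path must be resampled with >= 2 nodes")
    tangents = (
        path.tangents
        if path.tangents is not None
        else tangents_central_diff(path.nodes)
    )
    n = len(tangents)
    frames = np.empty((n, 3, 3))
    t0 = tangents[0]
    # initial normal: reject the world axis least aligned with the tangent
    ref = np.eye(3)[np.argmin(np.abs(t0))]
    n0 = _unit(ref - np.dot(ref, t0) * t0)
    frames[0] = [t0, n0, np.cross(t0, n0)]
    for i in range(1, n):
        t_prev, t_cur = tangents[i - 1], tangents[i]
        axis = np.cross(t_prev, t_cur)
        s = np.linalg.norm(axis)
        c = np.clip(np.dot(t_prev, t_cur), -1.0, 1.0)
        if s < 1e-12:
            normal = frames[i - 1, 1]
        else:
            rot = Rotation.from_rotvec(axis / s * np.arctan2(s, c))
            normal = rot.apply(frames[i - 1, 1])
        normal = _unit(normal - np.dot(normal, t_cur) * t_cur)
        frames[i] = [t_cur, normal, np.cross(t_cur, normal)]
    return frames
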