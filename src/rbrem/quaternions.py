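"""Minimal quaternion helpers for rigid-body orientation.

Quaternions are stored as (w, x, y, z) unit 4-vectors; ``rotation_matrix``
maps body-frame vectors to the world frame (world = R @ body).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["multiply", "rotation_matrix", "from_matrix", "axis_quat", "normalize"]


def multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 ⊗ q2."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def rotation_matrix(q: np.ndarray) -> np.ndarray:
    """3×3 rotation matrix of unit quaternion q (body → world)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def from_matrix(m: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a proper rotation matrix."""
    from scipy.spatial.transform import Rotation
    x, y, z, w = Rotation.from_matrix(m).as_quat()
    return np.array([w, x, y, z])


def axis_quat(axis: int, angle: float) -> np.ndarray:
    """Quaternion for rotation by ``angle`` about principal axis 0, 1 or 2."""
    half = 0.5 * angle
    q = np.array([math.cos(half), 0.0, 0.0, 0.0])
    q[1 + axis] = math.sin(half)
    return q


def normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)
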