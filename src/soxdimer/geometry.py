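"""Small geometric primitives shared across the modelling modules.

Everything here operates on plain numpy arrays: points are shape ``(3,)``,
point sets ``(n, 3)``, rotation matrices ``(3, 3)`` with determinant +1.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_about_axis",
    "dihedral",
    "angle_between",
    "principal_axis",
    "kabsch_rmsd",
    "random_rotation",
]


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    u = axis / n
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(u, u)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points.

    Sign follows the biomolecular convention: the C-alpha pseudo-torsion of a
    right-handed alpha-helix is close to +50 degrees.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n0 = np.cross(b0, b1)
    n1 = np.cross(b1, b2)
    b1_hat = b1 / np.linalg.norm(b1)
    return float(
        np.degrees(np.arctan2(np.dot(np.cross(n0, n1), b1_hat), np.dot(n0, n1)))
    )


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two vectors, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def principal_axis(points: np.ndarray, orient_along=None) -> np.ndarray:
    """Unit vector of the dominant principal component of a point cloud.

    If ``orient_along`` is given the sign is chosen so the axis has positive
    projection onto it (useful to orient a helix axis from N- to C-terminus).
    """
    pts = np.asarray(points, dtype=float)
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if orient_along is not None and np.dot(axis, orient_along) < 0:
        axis = -axis
    return axis


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two same-shape point sets after optimal superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = ac @ r.T - bc
    return float(np.sqrt((diff**2).sum() / len(a)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via the uniform-quaternion method."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
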