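"""Low-level vector geometry: internal-coordinate atom placement, rotations,
torsions, and least-squares superposition."""
from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "rotation_about_axis",
    "bond_angle",
    "dihedral",
    "kabsch",
    "rmsd",
    "random_unit_quaternion",
    "quaternion_to_matrix",
]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a new atom D from three reference positions (NeRF).

    D satisfies |C-D| = ``bond``, angle(B,C,D) = ``angle`` and
    dihedral(A,B,C,D) = ``torsion`` (degrees).
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("reference atoms A, B, C are collinear")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle A-B-C in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees) of the four points, IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with the convention ``x_fit = x @ R.T + t``.
    Raises ``ValueError`` for fewer than 3 points or a collinear point set,
    where the rotation is not uniquely determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 paired points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    P = mobile - mc
    Q = target - tc
    # collinearity: second singular value of either centred set ~ 0
    for pts in (P, Q):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] < 1e-6 * max(sv[0], 1.0):
            raise ValueError(
                "mapped atoms are collinear; rotation underdetermined")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - mc @ R.T
    fitted = mobile @ R.T + t
    return R, t, rmsd(fitted, target)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two matched coordinate sets (no fit)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation quaternion (normalized 4-vector of normals)."""
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
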