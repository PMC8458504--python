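"""Small geometric primitives shared by structure handling, conformers and docking.

Kabsch superposition, RMSD variants, internal-coordinate atom placement (NeRF)
and seeded uniform rotations.
"""

from __future__ import annotations

import numpy as np


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centred P onto centred Q (Kabsch)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD between two conformations after optimal rigid superposition.

    Atom correspondence is positional (no symmetry correction).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"coordinate shapes differ: {P.shape} vs {Q.shape}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    R = kabsch_rotation(Pc, Qc)
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff * diff).sum() / len(P)))


def rmsd_no_superposition(P: np.ndarray, Q: np.ndarray) -> float:
    """Plain coordinate RMSD in a common frame (used for docking poses)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"coordinate shapes differ: {P.shape} vs {Q.shape}")
    diff = P - Q
    return float(np.sqrt((diff * diff).sum() / len(P)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms A, B, C.

    NeRF construction: |CD| = bond, angle(B,C,D) = angle_deg,
    dihedral(A,B,C,D) = torsion_deg.
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        # colinear reference frame; pick an arbitrary perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def random_unit_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n quaternions uniform on SO(3) (Shoemake's subgroup algorithm)."""
    u1, u2, u3 = rng.random((3, n))
    q = np.stack([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ], axis=1)
    # reorder to (w, x, y, z)
    return q[:, [3, 0, 1, 2]]


def rotvec_to_matrix(v: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (axis * angle, Rodrigues)."""
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spaced unit vectors (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
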