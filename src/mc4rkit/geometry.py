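"""Rigid-body and internal-coordinate geometry primitives.

Small, dependency-light helpers shared by the structure, contact, and
synthetic-model code: Kabsch superposition, torsion-based atom placement
(the NeRF construction), and ideal Cβ building.
"""

from __future__ import annotations

import numpy as np

# ideal backbone internal coordinates (Engh–Huber-like values)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
TORSION_C_N_CA_CB = -122.6

# ideal alpha-helix torsions
HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA_TRANS = 180.0

#: nominal helical parameters used for layout bookkeeping
HELIX_RISE_PER_RESIDUE = 1.5   # Å
HELIX_TWIST_PER_RESIDUE = 100.0  # degrees
CA_CA_DISTANCE = 3.8  # Å


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D given atoms A-B-C, the C-D bond length, the B-C-D
    angle, and the A-B-C-D torsion (natural extension reference frame)."""
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cβ at ideal tetrahedral geometry from the backbone N, CA, C."""
    return place_atom(c, n, ca, BOND_CA_CB, ANGLE_N_CA_CB, TORSION_C_N_CA_CB)


def kabsch(mobile: np.ndarray, target: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(R, t, rmsd)`` with the proper rotation (det = +1) and
    translation mapping ``mobile`` onto ``target`` as ``R @ x + t``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("at least 3 point pairs are required")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10:
        raise ValueError("degenerate (collinear) geometry; superposition "
                         "is under-determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    moved = Pc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Qc) ** 2, axis=1))))
    return R, t, rmsd


def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    ca, sa = np.cos(a), np.sin(a)
    return np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])


def rotation_between(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying one direction onto another."""
    a, b = unit(np.asarray(v_from, float)), unit(np.asarray(v_to, float))
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite directions: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp = unit(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
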