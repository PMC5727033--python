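"""Backbone geometry primitives.

Ideal covalent parameters, NeRF-style chain construction from torsion
angles, dihedral measurement, and Kabsch superposition.  Everything here
works on plain numpy arrays; residue-level bookkeeping lives in
:mod:`adrpipe.structures`.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone covalent geometry (Engh/Huber-style values, Angstrom, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.02  # amide proton build-out length
BOND_CA_CB = 1.521

ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
ANGLE_C_CA_CB = 110.1

# Ideal beta-strand backbone torsions.
BETA_PHI = -139.0
BETA_PSI = 135.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A, B, C and internal coordinates.

    ``bond`` = |C-D|, ``angle`` = B-C-D in degrees, ``torsion`` = dihedral
    A-B-C-D in degrees (standard NeRF construction).
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d2 = bond * np.array([-np.cos(ang),
                          np.sin(ang) * np.cos(tor),
                          np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def dihedral(p0, p1, p2, p3) -> float | np.ndarray:
    """Signed dihedral angle in degrees.  Accepts (..., 3) stacked arrays."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    return np.rad2deg(np.arctan2(y, x))


def wrap_angle(delta):
    """Wrap angular differences (degrees) into (-180, 180]."""
    return -((-np.asarray(delta) + 180.0) % 360.0 - 180.0)


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   omega: np.ndarray | float = 180.0) -> dict[str, np.ndarray]:
    """Build N/CA/C coordinates for a chain from phi/psi (degrees).

    phi[0] and psi[-1] are not geometrically meaningful but must be supplied
    (phi[0] is ignored, psi[-1] fixes the final carbonyl direction).
    Returns dict with 'N', 'CA', 'C' arrays of shape (n, 3).
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    omega = np.full(n, omega, dtype=float) if np.isscalar(omega) else np.asarray(omega, float)

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    # seed triad for residue 0
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi[i])
    return {"N": N, "CA": CA, "C": C}


def add_amide_hydrogens(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Amide H for residues 1..n-1 along the anti-bisector of CA-N and C(i-1)-N.

    Residue 0 (no preceding carbonyl) gets an H trans to its own carbonyl
    direction so that every residue carries an HN.
    """
    n = len(N)
    H = np.zeros((n, 3))
    for i in range(n):
        if i == 0:
            u = _unit(N[i] - CA[i]) + _unit(N[i] - C[i])
        else:
            u = _unit(N[i] - CA[i]) + _unit(N[i] - C[i - 1])
        H[i] = N[i] + BOND_N_H * _unit(u)
    return H


def add_carbonyl_oxygens(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Carbonyl O along the anti-bisector of CA-C and N(i+1)-C (sp2 carbon)."""
    n = len(N)
    O = np.zeros((n, 3))
    for i in range(n):
        if i < n - 1:
            u = _unit(C[i] - CA[i]) + _unit(C[i] - N[i + 1])
        else:
            # terminal residue: mirror the previous peptide-plane geometry
            u = _unit(C[i] - CA[i]) + _unit(C[i] - N[i])
        O[i] = C[i] + BOND_C_O * _unit(u)
    return O


def add_beta_carbons(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """CB placed at ideal tetrahedral geometry with L-chirality."""
    n = len(N)
    CB = np.zeros((n, 3))
    c1 = np.cos(np.deg2rad(ANGLE_N_CA_CB))
    c2 = np.cos(np.deg2rad(ANGLE_C_CA_CB))
    for i in range(n):
        t1 = _unit(N[i] - CA[i])
        t2 = _unit(C[i] - CA[i])
        p = _unit(np.cross(t1, t2))
        # solve u = a*t1 + b*t2 + c*p with u.t1=c1, u.t2=c2, |u|=1, c>0 (L)
        dot = t1 @ t2
        M = np.array([[1.0, dot], [dot, 1.0]])
        a, b = np.linalg.solve(M, [c1, c2])
        rest = 1.0 - (a * a + b * b + 2 * a * b * dot)
        c = np.sqrt(max(rest, 0.0))
        u = a * t1 + b * t2 + c * p
        CB[i] = CA[i] + BOND_CA_CB * _unit(u)
    return CB


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centred P onto centred Q (proper rotation)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superposed_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD of P onto Q after optimal rigid superposition."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape:
        raise ValueError("coordinate sets differ in shape")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    R = kabsch_rotation(Pc, Qc)
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff ** 2).sum() / len(P)))
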