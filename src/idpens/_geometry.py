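"""Internal geometry engine: internal-coordinate atom placement, backbone
construction from dihedrals, dihedral measurement, and Kabsch superposition.

All public modules work in nanometers; this module builds in Angstrom
(the natural unit of the bond-geometry constants) and callers convert once.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone geometry (Angstrom / degrees). Dihedrals are the only
# degrees of freedom; bond lengths and angles are fixed.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_N_H = 119.0

ANGSTROM_PER_NM = 10.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d at distance *bond* from c, angle b-c-d, dihedral a-b-c-d.

    Natural-extension (NeRF) construction; inputs and output in the same
    length unit.
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(dihedral_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # a-b-c collinear: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(phi: np.ndarray, psi: np.ndarray,
                   omega: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Build an N/H/CA/C/O backbone from per-residue dihedrals (degrees).

    phi[0] and the chain-closing use of psi[-1] affect no inter-residue
    geometry; psi[i] also orients the carbonyl O of residue i.  Returns a
    dict of (n_res, 3) arrays in Angstrom.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = phi.shape[0]
    if psi.shape[0] != n_res:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = np.full(n_res, 180.0)

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    H = np.zeros((n_res, 3))

    # first residue in a canonical frame
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA,
                               omega[i])
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C,
                              ANGLE_N_CA_C, phi[i + 1])

    for i in range(n_res):
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                          psi[i] + 180.0)
        if i == 0:
            H[i] = place_atom(C[i], CA[i], N[i], BOND_N_H, ANGLE_C_N_H, 180.0)
        else:
            # amide H roughly trans to the carbonyl O of the previous residue
            H[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_H,
                              ANGLE_C_N_H, 180.0)
    return {"N": N, "H": H, "CA": CA, "C": C, "O": O}


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def backbone_dihedrals(N: np.ndarray, CA: np.ndarray,
                       C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """phi/psi per residue (degrees); phi[0] and psi[-1] are NaN."""
    n_res = N.shape[0]
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    for i in range(n_res):
        if i > 0:
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < n_res - 1:
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
    return phi, psi


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimal RMSD between two (m, 3) coordinate sets over proper rotations
    and translations (Kabsch, no reflection)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    ssd = (P * P).sum() + (Q * Q).sum() - 2.0 * (S[0] + S[1] + d * S[2])
    rmsd = float(np.sqrt(max(ssd, 0.0) / P.shape[0]))
    if rmsd < 1e-6:   # trace formula cancels near zero; use residuals
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        rmsd = float(np.sqrt(((Q @ R - P) ** 2).sum() / P.shape[0]))
    return rmsd


def kabsch_rmsd_many(P: np.ndarray, Qs: np.ndarray) -> np.ndarray:
    """Minimal RMSD of one (m, 3) reference against a (k, m, 3) batch."""
    P = P - P.mean(axis=0)
    Qs = Qs - Qs.mean(axis=1, keepdims=True)
    H = np.einsum("mi,kmj->kij", P, Qs)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("kij,klj->kil", Vt.transpose(0, 2, 1),
                                  U.transpose(0, 2, 1)))
    # det of V U^T decides whether the smallest singular value flips sign
    corr = S[:, 0] + S[:, 1] + np.sign(det) * S[:, 2]
    ssd = (P * P).sum() + (Qs * Qs).sum(axis=(1, 2)) - 2.0 * corr
    rmsd = np.sqrt(np.clip(ssd, 0.0, None) / P.shape[0])
    # the trace formula cancels catastrophically near zero; recompute tiny
    # entries from explicit rotation residuals
    small = np.nonzero(rmsd < 1e-6)[0]
    for k in small:
        D = np.diag([1.0, 1.0, np.sign(det[k])])
        R = Vt[k].T @ D @ U[k].T
        rmsd[k] = np.sqrt(((Qs[k] @ R - P) ** 2).sum() / P.shape[0])
    return rmsd


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
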