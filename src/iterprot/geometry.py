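"""Backbone geometry: building 3-D fragments from angles and measuring
them back.

Two complementary backbone representations are supported:

* the classic torsion representation — per-residue phi (about N-CA) and
  psi (about CA-C) dihedrals, with the peptide bond held trans
  (omega = 180 deg) and idealized bond lengths/angles; and
* the C-alpha representation — theta_i, the planar angle over CA_{i-1},
  CA_i, CA_{i+1}, and tau_i, the dihedral over CA_{i-1}..CA_{i+2} about
  the CA_i-CA_{i+1} bond, with a fixed CA-CA distance of 3.8 A.

Builders use sequential natural-extension (NeRF) atom placement in a
canonical frame (first atom at the origin, second on +x, third in the xy
plane); all measured quantities are invariant to rigid motion, so the
frame choice is immaterial.  RMSD between point sets is the Kabsch
optimal-superposition RMSD (proper rotations only).
"""

from __future__ import annotations

import numpy as np

#: Idealized backbone covalent geometry (Engh-Huber-style constants).
BOND_N_CA = 1.458   # A
BOND_CA_C = 1.525   # A
BOND_C_N = 1.329    # A
ANGLE_C_N_CA = 121.7   # deg
ANGLE_N_CA_C = 111.2   # deg
ANGLE_CA_C_N = 116.2   # deg

#: Standard virtual CA-CA bond length for the C-alpha representation.
CA_CA_DISTANCE = 3.8  # A

OMEGA_TRANS = 180.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length bond vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float,
               ) -> np.ndarray:
    """NeRF placement: the point D at distance ``bond`` from C, with angle
    B-C-D = ``angle_deg`` and dihedral A-B-C-D = ``torsion_deg``."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.cos(tor) * np.sin(ang),
        np.sin(tor) * np.sin(ang),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Planar angle a-b-c in degrees, in [0, 180]."""
    u = _unit(a - b)
    v = _unit(c - b)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
             ) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]; trans = 180."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValueError("degenerate (collinear) points in dihedral")
    x = n1 @ n2
    y = np.cross(n1, n2) @ _unit(b2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


# ---------------------------------------------------------------------------
# Builders


def build_backbone_from_torsions(phi: np.ndarray, psi: np.ndarray,
                                 omega: float = OMEGA_TRANS) -> np.ndarray:
    """Build N/CA/C coordinates for L residues from phi/psi torsions.

    ``phi[0]`` and ``psi[-1]`` are never used (undefined at the termini;
    NaN is accepted there).  Any other NaN torsion raises.  Returns an
    (L, 3, 3) array indexed [residue, atom(N, CA, C), xyz] in the canonical
    frame.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    L = phi.shape[0]
    if L < 2 or psi.shape[0] != L:
        raise ValueError("need phi and psi arrays of equal length >= 2")
    if np.isnan(phi[1:]).any() or np.isnan(psi[:-1]).any():
        bad = (np.flatnonzero(np.isnan(phi[1:])) + 2).tolist() or \
              (np.flatnonzero(np.isnan(psi[:-1])) + 1).tolist()
        raise ValueError(f"undefined interior torsion at residue {bad[0]}")

    coords = np.zeros((L, 3, 3))
    # canonical first residue: N at origin, CA on +x, C in the xy plane
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [BOND_N_CA, 0.0, 0.0]
    ang = np.radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, L):
        n_prev, ca_prev, c_prev = coords[i - 1]
        coords[i, 0] = place_atom(n_prev, ca_prev, c_prev,
                                  BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        coords[i, 1] = place_atom(ca_prev, c_prev, coords[i, 0],
                                  BOND_N_CA, ANGLE_C_N_CA, omega)
        coords[i, 2] = place_atom(c_prev, coords[i, 0], coords[i, 1],
                                  BOND_CA_C, ANGLE_N_CA_C, phi[i])
    return coords


def compute_phi_psi(backbone: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Measure phi/psi from an (L, 3, 3) N/CA/C backbone.

    Returns arrays of length L with NaN at phi[0] and psi[-1].
    """
    backbone = np.asarray(backbone, dtype=float)
    L = backbone.shape[0]
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    for i in range(L):
        n, ca, c = backbone[i]
        if i > 0:
            phi[i] = dihedral(backbone[i - 1, 2], n, ca, c)
        if i < L - 1:
            psi[i] = dihedral(n, ca, c, backbone[i + 1, 0])
    return phi, psi


def build_ca_trace_from_theta_tau(theta: np.ndarray, tau: np.ndarray,
                                  d: float = CA_CA_DISTANCE) -> np.ndarray:
    """Build an n-point C-alpha trace from n-2 planar angles and n-3
    dihedrals.

    ``theta[k]`` is the angle at point k+1 (over points k, k+1, k+2);
    ``tau[k]`` is the dihedral over points k..k+3.  Consecutive points are
    exactly ``d`` apart.  Collinear angles (0 or 180 deg) raise, since the
    dihedral frame degenerates.
    """
    theta = np.asarray(theta, dtype=float)
    tau = np.asarray(tau, dtype=float)
    n = theta.shape[0] + 2
    if tau.shape[0] != n - 3:
        raise ValueError(
            f"need len(tau) == len(theta) - 1; got {tau.shape[0]} and "
            f"{theta.shape[0]}"
        )
    if np.isnan(theta).any() or np.isnan(tau).any():
        raise ValueError("undefined angle in trace input")
    if ((theta <= 0) | (theta >= 180)).any():
        raise ValueError("theta must lie strictly between 0 and 180 degrees")

    pts = np.zeros((n, 3))
    pts[1] = [d, 0.0, 0.0]
    ang = np.radians(theta[0])
    pts[2] = pts[1] + d * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for k in range(3, n):
        pts[k] = place_atom(pts[k - 3], pts[k - 2], pts[k - 1],
                            d, theta[k - 2], tau[k - 3])
    return pts


def compute_theta_tau(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Measure (theta, tau) from an n-point C-alpha trace.

    Returns compact arrays: n-2 planar angles and n-3 dihedrals, indexed as
    in :func:`build_ca_trace_from_theta_tau`.
    """
    ca = np.asarray(ca, dtype=float)
    n = ca.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for theta")
    theta = np.array([bond_angle(ca[k], ca[k + 1], ca[k + 2])
                      for k in range(n - 2)])
    tau = np.array([dihedral(ca[k], ca[k + 1], ca[k + 2], ca[k + 3])
                    for k in range(n - 3)])
    return theta, tau


# ---------------------------------------------------------------------------
# Fragments and RMSD


def sliding_fragments(protein_length: int, l_frag: int,
                      ) -> list[tuple[int, int]]:
    """All contiguous spans of ``l_frag`` residues at stride 1, as 0-based
    half-open (start, end) pairs: max(0, length - l_frag + 1) of them."""
    if l_frag < 2:
        raise ValueError("fragment length must be >= 2")
    return [(s, s + l_frag)
            for s in range(max(0, protein_length - l_frag + 1))]


def kabsch_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD between two point sets over proper rigid superposition.

    The optimal rotation is the Kabsch solution (SVD with a determinant
    correction so reflections are never used).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"point sets must match and be N x 3, "
                         f"got {A.shape} and {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points")
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(U @ Vt))
    S_corr = S.copy()
    S_corr[-1] *= sign
    # rmsd^2 = (|A|^2 + |B|^2 - 2 * sum corrected singular values) / N
    msd = (np.sum(A0 ** 2) + np.sum(B0 ** 2) - 2.0 * S_corr.sum()) / A.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def superpose(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """B rigidly superposed onto A (proper Kabsch rotation + translation)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    muA = A.mean(axis=0)
    muB = B.mean(axis=0)
    H = (A - muA).T @ (B - muB)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    R = U @ D @ Vt
    return (B - muB) @ R.T + muA


def ca_from_backbone(backbone: np.ndarray) -> np.ndarray:
    """The C-alpha trace of an (L, 3, 3) N/CA/C backbone."""
    return np.asarray(backbone)[:, 1, :]


def fragment_rmsds(native_ca: np.ndarray, phi: np.ndarray, psi: np.ndarray,
                   theta: np.ndarray, tau: np.ndarray,
                   l_frag: int = 15) -> dict[str, np.ndarray]:
    """Sliding-window fragment accuracy for one protein.

    ``phi``/``psi``/``theta``/``tau`` are per-residue arrays (NaN at the
    structurally undefined termini; ``theta[i]``/``tau[i]`` follow the
    residue-centered convention).  For every ``l_frag``-residue span this
    builds the torsion-derived backbone fragment and the CA-angle-derived
    trace and returns three RMSD arrays against the native CA coordinates:
    ``phi_psi``, ``theta_tau`` and their mutual ``consistency``.
    """
    native_ca = np.asarray(native_ca, dtype=float)
    L = native_ca.shape[0]
    spans = sliding_fragments(L, l_frag)
    out = {"phi_psi": [], "theta_tau": [], "consistency": []}
    for s, e in spans:
        bb = build_backbone_from_torsions(phi[s:e], psi[s:e])
        ca_t = ca_from_backbone(bb)
        trace = build_ca_trace_from_theta_tau(theta[s + 1:e - 1],
                                              tau[s + 1:e - 2])
        native = native_ca[s:e]
        out["phi_psi"].append(kabsch_rmsd(native, ca_t))
        out["theta_tau"].append(kabsch_rmsd(native, trace))
        out["consistency"].append(kabsch_rmsd(ca_t, trace))
    return {k: np.array(v) for k, v in out.items()}


def consistency_rmsd(phi_psi_fragment: np.ndarray,
                     theta_tau_fragment: np.ndarray) -> float:
    """Kabsch RMSD between the CA trace of a phi/psi-built fragment and a
    theta/tau-built CA trace over the same span."""
    frag = np.asarray(phi_psi_fragment)
    ca = ca_from_backbone(frag) if frag.ndim == 3 else frag
    return kabsch_rmsd(ca, np.asarray(theta_tau_fragment))
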