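"""Geometry: builders, measurers, fragments, Kabsch RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from iterprot import geometry as geom


def _random_torsions(rng, L):
    phi = rng.uniform(-179, 179, L)
    psi = rng.uniform(-179, 179, L)
    return phi, psi


# ---------------------------------------------------------------------------
# Angle / dihedral measurers


def test_equilateral_triangle_theta_is_60():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    assert geom.bond_angle(pts[0], pts[1], pts[2]) == pytest.approx(60.0)


def test_dihedral_cis_zero_trans_180():
    a, b, c = np.array([0., 1, 0]), np.array([0., 0, 0]), np.array([1., 0, 0])
    d_cis = np.array([1.0, 1.0, 0.0])
    d_trans = np.array([1.0, -1.0, 0.0])
    assert geom.dihedral(a, b, c, d_cis) == pytest.approx(0.0)
    assert geom.dihedral(a, b, c, d_trans) == pytest.approx(180.0)


def test_dihedral_degenerate_raises():
    z = np.zeros(3)
    with pytest.raises(ValueError):
        geom.dihedral(z, z, np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_measurers_invariant_under_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(6, 3)) * 3
    theta, tau = geom.compute_theta_tau(pts)
    R = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
    moved = pts @ R.T + rng.normal(size=3)
    theta2, tau2 = geom.compute_theta_tau(moved)
    np.testing.assert_allclose(theta2, theta, atol=1e-9)
    np.testing.assert_allclose(tau2, tau, atol=1e-9)


# ---------------------------------------------------------------------------
# Torsion backbone builder


def test_phi_psi_round_trip(rng):
    phi, psi = _random_torsions(rng, 12)
    bb = geom.build_backbone_from_torsions(phi, psi)
    phi2, psi2 = geom.compute_phi_psi(bb)
    np.testing.assert_allclose(phi2[1:], phi[1:], atol=0.01)
    np.testing.assert_allclose(psi2[:-1], psi[:-1], atol=0.01)


def test_trans_backbone_has_constant_ca_ca_distance(rng):
    phi, psi = _random_torsions(rng, 10)
    ca = geom.ca_from_backbone(geom.build_backbone_from_torsions(phi, psi))
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    assert np.ptp(d) < 1e-9          # omega=180 forces a single distance
    assert d[0] == pytest.approx(3.8, abs=0.05)


def test_interior_nan_torsion_raises():
    phi = np.array([np.nan, -60.0, np.nan, -60.0])
    psi = np.full(4, -40.0)
    with pytest.raises(ValueError, match="residue 3"):
        geom.build_backbone_from_torsions(phi, psi)


def test_ideal_helix_distance_pattern():
    """An ideal alpha-helix trace shows the canonical contraction
    d(i,i+3) < d(i,i+2) < d(i,i+4); cross-checked against a parametric
    helix (radius 2.3 A, rise 1.5 A, 100 deg/residue)."""
    L = 15
    bb = geom.build_backbone_from_torsions(np.full(L, -57.0),
                                           np.full(L, -47.0))
    ca = geom.ca_from_backbone(bb)

    def sep(pts, k):
        return np.mean(np.linalg.norm(pts[k:] - pts[:-k], axis=1))

    assert sep(ca, 3) < sep(ca, 2) < sep(ca, 4)
    t = np.radians(100.0) * np.arange(L)
    ideal = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 *
                      np.arange(L, dtype=float)], axis=1)
    for k in (2, 3, 4):
        assert sep(ca, k) == pytest.approx(sep(ideal, k), abs=0.5)


# ---------------------------------------------------------------------------
# C-alpha trace builder


def test_theta_tau_round_trip(rng):
    theta = rng.uniform(60, 150, 10)
    tau = rng.uniform(-179, 179, 9)
    trace = geom.build_ca_trace_from_theta_tau(theta, tau)
    theta2, tau2 = geom.compute_theta_tau(trace)
    np.testing.assert_allclose(theta2, theta, atol=0.01)
    np.testing.assert_allclose(tau2, tau, atol=0.01)


def test_trace_distances_exact(rng):
    theta = rng.uniform(60, 150, 20)
    tau = rng.uniform(-179, 179, 19)
    trace = geom.build_ca_trace_from_theta_tau(theta, tau)
    d = np.linalg.norm(np.diff(trace, axis=0), axis=1)
    np.testing.assert_allclose(d, 3.8, rtol=0, atol=1e-12)


def test_collinear_theta_rejected():
    with pytest.raises(ValueError):
        geom.build_ca_trace_from_theta_tau(np.array([180.0, 90.0]),
                                           np.array([10.0]))


def test_planar_zigzag_is_coplanar():
    theta = np.full(8, 90.0)
    tau = np.full(7, 180.0)
    trace = geom.build_ca_trace_from_theta_tau(theta, tau)
    assert np.abs(trace[:, 2]).max() < 1e-9


# ---------------------------------------------------------------------------
# Sliding fragments


@pytest.mark.parametrize("length,lfrag,expected",
                         [(20, 15, 6), (15, 15, 1), (14, 15, 0)])
def test_sliding_fragment_counts(length, lfrag, expected):
    spans = geom.sliding_fragments(length, lfrag)
    assert len(spans) == expected
    assert all(e - s == lfrag for s, e in spans)


# ---------------------------------------------------------------------------
# Kabsch RMSD


def test_rigid_copy_has_zero_rmsd(rng):
    A = rng.normal(size=(8, 3))
    R = Rotation.random(rng=rng).as_matrix()
    B = A @ R.T + np.array([1.0, -2.0, 3.0])
    assert geom.kabsch_rmsd(A, B) < 1e-9


def test_mirror_image_not_superposable(rng):
    A = rng.normal(size=(6, 3))
    B = A * np.array([1.0, 1.0, -1.0])   # improper copy of a chiral set
    assert geom.kabsch_rmsd(A, B) > 0.1


def test_kabsch_matches_scipy(rng):
    A = rng.normal(size=(7, 3))
    B = rng.normal(size=(7, 3))
    _, rssd = Rotation.align_vectors(A - A.mean(0), B - B.mean(0))
    assert geom.kabsch_rmsd(A, B) == pytest.approx(rssd / np.sqrt(7),
                                                   abs=1e-9)


def _grid_rmsd_oracle(A, B, step_deg=10.0):
    """Brute-force minimum RMSD over a dense Euler-angle rotation grid."""
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    grid = np.arange(0.0, 360.0, step_deg)
    half = np.arange(0.0, 180.0, step_deg)
    best = np.inf
    for a in grid:
        for b in half:
            for c in grid:
                R = Rotation.from_euler("zyz", [a, b, c],
                                        degrees=True).as_matrix()
                r = np.sqrt(np.mean(np.sum((B0 @ R.T - A0) ** 2, axis=1)))
                best = min(best, r)
    return best


def test_kabsch_matches_grid_search_oracle(rng):
    for _ in range(3):
        A = rng.normal(size=(5, 3))
        B = rng.normal(size=(5, 3))
        assert geom.kabsch_rmsd(A, B) <= _grid_rmsd_oracle(A, B) + 1e-9
        assert geom.kabsch_rmsd(A, B) == pytest.approx(
            _grid_rmsd_oracle(A, B), abs=0.05)


def test_kabsch_point_count_mismatch():
    with pytest.raises(ValueError):
        geom.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# Cross-representation consistency


def test_native_angles_give_consistent_fragments(tiny_records):
    """Fragments rebuilt from a protein's true torsions and true CA angles
    agree with each other and with the stored trace to < 0.3 A."""
    rec = next(r for r in tiny_records if len(r) >= 20)
    out = geom.fragment_rmsds(rec.ca_coords, rec.phi, rec.psi, rec.theta,
                              rec.tau, l_frag=15)
    assert out["phi_psi"].max() < 0.3
    assert out["theta_tau"].max() < 0.3
    assert out["consistency"].max() < 0.3
    assert (out["consistency"] >= 0).all()


def test_identical_traces_zero_consistency(rng):
    trace = geom.build_ca_trace_from_theta_tau(rng.uniform(60, 150, 8),
                                               rng.uniform(-179, 179, 7))
    assert geom.consistency_rmsd(trace, trace) < 1e-12
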