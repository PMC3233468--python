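"""Geometry kernels: torsions, builder round trips, Kabsch, SASA oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from remdens.geometry import (
    GeometryError,
    InternalCoordinates,
    build_backbone,
    build_backbone_batch,
    compute_phi_psi,
    dihedral_angle,
    golden_spiral_points,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    phi_psi_from_coords,
    rmsd_ca,
    rmsd_to_reference,
    shrake_rupley_sasa,
)
from tests.conftest import make_ic


def brute_force_dihedral(p1, p2, p3, p4):
    """Independent oracle: atan2 of the two plane normals around the axis."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b = p3 - p2
    b /= np.linalg.norm(b)
    n1 = np.cross(p2 - p1, p3 - p2)
    n2 = np.cross(p3 - p2, p4 - p3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b)
    ang = np.degrees(np.arctan2(y, x))
    return ((ang + 180.0) % 360.0) - 180.0


class TestDihedral:
    def test_planar_trans_is_minus_180(self):
        # trans is +-180; the half-open convention reports -180
        assert dihedral_angle((1, 0, 0), (0, 0, 0), (0, 0, 1), (-1, 0, 1)) == -180.0

    def test_planar_cis_is_zero(self):
        assert dihedral_angle((1, 0, 0), (0, 0, 0), (0, 0, 1), (1, 0, 1)) == 0.0

    @pytest.mark.parametrize("p4,expected", [((0, 1, 1), 90.0), ((0, -1, 1), -90.0)])
    def test_quarter_turn_and_mirror(self, p4, expected):
        got = dihedral_angle((1, 0, 0), (0, 0, 0), (0, 0, 1), p4)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(
            brute_force_dihedral((1, 0, 0), (0, 0, 0), (0, 0, 1), p4)
        )

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=12, max_size=12))
    def test_matches_plane_normal_oracle(self, flat):
        pts = np.array(flat).reshape(4, 3)
        b1 = pts[1] - pts[0]
        b2 = pts[2] - pts[1]
        b3 = pts[3] - pts[2]
        if (np.linalg.norm(np.cross(b1, b2)) < 1e-3
                or np.linalg.norm(np.cross(b2, b3)) < 1e-3
                or np.linalg.norm(b2) < 1e-3):
            return  # degenerate draws are rejected, not asserted on
        assert dihedral_angle(*pts) == pytest.approx(brute_force_dihedral(*pts), abs=1e-9)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(GeometryError):
            dihedral_angle((0, 0, 0), (0, 0, 0), (0, 0, 1), (1, 0, 1))
        with pytest.raises(GeometryError):
            dihedral_angle((0, 0, -1), (0, 0, 0), (0, 0, 1), (1, 0, 2))


def independent_nerf(phi, psi, omega=-180.0):
    """Independent natural-extension oracle built on scipy Rotations.

    Places N/CA/C only, using axis-angle rotations instead of the local
    reference-frame construction of the implementation under test.
    """
    from remdens.geometry import (
        ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_N_CA_C,
        BOND_CA_C, BOND_C_N, BOND_N_CA,
    )

    def place(a, b, c, bond, angle, torsion):
        # start from the direction b->c, bend by (180 - angle) about the
        # normal of plane (a, b, c), then twist by torsion about b->c
        bc = (c - b) / np.linalg.norm(c - b)
        n = np.cross(b - a, bc)
        n /= np.linalg.norm(n)
        d0 = bc * bond
        d0 = Rotation.from_rotvec(np.radians(180.0 - angle) * n).apply(d0)
        d0 = Rotation.from_rotvec(np.radians(torsion) * bc).apply(d0)
        return c + d0

    n_res = len(phi)
    N = [np.zeros(3)]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    th = np.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])]
    for i in range(n_res - 1):
        N.append(place(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi[i]))
        CA.append(place(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, omega))
        C.append(place(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi[i + 1]))
    return np.array(N), np.array(CA), np.array(C)


class TestBuilderRoundTrip:
    def test_helix_dihedrals_recovered(self, helix_conf):
        ic = compute_phi_psi(helix_conf)
        assert np.allclose(ic.phi[1:], -63.0, atol=1e-6)
        assert np.allclose(ic.psi[:-1], -43.0, atol=1e-6)

    def test_terminal_angles_undefined(self, helix_conf):
        ic = compute_phi_psi(helix_conf)
        assert np.isnan(ic.phi[0]) and np.isnan(ic.psi[-1])
        assert np.isfinite(ic.phi[1:]).all() and np.isfinite(ic.psi[:-1]).all()

    def test_extended_chain_shape(self, extended_conf):
        assert extended_conf.n_atoms == 85
        ca = extended_conf.ca_coords()
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(steps > 0.3)  # monotonically extending trace

    def test_helix_matches_independent_nerf_oracle(self, helix_conf):
        phi = np.full(17, -63.0)
        psi = np.full(17, -43.0)
        N, CA, C = independent_nerf(phi, psi)
        np.testing.assert_allclose(helix_conf.ca_coords(), CA, atol=1e-9)
        # i -> i+3 CA distance is the alpha-helical pitch scale (~0.5 nm)
        d = np.linalg.norm(CA[3] - CA[0])
        assert 0.45 < d < 0.60

    def test_random_round_trip_below_1e4_deg(self):
        rng = np.random.default_rng(42)
        phi = rng.uniform(-180, 180, (100, 17))
        psi = rng.uniform(-180, 180, (100, 17))
        phi[:, 0] = np.nan
        psi[:, -1] = np.nan
        coords = build_backbone_batch(phi, psi)
        phi2, psi2 = phi_psi_from_coords(coords)
        assert np.nanmax(np.abs(phi2 - phi)) < 1e-4
        assert np.nanmax(np.abs(psi2 - psi)) < 1e-4

    def test_out_of_range_angles_rejected(self):
        ic = make_ic(-63.0, -43.0)
        ic.phi[3] = 250.0
        with pytest.raises((GeometryError, ValueError)):
            build_backbone(ic)


class TestKabsch:
    def test_identity(self, helix_conf):
        ca = helix_conf.ca_coords()
        _, _, rmsd = kabsch_superpose(ca, ca)
        assert rmsd < 1e-12

    def test_rigid_motion_invariance(self, helix_conf):
        rng = np.random.default_rng(0)
        ca = helix_conf.ca_coords()
        R = Rotation.random(random_state=1).as_matrix()
        moved = ca @ R.T + rng.normal(size=3)
        rot, _, rmsd = kabsch_superpose(moved, ca)
        assert rmsd < 1e-10
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_rotation_always_proper(self):
        # a near-planar set invites a reflection without the determinant guard
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        pts[:, 2] *= 1e-4
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rot, _, _ = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_rotation_grid(self):
        """Exhaustive search over rotations confirms the global optimum."""
        base = np.array([[0.0, 0, 0], [0.3, 0, 0], [0, 0.3, 0], [0, 0, 0.3]])
        target = base.copy()
        target[3] += np.array([0.05, -0.02, 0.03])  # displace one atom
        _, _, rmsd = kabsch_superpose(base, target)

        best = np.inf
        grid = np.linspace(-12, 12, 25)  # degrees around the analytic optimum
        bc = base - base.mean(axis=0)
        tc = target - target.mean(axis=0)
        for a in grid:
            for b in grid:
                for c in grid:
                    R = Rotation.from_euler("xyz", [a, b, c], degrees=True).as_matrix()
                    d = bc @ R.T - tc
                    best = min(best, np.sqrt(np.mean(np.sum(d * d, axis=1))))
        assert rmsd <= best + 1e-9
        assert rmsd == pytest.approx(best, abs=1e-4)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsd:
    def test_symmetry(self, helix_conf, extended_conf):
        a = rmsd_ca(helix_conf, extended_conf)
        b = rmsd_ca(extended_conf, helix_conf)
        assert abs(a - b) < 1e-12

    def test_noise_calibration_supports_clustering_cutoff(self, hairpin1_ref):
        """sigma = 0.02 nm Cartesian noise keeps frames within the 0.15 nm cutoff."""
        rng = np.random.default_rng(5)
        ca = hairpin1_ref.ca_coords()
        noisy = ca[None] + rng.normal(0.0, 0.02, size=(1000, *ca.shape))
        r = rmsd_to_reference(noisy, ca)
        assert (r < 0.15).mean() >= 0.99

    def test_pairwise_matrix_consistent_with_direct_calls(self):
        rng = np.random.default_rng(9)
        stack = rng.normal(scale=0.4, size=(25, 17, 3))
        M = pairwise_rmsd_matrix(stack)
        assert np.allclose(M, M.T, atol=1e-12)
        assert np.allclose(np.diag(M), 0.0)
        idx = rng.integers(0, 25, size=(100, 2))
        for i, j in idx:
            assert M[i, j] == pytest.approx(rmsd_ca(stack[i], stack[j]), abs=1e-8)


SPHERE_POINTS = 960


class TestSasa:
    def test_isolated_sphere_analytic(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), radii=[0.17],
                                  probe=0.14, n_points=SPHERE_POINTS)
        assert area[0] == pytest.approx(4 * np.pi * 0.31**2, rel=0.01)

    def test_distant_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        area = shrake_rupley_sasa(coords, radii=[0.17, 0.17], probe=0.14,
                                  n_points=SPHERE_POINTS)
        iso = 4 * np.pi * 0.31**2
        assert np.allclose(area, iso)

    def test_overlapping_spheres_match_spherical_cap_formula(self):
        """Two equal spheres: exposed area = 4 pi R^2 - 2 pi R h per sphere."""
        R = 0.17 + 0.14
        d = 0.4  # < 2R, overlapping
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        area = shrake_rupley_sasa(coords, radii=[0.17, 0.17], probe=0.14,
                                  n_points=SPHERE_POINTS)
        h = R - d / 2.0  # cap height buried on each sphere
        expected = 4 * np.pi * R**2 - 2 * np.pi * R * h
        assert area[0] == pytest.approx(expected, rel=0.01)
        assert area[1] == pytest.approx(expected, rel=0.01)

    def test_monotone_decrease_on_approach(self):
        prev = np.inf
        for d in [1.0, 0.6, 0.5, 0.4, 0.3]:
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            total = shrake_rupley_sasa(coords, radii=[0.17, 0.17], probe=0.14,
                                       n_points=SPHERE_POINTS).sum()
            assert total <= prev + 1e-9
            prev = total

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa(np.zeros((1, 3)), radii=[-0.1])

    def test_mesh_is_unit_sphere(self):
        pts = golden_spiral_points(SPHERE_POINTS)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)


class TestRigidMotionInvariance:
    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_angles_rmsd_sasa_invariant(self, helix_conf, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.normal(size=3)
        moved_coords = helix_conf.coords @ R.T + t
        phi0, psi0 = phi_psi_from_coords(helix_conf.coords)
        phi1, psi1 = phi_psi_from_coords(moved_coords)
        assert np.nanmax(np.abs(phi1 - phi0)) < 1e-9
        assert np.nanmax(np.abs(psi1 - psi0)) < 1e-9
        assert rmsd_ca(moved_coords[helix_conf.atom_names == "CA"],
                       helix_conf.ca_coords()) < 1e-9
        # SASA: exactly invariant under translation; invariant under rotation
        # up to the finite sphere-mesh resolution
        a0 = shrake_rupley_sasa(helix_conf.coords[:10], radii=np.full(10, 0.16),
                                n_points=960)
        a_shift = shrake_rupley_sasa(helix_conf.coords[:10] + t,
                                     radii=np.full(10, 0.16), n_points=960)
        a_rot = shrake_rupley_sasa(helix_conf.coords[:10] @ R.T + t,
                                   radii=np.full(10, 0.16), n_points=960)
        assert np.allclose(a0, a_shift, atol=1e-9)
        # a handful of mesh points (4 pi R^2 / n each) may flip per atom,
        # but the total area is stable
        assert np.allclose(a0, a_rot, atol=0.02)
        assert a_rot.sum() == pytest.approx(a0.sum(), rel=0.01)
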