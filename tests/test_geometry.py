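"""Superposition and inter-conformation measurements."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oligosym.core import select
from oligosym.geometry import (
    GeometryError,
    RigidTransform,
    apply_transform,
    axis_rotation_angle,
    displacement,
    estimate_pore_axis,
    helix_tilt,
    rmsd_matrix,
    superpose,
    thickness_along_axis,
)
from oligosym.synth import SubunitMode, apply_subunit_modes, build_pentamer

from conftest import ideal_helix

RNG = np.random.default_rng(42)


def random_rigid(rng) -> RigidTransform:
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.uniform(-10, 10, 3))


class TestSuperpose:
    def test_identical_sets_identity(self):
        P = RNG.uniform(-5, 5, (10, 3))
        tr, rmsd = superpose(P, P)
        assert rmsd < 1e-10
        np.testing.assert_allclose(tr.rot, np.eye(3), atol=1e-10)

    def test_exact_recovery_of_rotation_translation(self):
        P = RNG.uniform(-5, 5, (12, 3))
        th = np.radians(30)
        R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        Q = P @ R.T + np.array([1.0, 2.0, 3.0])
        tr, rmsd = superpose(P, Q)
        assert rmsd < 1e-6
        np.testing.assert_allclose(tr.apply(P), Q, atol=1e-6)

    def test_rmsd_matches_euler_grid_oracle(self):
        """Brute-force oracle: minimum RMSD over a fine Euler-angle grid."""
        P = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 4]], dtype=float)
        rng = np.random.default_rng(7)
        Q = P + rng.normal(0, 0.3, P.shape)
        _, rmsd = superpose(P, Q)

        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        grid = np.radians(np.arange(-20, 20.001, 2.0))
        best = np.inf
        for a in grid:
            Ra = Rotation.from_euler("z", a).as_matrix()
            for b in grid:
                Rb = Rotation.from_euler("y", b).as_matrix()
                for c in grid:
                    R = Ra @ Rb @ Rotation.from_euler("z", c).as_matrix()
                    d = Pc @ R.T - Qc
                    best = min(best, float(np.sqrt((d**2).sum(1).mean())))
        assert rmsd <= best + 1e-9
        assert abs(rmsd - best) < 1e-2

    def test_invariant_under_common_rigid_motion(self):
        P = RNG.uniform(-5, 5, (15, 3))
        Q = P + RNG.normal(0, 0.5, P.shape)
        _, r0 = superpose(P, Q)
        tr = random_rigid(RNG)
        _, r1 = superpose(tr.apply(P), tr.apply(Q))
        assert abs(r0 - r1) < 1e-9

    def test_too_few_atoms_raises(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_length_mismatch_raises(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestDisplacement:
    def test_zero_for_identical(self, pentamer):
        assert displacement(pentamer, pentamer, ("A", 260, "CA")) == 0.0

    def test_translated_subunit_measured_in_other_subunit_frame(self, pentamer):
        moved, _ = apply_subunit_modes(
            pentamer, {"A": SubunitMode(translation=(3.0, 0.0, 4.0))}
        )
        d = displacement(
            pentamer, moved, ("A", 260, "CA"),
            frame={"chains": ["B", "C", "D", "E"], "atom_names": ["CA"]},
        )
        assert abs(d - 5.0) < 1e-6

    def test_same_subunit_frame_removes_rigid_motion(self, pentamer):
        moved, _ = apply_subunit_modes(pentamer, {"A": SubunitMode(translation=(0, 0, 7.0))})
        d = displacement(
            pentamer, moved, ("A", 260, "CA"),
            frame={"chains": ["A"], "atom_names": ["CA"]},
        )
        assert d < 1e-6


class TestHelixTilt:
    def test_self_is_zero(self):
        h = ideal_helix(20)
        assert helix_tilt(h, h) < 1e-6

    @pytest.mark.parametrize("angle", [9.0, 15.0])
    def test_recovers_construction_angle(self, angle):
        h = ideal_helix(25)
        R = Rotation.from_euler("x", angle, degrees=True).as_matrix()
        assert abs(helix_tilt(h, h @ R.T) - angle) < 0.2

    def test_symmetric_and_rigid_invariant(self):
        h1 = ideal_helix(20)
        h2 = ideal_helix(20) @ Rotation.from_euler("y", 12, degrees=True).as_matrix().T
        t12, t21 = helix_tilt(h1, h2), helix_tilt(h2, h1)
        assert abs(t12 - t21) < 1e-9
        tr = random_rigid(np.random.default_rng(3))
        assert abs(helix_tilt(tr.apply(h1), tr.apply(h2)) - t12) < 1e-6

    def test_degenerate_raises(self):
        line = np.stack([np.zeros(6), np.zeros(6), np.arange(6.0)], axis=1)
        with pytest.raises(GeometryError):
            helix_tilt(line[:2], line[:2])


class TestAxisRotation:
    def test_pure_twist(self):
        R = Rotation.from_euler("z", 2.2, degrees=True).as_matrix()
        t = RigidTransform(R, np.zeros(3))
        assert abs(axis_rotation_angle(t, np.array([0, 0, 1.0])) - 2.2) < 1e-9

    def test_pure_translation_zero(self):
        t = RigidTransform(np.eye(3), np.array([3.0, 1.0, -2.0]))
        assert axis_rotation_angle(t, np.array([0, 0, 1.0])) == 0.0

    def test_sign_follows_right_hand_rule(self):
        R = Rotation.from_euler("z", -5.0, degrees=True).as_matrix()
        assert axis_rotation_angle(RigidTransform(R, np.zeros(3)), np.array([0, 0, 1.0])) < 0

    def test_perpendicular_rotation_matches_ring_average_oracle(self):
        """Oracle: mean angular displacement of ring points about the axis."""
        axis = np.array([0.0, 0.0, 1.0])
        R = Rotation.from_euler("x", 10, degrees=True).as_matrix()
        t = RigidTransform(R, np.zeros(3))
        twist = axis_rotation_angle(t, axis)

        ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ring = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
        moved = t.apply(ring)
        # angular displacement about z of each point's projection
        a0 = np.arctan2(ring[:, 1], ring[:, 0])
        a1 = np.arctan2(moved[:, 1], moved[:, 0])
        d = np.degrees(np.angle(np.exp(1j * (a1 - a0))))
        assert abs(twist - d.mean()) < 0.1

    def test_twist_additivity(self):
        axis = np.array([0, 0, 1.0])
        t1 = RigidTransform(Rotation.from_euler("z", 4.0, degrees=True).as_matrix(), np.zeros(3))
        t2 = RigidTransform(Rotation.from_euler("z", 7.5, degrees=True).as_matrix(), np.zeros(3))
        total = axis_rotation_angle(t1.compose(t2), axis)
        assert abs(total - 11.5) < 1e-6


class TestPoreAxis:
    def test_ideal_pentamer_axis_is_z(self, pentamer):
        point, d = estimate_pore_axis(pentamer)
        assert abs(abs(d[2]) - 1.0) < 1e-3
        assert np.hypot(point[0], point[1]) < 1e-3

    def test_equivariance_under_rotation(self, pentamer):
        tr = random_rigid(np.random.default_rng(11))
        rotated = apply_transform(pentamer, tr)
        _, d = estimate_pore_axis(rotated)
        expected = tr.rot @ np.array([0, 0, 1.0])
        assert min(np.linalg.norm(d - expected), np.linalg.norm(d + expected)) < 1e-3

    def test_perturbed_subunit_matches_line_fit_oracle(self, pentamer):
        moved, _ = apply_subunit_modes(pentamer, {"B": SubunitMode(radial_shift=3.0)})
        point, d = estimate_pore_axis(moved)
        # oracle: direct least-squares line through the per-residue ring centroids
        per_chain = []
        for c in moved.chains:
            per_chain.append({r.seq: r.atoms[0].xyz for r in c.residues})
        shared = sorted(set.intersection(*(set(x) for x in per_chain)))
        cents = np.array([np.mean([x[s] for x in per_chain], axis=0) for s in shared])
        mu = cents.mean(axis=0)
        _, _, Vt = np.linalg.svd(cents - mu)
        d_oracle = Vt[0]
        assert min(np.linalg.norm(d - d_oracle), np.linalg.norm(d + d_oracle)) < 1e-9
        assert np.linalg.norm(point - mu) < 1e-9

    def test_too_few_chains_raises(self, pentamer):
        from oligosym.core import Structure

        partial = Structure("x", chains=pentamer.copy().chains[:3])
        with pytest.raises(GeometryError):
            estimate_pore_axis(partial)


class TestThickness:
    def test_construction_value(self, pentamer):
        # helix spans 39 Å: residues 221..247 at rise 1.5 Å
        t = thickness_along_axis(pentamer, 221, 247)
        assert abs(t - 39.0) < 1e-6

    def test_rigid_invariance_with_axis_reestimated(self, pentamer):
        tr = random_rigid(np.random.default_rng(5))
        t0 = thickness_along_axis(pentamer, 221, 247)
        t1 = thickness_along_axis(apply_transform(pentamer, tr), 221, 247)
        assert abs(t0 - t1) < 1e-6


class TestRmsdMatrix:
    def test_c5_symmetric_pentamer_all_zero(self, pentamer):
        M = rmsd_matrix(pentamer, (251, 277), atom_names=["CA"])
        assert np.abs(M).max() < 1e-6

    def test_two_mode_block_structure(self, pentamer):
        moved, _ = apply_subunit_modes(pentamer)  # A/C vs B/D/E default modes
        M = rmsd_matrix(moved, (221, 337), atom_names=["CA"])
        idx = {c: i for i, c in enumerate("ABCDE")}
        within = [M[idx["A"], idx["C"]], M[idx["B"], idx["D"]],
                  M[idx["B"], idx["E"]], M[idx["D"], idx["E"]]]
        between = [M[idx[a], idx[b]] for a in "AC" for b in "BDE"]
        assert max(within) < min(between)

    def test_superpose_mode_zero_for_rigid_copies(self, pentamer):
        moved, _ = apply_subunit_modes(pentamer)
        M = rmsd_matrix(moved, (251, 277), atom_names=["CA"], align="superpose")
        assert np.abs(M).max() < 1e-6
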