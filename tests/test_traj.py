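"""Trajectory analyses: hydration, permeation, fluctuation, helix shape."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from oligosym.traj import (
    PermeationEvent,
    Trajectory,
    bend_profile,
    count_waters_near,
    detect_permeations,
    read_frames,
    rmsf,
    shape_classify,
    write_frames,
)

from conftest import Z_AXIS, ideal_helix

SLAB = (-18.0, 18.0)


def make_traj(z_paths, waters=None, protein=None, meta=None):
    """Trajectory from per-ion axial paths (dict/array of shape (F,) each)."""
    z = np.asarray(z_paths, dtype=float).T  # (F, Ni)
    F = z.shape[0]
    ions = np.zeros((F, z.shape[1], 3))
    ions[:, :, 2] = z
    prot = protein if protein is not None else np.zeros((F, 1, 3))
    wat = waters if waters is not None else np.zeros((F, 0, 3))
    return Trajectory(prot, ions, wat, 0.2, Z_AXIS, meta)


class TestDetectPermeations:
    def test_single_upward_crossing(self):
        t = make_traj([np.linspace(-30, 30, 100)])
        events = detect_permeations(t, SLAB)
        assert len(events) == 1
        assert events[0].direction == 1
        assert events[0].entry_frame < events[0].exit_frame

    def test_aborted_entry_records_nothing(self):
        z = np.concatenate([np.linspace(-30, 0, 50), np.linspace(0, -30, 50)])
        assert detect_permeations(make_traj([z]), SLAB) == []

    def test_dwell_inside_still_one_event(self):
        z = np.concatenate([np.linspace(-30, 0, 30), np.zeros(40), np.linspace(0, 30, 30)])
        assert len(detect_permeations(make_traj([z]), SLAB)) == 1

    def test_ion_starting_inside_has_no_entry_boundary(self):
        z = np.linspace(0, 30, 50)
        assert detect_permeations(make_traj([z]), SLAB) == []

    def test_jump_straight_across_counts(self):
        z = np.array([-30.0, -25.0, 25.0, 30.0])
        events = detect_permeations(make_traj([z]), SLAB)
        assert len(events) == 1 and events[0].direction == 1

    def test_time_reversal_swaps_directions_preserves_count(self):
        rng = np.random.default_rng(0)
        paths = [np.linspace(-30, 30, 200) + rng.normal(0, 0.5, 200),
                 np.linspace(30, -30, 200) + rng.normal(0, 0.5, 200)]
        t = make_traj(paths)
        fwd = detect_permeations(t, SLAB)
        rev = detect_permeations(t.reversed(), SLAB)
        assert len(fwd) == len(rev)
        assert sorted(e.direction for e in fwd) == sorted(-e.direction for e in rev)

    def test_subsampling_keeps_count(self):
        z = np.linspace(-30, 30, 400)
        t_full = make_traj([z])
        t_sub = make_traj([z[::5]])
        assert len(detect_permeations(t_full, SLAB)) == len(detect_permeations(t_sub, SLAB)) == 1

    def test_invalid_slab(self):
        with pytest.raises(ValueError):
            detect_permeations(make_traj([np.zeros(5)]), (5.0, -5.0))

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            PermeationEvent(0, 5, 5, 1)
        with pytest.raises(ValueError):
            PermeationEvent(0, 1, 2, 0)


class TestCountWaters:
    def _meta(self):
        return pd.DataFrame(
            {"chain": ["A"], "res_seq": [260], "res_name": ["LEU"], "name": ["CA"]}
        )

    def test_constructed_counts(self):
        F = 3
        prot = np.zeros((F, 1, 3))
        wat = np.zeros((F, 12, 3))
        wat[:, :7, 0] = 2.0  # 7 oxygens inside 4 Å
        wat[:, 7:, 0] = 50.0  # 5 far outside
        t = Trajectory(prot, np.zeros((F, 0, 3)), wat, 0.2, Z_AXIS, self._meta())
        out = count_waters_near(t, [260], cutoff=4.0)
        assert list(out["counts"]) == [7, 7, 7]

    def test_empty_water_group_counts_zero(self):
        t = Trajectory(np.zeros((4, 1, 3)), np.zeros((4, 0, 3)), np.zeros((4, 0, 3)),
                       0.2, Z_AXIS, self._meta())
        out = count_waters_near(t, [260])
        assert out["mean"] == 0.0 and not out["counts"].any()

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        wat = rng.uniform(-8, 8, size=(5, 30, 3))
        t = Trajectory(np.zeros((5, 1, 3)), np.zeros((5, 0, 3)), wat, 0.2, Z_AXIS, self._meta())
        c_small = count_waters_near(t, [260], cutoff=3.0)["counts"]
        c_big = count_waters_near(t, [260], cutoff=6.0)["counts"]
        assert np.all(c_big >= c_small)

    def test_missing_target_raises(self):
        t = Trajectory(np.zeros((2, 1, 3)), np.zeros((2, 0, 3)), np.zeros((2, 0, 3)),
                       0.2, Z_AXIS, self._meta())
        with pytest.raises(ValueError):
            count_waters_near(t, [999])


class TestRmsf:
    def test_static_trajectory_zero(self):
        prot = np.broadcast_to(np.arange(30.0).reshape(10, 3), (6, 10, 3)).copy()
        t = Trajectory(prot, np.zeros((6, 0, 3)), np.zeros((6, 0, 3)), 0.2, Z_AXIS)
        assert np.allclose(rmsf(t), 0.0)

    def test_gaussian_jitter_closed_form(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(-20, 20, (150, 3))
        frames = ref[None] + rng.normal(0, 1.0, (5000, 150, 3))
        t = Trajectory(frames, np.zeros((5000, 0, 3)), np.zeros((5000, 0, 3)), 0.2, Z_AXIS)
        r = rmsf(t)
        assert abs(r.mean() - np.sqrt(3.0)) < 0.05

    def test_jittered_half_exceeds_static_half(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(-20, 20, (40, 3))
        frames = np.broadcast_to(ref, (500, 40, 3)).copy()
        frames[:, 20:, :] += rng.normal(0, 1.0, (500, 20, 3))
        t = Trajectory(frames, np.zeros((500, 0, 3)), np.zeros((500, 0, 3)), 0.2, Z_AXIS)
        r = rmsf(t, fit_selection=np.arange(20))
        assert r[20:].min() > r[:20].max()

    def test_rigid_motion_removed_by_fitting(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(-10, 10, (25, 3))
        frames = np.empty((50, 25, 3))
        for f in range(50):
            R = Rotation.from_euler("z", 3.0 * f, degrees=True).as_matrix()
            frames[f] = ref @ R.T + np.array([0.1 * f, 0, 0])
        t = Trajectory(frames, np.zeros((50, 0, 3)), np.zeros((50, 0, 3)), 0.2, Z_AXIS)
        assert rmsf(t).max() < 1e-6

    def test_single_frame_rejected(self):
        t = Trajectory(np.zeros((1, 5, 3)), np.zeros((1, 0, 3)), np.zeros((1, 0, 3)),
                       0.2, Z_AXIS)
        with pytest.raises(ValueError):
            rmsf(t)


class TestBendProfile:
    def test_straight_helix_bends_below_two_degrees(self):
        b = bend_profile(ideal_helix(50))
        assert b["bend_deg"].max() < 2.0

    def test_hinge_recovered(self):
        h = ideal_helix(50)
        pivot = h[25]
        R = Rotation.from_euler("x", 25, degrees=True).as_matrix()
        h[25:] = (h[25:] - pivot) @ R.T + pivot
        b = bend_profile(h)
        assert abs(b["kink_position"] - 25) <= 1
        assert abs(b["kink_angle"] - 25.0) <= 3.0

    @pytest.mark.parametrize("hinge", [12, 38])
    def test_hinge_position_discriminates_ends(self, hinge):
        h = ideal_helix(50)
        pivot = h[hinge]
        R = Rotation.from_euler("x", 20, degrees=True).as_matrix()
        h[hinge:] = (h[hinge:] - pivot) @ R.T + pivot
        b = bend_profile(h)
        mid = 25
        assert (b["kink_position"] < mid) == (hinge < mid)

    def test_too_short_raises(self):
        from oligosym.geometry import GeometryError

        with pytest.raises(GeometryError):
            bend_profile(ideal_helix(10))


class TestShapeClassify:
    def _m2(self, tilt_top=0.0, tilt_bot=0.0):
        out = []
        for k in range(5):
            phi = np.radians(72 * k)
            base = ideal_helix(27) + np.array([8 * np.cos(phi), 8 * np.sin(phi), -19.5])
            z = base[:, 2]
            w = (z - z.min()) / (z.max() - z.min())
            radial = np.array([np.cos(phi), np.sin(phi), 0.0])
            out.append(base - np.outer(w, tilt_top * radial) - np.outer(1 - w, tilt_bot * radial))
        return out

    def test_parallel_is_h(self):
        assert shape_classify(self._m2(), Z_AXIS) == "H"

    def test_top_tips_inward_is_a(self):
        assert shape_classify(self._m2(tilt_top=3.0), Z_AXIS) == "A"

    def test_bottom_tips_inward_is_v(self):
        assert shape_classify(self._m2(tilt_bot=3.0), Z_AXIS) == "V"


class TestFramesIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        meta = pd.DataFrame({"chain": ["A", "A"], "res_seq": [1, 2],
                             "res_name": ["ALA", "ALA"], "name": ["CA", "CA"]})
        t = Trajectory(rng.normal(size=(4, 2, 3)), rng.normal(size=(4, 3, 3)),
                       rng.normal(size=(4, 5, 3)), 0.5, Z_AXIS, meta)
        write_frames(t, tmp_path / "r.frames", tmp_path / "r.meta.tsv")
        t2 = read_frames(tmp_path / "r.frames", tmp_path / "r.meta.tsv")
        assert t2.n_frames == 4 and t2.dt_ns == 0.5
        np.testing.assert_allclose(t.ions, t2.ions, atol=5e-4)
        np.testing.assert_allclose(t.waters, t2.waters, atol=5e-4)
        assert list(t2.protein_meta.columns) == list(meta.columns)

    def test_tail_window(self):
        t = Trajectory(np.zeros((100, 1, 3)), np.zeros((100, 0, 3)), np.zeros((100, 0, 3)),
                       0.2, Z_AXIS)
        assert t.tail(0.25).n_frames == 25
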