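"""Trajectory geometry: leaflets, thickness, tilt, RMSD, interface depth."""

import numpy as np
import pytest

from membranegp.mdgeom import (
    BilayerFrame,
    BilayerTrajectory,
    DepthSeries,
    assign_leaflets,
    convergence_time,
    depth_series,
    heavy_atom_rmsd,
    interface_distance,
    membrane_thickness,
    tilt_angle,
    window_average,
)
from membranegp.synth import TrajectorySpec, make_trajectory


def _frame(p_z, dye_coords, dye_names=("N2", "N3", "C23"), time=0.0):
    """Small hand-built frame: P atoms on a grid at given z, plus a dye."""
    n_p = len(p_z)
    p_xy = np.column_stack([np.arange(n_p, dtype=float), np.zeros(n_p)])
    coords = np.vstack([np.column_stack([p_xy, p_z]), np.asarray(dye_coords, float)])
    names = tuple(["P"] * n_p + list(dye_names))
    dye_idx = np.arange(n_p, n_p + len(dye_coords))
    return BilayerFrame(
        time=time,
        coordinates=coords,
        atom_names=names,
        p_atom_indices=np.arange(n_p),
        dye_atom_indices=dye_idx,
        dye_heavy_indices=dye_idx,
    )


ROD = [[0.0, 0.0, 15.0], [0.0, 0.0, 14.0], [0.0, 0.0, 10.0]]
PLANES = [20.0, 20.0, 20.0, -20.0, -20.0, -20.0]


class TestLeaflets:
    def test_clean_split(self):
        top, bottom = assign_leaflets(_frame(PLANES, ROD))
        assert top.size == 3 and bottom.size == 3

    def test_jittered_split_matches_generation(self):
        spec = TrajectorySpec(thickness=40.0, p_jitter_sd=2.0, duration=1.0, seed=8)
        traj, _ = make_trajectory(spec)
        n = spec.n_lipids_per_leaflet
        top, bottom = assign_leaflets(traj.frame(0))
        np.testing.assert_array_equal(np.sort(top), np.arange(n))
        np.testing.assert_array_equal(np.sort(bottom), np.arange(n, 2 * n))

    def test_median_atom_goes_to_bottom(self):
        z = [10.0, 10.0, 0.0, -10.0, -10.0]
        top, bottom = assign_leaflets(_frame(z, ROD))
        assert 2 in bottom and 2 not in top

    def test_flat_system_rejected(self):
        with pytest.raises(ValueError, match="no bilayer"):
            assign_leaflets(_frame([5.0, 5.0, 5.0, 5.0], ROD))


class TestThickness:
    def test_planes_at_pm20(self):
        assert membrane_thickness(_frame(PLANES, ROD)) == pytest.approx(40.0)

    def test_matches_brute_force_on_jittered_planes(self, rng):
        z_top = 19.0 + rng.normal(0, 2, 10)
        z_bot = -19.5 + rng.normal(0, 2, 10)
        frame = _frame(np.concatenate([z_top, z_bot]), ROD)
        assert membrane_thickness(frame) == pytest.approx(
            z_top.mean() - z_bot.mean(), abs=1e-12)

    def test_translation_invariance(self):
        frame = _frame(PLANES, ROD)
        shifted = _frame([z + 7.0 for z in PLANES],
                         [[x, y, z + 7.0] for x, y, z in ROD])
        assert membrane_thickness(shifted) == pytest.approx(
            membrane_thickness(frame), abs=1e-12)


class TestTilt:
    def test_rod_along_z_is_zero(self):
        frame = _frame(PLANES, [[0, 0, 10], [0, 0, 12], [0, 0, 14]])
        assert tilt_angle(frame) == pytest.approx(0.0, abs=1e-12)

    def test_rod_in_plane_is_ninety(self):
        frame = _frame(PLANES, [[0, 0, 10], [3, 0, 10], [6, 0, 10]])
        assert tilt_angle(frame) == pytest.approx(90.0, abs=1e-12)

    def test_generated_thirty_degree_rod_round_trip(self):
        spec = TrajectorySpec(tilt_mean=30.0, tilt_sd=0.0, depth_sd=0.0,
                              p_jitter_sd=0.0, duration=1.0, seed=0)
        traj, _ = make_trajectory(spec)
        assert tilt_angle(traj.frame(0)) == pytest.approx(30.0, abs=1e-9)

    def test_folding_option(self):
        frame = _frame(PLANES, [[0, 0, 14], [0, 0, 12], [0, 0, 10]])  # N2->N3 down
        assert tilt_angle(frame) == pytest.approx(180.0)
        assert tilt_angle(frame, fold=True) == pytest.approx(0.0)

    def test_coincident_atoms_rejected(self):
        frame = _frame(PLANES, [[0, 0, 10], [0, 0, 10], [0, 0, 14]])
        with pytest.raises(ValueError, match="coincide"):
            tilt_angle(frame)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _quaternion_rmsd(p, q):
    """Independent superposition oracle (Horn's quaternion method)."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e = float((p**2).sum() + (q**2).sum() - 2.0 * lam)
    return np.sqrt(max(e, 0.0) / p.shape[0])


class TestRMSD:
    def test_frame_vs_itself_zero(self):
        frame = _frame(PLANES, ROD)
        assert heavy_atom_rmsd(frame, frame) == 0.0

    def test_rigid_motion_removed(self, rng):
        frame = _frame(PLANES, ROD)
        rot = _random_rotation(rng)
        moved_dye = (np.asarray(ROD) @ rot.T) + np.array([3.0, -2.0, 5.0])
        moved = _frame(PLANES, moved_dye)
        assert heavy_atom_rmsd(moved, frame) == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        base = rng.normal(size=(7, 3)) * 3.0
        pert = base + rng.normal(0, 0.4, size=(7, 3))
        frame_a = _frame(PLANES, base, dye_names=tuple(f"C{i}" for i in range(7)))
        frame_b = _frame(PLANES, pert, dye_names=tuple(f"C{i}" for i in range(7)))
        assert heavy_atom_rmsd(frame_b, frame_a) == pytest.approx(
            _quaternion_rmsd(pert, base), abs=1e-9)

    def test_too_few_heavy_atoms_rejected(self):
        frame = _frame(PLANES, [[0, 0, 10], [0, 0, 14]], dye_names=("N2", "C23"))
        with pytest.raises(ValueError, match="3 heavy"):
            heavy_atom_rmsd(frame, frame)


class TestInterfaceDistance:
    def test_atom_below_plane(self):
        # proximal (top) plane mean z = 19, atom N2 at z = 15 -> +4 toward center
        frame = _frame([19.0, 19.0, 19.0, -19.0, -19.0, -19.0], ROD)
        assert interface_distance(frame, "N2") == pytest.approx(4.0)

    def test_atom_on_plane_zero(self):
        frame = _frame(PLANES, [[0, 0, 20.0], [0, 0, 14.0], [0, 0, 10.0]])
        assert interface_distance(frame, "N2") == pytest.approx(0.0)

    def test_bottom_leaflet_sign_points_inward(self):
        # dye near the bottom plane: positive distance = above the plane
        frame = _frame(PLANES, [[0, 0, -15.0], [0, 0, -14.0], [0, 0, -10.0]])
        assert interface_distance(frame, "N2") == pytest.approx(5.0)


class TestSeriesAndWindows:
    def test_constant_trajectory_constant_series(self):
        spec = TrajectorySpec(depth_sd=0.0, tilt_sd=0.0, p_jitter_sd=0.0,
                              duration=2.0, seed=0)
        traj, _ = make_trajectory(spec)
        series = depth_series(traj)
        assert series.time.size == traj.n_frames
        for arr in (series.thickness, series.tilt, series.dist_edge1,
                    series.dist_edge2, series.rmsd):
            assert np.ptp(arr) == pytest.approx(0.0, abs=1e-9)

    def test_series_equals_per_frame_loop(self, short_trajectory):
        """Composition oracle: the series equals single-frame ops in a loop."""
        _, traj, _ = short_trajectory
        series = depth_series(traj)
        ref = traj.frame(0)
        for i in (0, 7, traj.n_frames - 1):
            frame = traj.frame(i)
            assert series.thickness[i] == membrane_thickness(frame)
            assert series.tilt[i] == tilt_angle(frame)
            assert series.rmsd[i] == heavy_atom_rmsd(frame, ref)
            assert series.dist_edge1[i] == interface_distance(
                frame, "N2", proximal_top=True)
            assert series.dist_edge2[i] == interface_distance(
                frame, "C23", proximal_top=True)

    def test_window_average_boundary_inclusive(self):
        t = np.arange(0.0, 300.5, 1.0)
        const = np.ones_like(t)
        series = DepthSeries(time=t, thickness=const, tilt=const, rmsd=const,
                             dist_edge1=4.0 * const, dist_edge2=2.0 * const)
        summary = window_average(series, window_ns=100.0)
        assert summary.window[0] == pytest.approx(200.0)  # t >= 200 used
        assert summary.n_frames == 101
        assert summary.mean_midpoint == pytest.approx(3.0)
        assert summary.mean_dist_edge1 == pytest.approx(4.0)

    def test_window_longer_than_span_rejected(self):
        t = np.arange(0.0, 10.5, 1.0)
        c = np.ones_like(t)
        series = DepthSeries(time=t, thickness=c, tilt=c, rmsd=c,
                             dist_edge1=c, dist_edge2=c)
        with pytest.raises(ValueError, match="window"):
            window_average(series, window_ns=50.0)


def _series_from_midpoint(t, mid):
    z = np.zeros_like(t)
    return DepthSeries(time=t, thickness=z, tilt=z, rmsd=z,
                       dist_edge1=mid, dist_edge2=mid)


class TestConvergence:
    def test_identical_series_converge_at_zero(self):
        t = np.arange(0.0, 50.5, 0.5)
        a = _series_from_midpoint(t, np.full_like(t, 4.0))
        assert convergence_time(a, a, tolerance=0.5, hold=10.0) == 0.0

    def test_step_series_converge_at_step(self):
        t = np.arange(0.0, 100.5, 0.5)
        a = _series_from_midpoint(t, np.full_like(t, 4.0))
        b_mid = np.where(t < 40.0, 9.0, 4.0)
        b = _series_from_midpoint(t, b_mid)
        assert convergence_time(a, b, tolerance=1.0, hold=20.0) == pytest.approx(40.0)

    def test_never_converging_returns_none(self):
        t = np.arange(0.0, 50.5, 0.5)
        a = _series_from_midpoint(t, np.full_like(t, 4.0))
        b = _series_from_midpoint(t, np.full_like(t, 9.0))
        assert convergence_time(a, b, tolerance=1.0, hold=10.0) is None

    def test_two_start_pair_converges_reproducibly(self):
        """Generator scenario: a 5 A-offset start relaxes onto the reference
        trajectory at a finite, seed-reproducible time."""
        a, _ = make_trajectory(TrajectorySpec(
            duration=150.0, depth_relaxation_time=20.0, seed=300))
        b, _ = make_trajectory(TrajectorySpec(
            duration=150.0, depth_relaxation_time=20.0,
            initial_depth_offset=5.0, seed=301))
        sa, sb = depth_series(a), depth_series(b)
        t1 = convergence_time(sa, sb, tolerance=2.5, hold=20.0, smooth_ns=80.0)
        t2 = convergence_time(sa, sb, tolerance=2.5, hold=20.0, smooth_ns=80.0)
        assert t1 is not None and t1 == t2


def test_rigid_translation_leaves_geometry_unchanged(short_trajectory):
    _, traj, _ = short_trajectory
    shifted = BilayerTrajectory(
        times=traj.times,
        coordinates=traj.coordinates + np.array([5.0, -3.0, 12.0]),
        atom_names=traj.atom_names,
        p_atom_indices=traj.p_atom_indices,
        dye_atom_indices=traj.dye_atom_indices,
        dye_heavy_indices=traj.dye_heavy_indices,
    )
    a = depth_series(traj)
    b = depth_series(shifted)
    np.testing.assert_allclose(a.thickness, b.thickness, atol=1e-9)
    np.testing.assert_allclose(a.tilt, b.tilt, atol=1e-9)
    np.testing.assert_allclose(a.dist_edge1, b.dist_edge1, atol=1e-9)
    np.testing.assert_allclose(a.rmsd, b.rmsd, atol=1e-9)


def test_window_mean_recovers_ou_depth(short_trajectory):
    """OU stationary-mean oracle at trajectory level."""
    spec, traj, truth = short_trajectory
    series = depth_series(traj)
    summary = window_average(series, window_ns=15.0)
    se = spec.depth_sd * np.sqrt(2 * spec.depth_relaxation_time / 15.0)
    assert abs(summary.mean_midpoint - spec.dye_depth) < 3 * se + 1.0
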