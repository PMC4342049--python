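import numpy as np
import pytest
from hypothesis import given, strategies as st

from dbsmotor.io_schedule import TrajectoryRecording
from dbsmotor.motor_processes import (
    InsufficientDataError,
    activity_decomposition,
    classify_angle,
    classify_window_dimension,
    dimension_processes,
    extract_processes,
    forward_fraction,
    forward_mean,
    reconstruct_positions,
    rl_difference,
    velocity_speed_angle,
)


def brute_force_hull_area(points):
    """Gift-wrapping hull + shoelace area; independent of scipy."""
    pts = [tuple(p) for p in np.asarray(points, dtype=float)]
    uniq = sorted(set(pts))
    if len(uniq) < 3:
        return 0.0
    start = uniq[0]
    hull = [start]
    current = start
    prev_dir = None
    while True:
        candidate = None
        for q in uniq:
            if q == current:
                continue
            if candidate is None:
                candidate = q
                continue
            cross = (candidate[0] - current[0]) * (q[1] - current[1]) - (
                candidate[1] - current[1]
            ) * (q[0] - current[0])
            if cross < 0 or (
                cross == 0
                and (q[0] - current[0]) ** 2 + (q[1] - current[1]) ** 2
                > (candidate[0] - current[0]) ** 2 + (candidate[1] - current[1]) ** 2
            ):
                candidate = q
        hull.append(candidate)
        current = candidate
        if candidate == start:
            break
        if len(hull) > len(uniq) + 1:
            raise RuntimeError("gift wrapping failed to close")
    area = 0.0
    for (x0, y0), (x1, y1) in zip(hull[:-1], hull[1:]):
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


def recording(x, y):
    return TrajectoryRecording(np.asarray(x, float), np.asarray(y, float))


class TestVelocitySpeedAngle:
    def test_single_step(self):
        ps = velocity_speed_angle(recording([0, 3], [0, 4]))
        assert ps.m[0] == pytest.approx(5.0)
        assert ps.theta[0] == pytest.approx(np.arctan2(4, 3))

    def test_constant_position_rest(self):
        ps = velocity_speed_angle(recording(np.ones(10), np.ones(10)))
        assert (ps.m == 0).all()
        assert np.isnan(ps.theta).all()
        assert (ps.is_p == 0).all() and (ps.is_np == 0).all()

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            velocity_speed_angle(recording([1.0], [1.0]))

    def test_angle_range_half_open(self):
        # a straight leftward move maps to -pi (pi identified with -pi)
        ps = velocity_speed_angle(recording([1, 0], [0, 0]))
        assert ps.theta[0] == pytest.approx(-np.pi)


class TestReconstruction:
    def test_zero_speed_constant_path(self):
        path = reconstruct_positions(np.zeros(5), np.full(5, np.nan), (2.0, 3.0))
        assert (path == [2.0, 3.0]).all()

    def test_single_step_east(self):
        path = reconstruct_positions([5.0], [0.0])
        np.testing.assert_allclose(path[-1], [5.0, 0.0])

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="undefined angle"):
            reconstruct_positions([1.0], [np.nan])

    def test_random_path_roundtrip(self, rng):
        x = np.cumsum(rng.normal(size=1000))
        y = np.cumsum(rng.normal(size=1000))
        # inject rest seconds
        x[200:230] = x[199]
        y[200:230] = y[199]
        rec = recording(x, y)
        ps = velocity_speed_angle(rec)
        path = reconstruct_positions(ps.m, ps.theta, (x[0], y[0]))
        assert np.abs(path[:, 0] - x).max() < 1e-9
        assert np.abs(path[:, 1] - y).max() < 1e-9


class TestAngleClass:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 1), (-np.pi / 2, 1), (np.pi / 2, 1), (-np.pi, 1), (np.pi, 1),
         (np.pi / 4, 0), (1.0, 0), (-2.0, 0)],
    )
    def test_multiples_of_half_pi(self, theta, expected):
        assert classify_angle(theta) == expected

    def test_tolerance(self):
        assert classify_angle(1e-12) == 1
        assert classify_angle(1e-6, tol=1e-9) == 0
        assert classify_angle(1e-6, tol=1e-3) == 1


class TestWindowDimension:
    def test_all_points_coincide(self):
        pts = np.tile([2.0, 3.0], (30, 1))
        assert classify_window_dimension(pts) == (0, 0.0, 0.0)

    def test_collinear_on_axis(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6)])
        k, d1, d2 = classify_window_dimension(pts)
        assert (k, d2) == (1, 0.0)
        assert d1 == pytest.approx(5.0)

    def test_unit_square_hull(self):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        pts = np.tile(corners, (8, 1))[:30]
        k, d1, d2 = classify_window_dimension(pts)
        assert k == 2 and d1 == 0.0
        assert d2 == pytest.approx(1.0)

    def test_window_too_small(self):
        with pytest.raises(InsufficientDataError):
            classify_window_dimension(np.array([[0.0, 0.0]]))

    def test_hull_area_matches_brute_force(self, rng):
        for _ in range(60):
            pts = rng.uniform(0, 30, size=(30, 2))
            k, _, d2 = classify_window_dimension(pts)
            assert k == 2
            assert abs(d2 - brute_force_hull_area(pts)) < 1e-9

    def test_oblique_line_length_matches_pairwise_oracle(self, rng):
        for _ in range(30):
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            offs = rng.uniform(-5, 5, 30)
            pts = np.array([3.0, 4.0]) + offs[:, None] * direction
            k, d1, _ = classify_window_dimension(pts)
            assert k == 1
            longest = max(
                np.hypot(*(p - q)) for p in pts for q in pts
            )
            assert abs(d1 - longest) < 1e-9


class TestDimensionProcesses:
    def test_pure_wall_run_is_one_dimensional(self):
        x = np.concatenate([np.zeros(10), np.cumsum(np.ones(40)), np.full(20, 40.0)])
        rec = recording(x, np.full(x.size, 5.0))
        ps = dimension_processes(rec, w=10)
        defined = ps.id_ >= 0
        assert set(np.unique(ps.id_[defined])) <= {0, 1}
        assert np.nansum(ps.m2d) == 0.0

    def test_speed_splits_by_dimension(self, small_effect_processes):
        ps = small_effect_processes
        sel = (ps.id_ == 1) | (ps.id_ == 2)
        np.testing.assert_allclose(
            ps.m[sel], ps.m1d[sel] + ps.m2d[sel], rtol=0, atol=1e-12
        )
        # exclusivity: D1 only when 1-D, D2 only when 2-D
        assert np.nansum(np.abs(ps.d1[ps.id_ != 1][ps.id_[ps.id_ != 1] >= 0])) == 0
        assert np.nansum(np.abs(ps.d2[ps.id_ != 2][ps.id_[ps.id_ != 2] >= 0])) == 0

    def test_fast_paths_agree_with_reference_classifier(self, small_effect_sim):
        rec = small_effect_sim.recording
        sub = TrajectoryRecording(rec.x[:4000], rec.y[:4000])
        ps = dimension_processes(sub, w=30)
        pts = sub.positions()
        for i in range(0, 4000 - 30, 7):
            k, d1, d2 = classify_window_dimension(pts[i : i + 30])
            assert ps.id_[i] == k
            assert ps.d1[i] == pytest.approx(d1, abs=1e-9)
            assert ps.d2[i] == pytest.approx(d2, abs=1e-9)

    def test_interior_loop_is_two_dimensional(self):
        t = np.linspace(0, 4 * np.pi, 80)
        rec = recording(10 + 3 * np.cos(t), 10 + 3 * np.sin(t))
        ps = dimension_processes(rec, w=20)
        assert (ps.id_[ps.id_ >= 0] == 2).all()
        assert np.nanmin(ps.d2[ps.id_ == 2]) > 0

    def test_quarter_turn_rotation_covariance(self, small_effect_sim):
        rec = small_effect_sim.recording
        n = 6000
        cx = cy = 18.0  # rotate about a fixed point; cage asymmetry is irrelevant
        x, y = rec.x[:n], rec.y[:n]
        rx = cx - (y - cy)
        ry = cy + (x - cx)
        ps = extract_processes(TrajectoryRecording(x, y))
        pr = extract_processes(TrajectoryRecording(rx, ry))
        np.testing.assert_allclose(pr.m, ps.m, atol=1e-9)
        np.testing.assert_array_equal(pr.id_, ps.id_)
        np.testing.assert_allclose(pr.d1, ps.d1, atol=1e-7)
        np.testing.assert_allclose(pr.d2, ps.d2, atol=1e-7)
        np.testing.assert_array_equal(pr.is_p, ps.is_p)


class TestWindowStatistics:
    def test_forward_mean_constant(self):
        out = forward_mean(np.full(50, 3.3), 10)
        np.testing.assert_allclose(out[:41], 3.3)
        assert np.isnan(out[41:]).all()

    def test_forward_fraction_half_ones(self):
        num = np.tile([1.0, 0.0], 50)
        den = np.ones(100)
        out = forward_fraction(num, den, 10)
        np.testing.assert_allclose(out[:91], 0.5)

    def test_forward_mean_matches_direct_sum(self, rng):
        x = rng.normal(size=3000)
        out = forward_mean(x, 60)
        for i in [0, 17, 1500, 2940]:
            assert abs(out[i] - x[i : i + 60].sum() / 60) < 1e-12

    def test_circular_forward_mean_wraps(self, rng):
        x = rng.normal(size=200)
        out = forward_mean(x, 50, circular=True)
        wrapped = np.concatenate([x, x])
        for i in [0, 120, 180, 199]:
            assert abs(out[i] - wrapped[i : i + 50].mean()) < 1e-12

    def test_rl_difference_constant_zero(self):
        out = rl_difference(np.full(100, 7.0), 10)
        np.testing.assert_allclose(out[10:91], 0.0, atol=1e-13)

    def test_rl_difference_detects_step(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        out = rl_difference(x, 10)
        assert out[50] == pytest.approx(1.0)

    def test_rl_difference_matches_two_window_oracle(self, rng):
        x = rng.normal(size=1000)
        out = rl_difference(x, 25)
        for i in [25, 300, 975]:
            expect = x[i : i + 25].mean() - x[i - 25 : i].mean()
            assert abs(out[i] - expect) < 1e-12

    @given(st.integers(0, 2**31 - 1))
    def test_activity_decomposition_additive(self, seed):
        r = np.random.default_rng(seed)
        n = 700
        m1d = np.abs(r.normal(size=n)) * r.integers(0, 2, n)
        m2d = np.abs(r.normal(size=n)) * (m1d == 0)
        abar, a2, a1 = activity_decomposition(m1d, m2d, 60)
        ok = np.isfinite(abar)
        assert np.abs(abar[ok] - (a1[ok] + a2[ok])).max() < 1e-12

    def test_all_one_dimensional_path(self):
        m1d = np.abs(np.sin(np.arange(300.0)))
        abar, a2, a1 = activity_decomposition(m1d, np.zeros(300), 30)
        ok = np.isfinite(abar)
        np.testing.assert_allclose(abar[ok], a1[ok])
        assert np.nansum(a2) == 0
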