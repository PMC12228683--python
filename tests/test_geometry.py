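"""B-tubule registration, curvature radii, circle fits and the two-circle
ring measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tubulekit import (
    ArcSpec,
    TubuleTrace,
    compare_curvature_groups,
    curvature_result,
    fit_circle,
    local_radii,
    make_annulus_slice,
    make_arc,
    mean_radius,
    measure_ring_radius,
    overlay_traces,
    register_trace,
    two_circle_radius,
)


def rigid(points, angle_deg, shift):
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return points @ R.T + np.asarray(shift)


class TestRegistration:
    def canonical(self):
        pts = make_arc(ArcSpec(radius_true=13.5, arc_span=90, n_points=8)).points
        return TubuleTrace(points=pts, O=np.array([-13.5, 0.0]), X=np.array([0.0, 0.0]))

    def test_canonical_trace_gets_identity(self):
        tr = self.canonical()
        al = register_trace(tr)
        np.testing.assert_allclose(al.points, tr.points, atol=1e-9)
        assert abs(al.angle % (2 * np.pi)) < 1e-9
        np.testing.assert_allclose(al.shift, 0.0, atol=1e-9)

    def test_posed_trace_recovers_canonical(self):
        tr = self.canonical()
        posed = TubuleTrace(points=rigid(tr.points, 90, (5, -7)),
                            O=rigid(tr.O, 90, (5, -7)), X=rigid(tr.X, 90, (5, -7)))
        al = register_trace(posed)
        np.testing.assert_allclose(al.points, tr.points, atol=1e-9)

    def test_contract_x_origin_o_negative_axis(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tr = make_arc(ArcSpec(jitter_sigma=0.4, rng_seed=rng.integers(1 << 30),
                                  pose_angle=rng.uniform(0, 360),
                                  pose_shift=tuple(rng.uniform(-50, 50, 2))))
            al = register_trace(tr)
            RX = rigid(tr.X[None], np.rad2deg(al.angle), al.shift)[0]
            RO = rigid(tr.O[None], np.rad2deg(al.angle), al.shift)[0]
            assert np.hypot(*RX) < 1e-9
            assert abs(RO[1]) < 1e-9 and RO[0] < 0
            # distances preserved
            d0 = np.linalg.norm(np.diff(tr.points, axis=0), axis=1)
            d1 = np.linalg.norm(np.diff(al.points, axis=0), axis=1)
            np.testing.assert_allclose(d0, d1, rtol=1e-9)

    def test_idempotent(self):
        tr = make_arc(ArcSpec(pose_angle=123.0, pose_shift=(4, 5)))
        al = register_trace(tr)
        again = register_trace(TubuleTrace(points=al.points,
                                           O=np.array([-13.5, 0.0]),
                                           X=np.array([0.0, 0.0])))
        np.testing.assert_allclose(again.points, al.points, atol=1e-9)
        assert abs(again.angle % (2 * np.pi)) < 1e-9

    def test_degenerate_landmarks_rejected(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 1]])
        with pytest.raises(ValueError):
            TubuleTrace(points=pts, O=np.zeros(2), X=np.zeros(2))


class TestCurvature:
    def test_exact_circle_local_radii(self):
        arc = make_arc(ArcSpec(radius_true=13.5, arc_span=90, n_points=10))
        r = local_radii(arc.points)
        np.testing.assert_allclose(r, 13.5, rtol=1e-9)
        assert mean_radius(arc.points) == pytest.approx(13.5, rel=1e-9)

    def test_collinear_triplet_flagged_nonfinite(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [3, 1]])
        r = local_radii(pts)
        assert np.isinf(r[0]) and np.isfinite(r[1])
        assert np.isfinite(mean_radius(pts))

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            local_radii(np.array([[0.0, 0], [0, 0], [1, 1]]))

    def test_jittered_arc_radius_recovery(self):
        ms = [mean_radius(make_arc(ArcSpec(radius_true=13.5, jitter_sigma=0.3,
                                           n_points=10, rng_seed=s)).points)
              for s in range(200)]
        assert np.mean(ms) == pytest.approx(13.5, rel=0.02)

    @given(angle=st.floats(0, 360), sx=st.floats(-100, 100), sy=st.floats(-100, 100))
    @settings(derandomize=True, max_examples=40)
    def test_rigid_motion_invariance(self, angle, sx, sy):
        arc = make_arc(ArcSpec(jitter_sigma=0.3, rng_seed=5))
        moved = rigid(arc.points, angle, (sx, sy))
        np.testing.assert_allclose(local_radii(moved), local_radii(arc.points), rtol=1e-9)
        assert fit_circle(moved)[1] == pytest.approx(fit_circle(arc.points)[1], rel=1e-9)

    def test_scaling_covariance(self):
        arc = make_arc(ArcSpec(jitter_sigma=0.2, rng_seed=3))
        for s in (0.5, 3.0):
            np.testing.assert_allclose(local_radii(arc.points * s),
                                       s * local_radii(arc.points), rtol=1e-12)
            assert mean_radius(arc.points * s) == pytest.approx(s * mean_radius(arc.points))


class TestCircleFit:
    def test_exact_on_circle(self):
        th = np.linspace(0, 2 * np.pi, 5)[:-1]
        pts = 20 * np.column_stack([np.cos(th), np.sin(th)])
        c, r = fit_circle(pts)
        assert r == pytest.approx(20.0, rel=1e-12)
        np.testing.assert_allclose(c, 0.0, atol=1e-9)

    def test_equilateral_triangle_circumradius(self):
        s = 7.0
        pts = np.array([[0.0, 0], [s, 0], [s / 2, s * np.sqrt(3) / 2]])
        _, r = fit_circle(pts)
        assert r == pytest.approx(s / np.sqrt(3), rel=1e-12)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            fit_circle(np.array([[0.0, 0], [1, 1], [2, 2]]))

    def test_small_bias_on_noisy_circles(self):
        rng = np.random.default_rng(0)
        radii = []
        for _ in range(500):
            th = rng.uniform(0, 2 * np.pi, 30)
            pts = 10 * np.column_stack([np.cos(th), np.sin(th)])
            pts += rng.normal(0, 0.2, pts.shape)  # sigma/R = 0.02
            radii.append(fit_circle(pts)[1])
        assert abs(np.mean(radii) / 10.0 - 1) < 0.01

    def test_estimators_agree_on_circles(self):
        arc = make_arc(ArcSpec(radius_true=13.5, arc_span=200, n_points=12))
        tm = curvature_result(arc, "triplet_mean").mean_radius
        cf = curvature_result(arc, "circle_fit").mean_radius
        assert tm == pytest.approx(cf, rel=1e-9)


class TestTwoCircle:
    def test_arithmetic_mean(self):
        assert two_circle_radius(15.0, 12.0) == 13.5
        assert two_circle_radius(10.0, 10.0 - 1e-6) == pytest.approx(10.0 - 5e-7)
        with pytest.raises(ValueError):
            two_circle_radius(10.0, 11.0)

    def test_synthetic_annulus_mid_radius(self):
        img = make_annulus_slice(mid_radius_nm=13.5, wall_thickness_nm=3.0,
                                 nm_per_px=0.25)
        m = measure_ring_radius(img, nm_per_px=0.25)
        assert m["r_outer"] > m["r_inner"]
        assert m["radius"] == pytest.approx(13.5, rel=0.02)


class TestGroupsAndOverlay:
    def test_percent_change_arithmetic(self):
        a = [curvature_result(make_arc(ArcSpec(radius_true=10.0)))]
        b = [curvature_result(make_arc(ArcSpec(radius_true=11.5)))]
        cmp_ = compare_curvature_groups(a, b)
        assert cmp_["percent_change"] == pytest.approx(15.0, abs=1e-6)
        same = compare_curvature_groups(a, a)
        assert same["percent_change"] == pytest.approx(0.0, abs=1e-9)

    def test_group_recovery_with_jitter(self):
        ga = [curvature_result(make_arc(ArcSpec(radius_true=13.15, jitter_sigma=0.3, rng_seed=s)))
              for s in range(200)]
        gb = [curvature_result(make_arc(ArcSpec(radius_true=15.1, jitter_sigma=0.3, rng_seed=1000 + s)))
              for s in range(200)]
        cmp_ = compare_curvature_groups(ga, gb)
        assert abs(cmp_["percent_change"] - 14.83) < 2.0

    def test_overlay_row_count(self):
        arcs = [make_arc(ArcSpec(rng_seed=s, n_points=5 + s)) for s in range(3)]
        aligned = [register_trace(a) for a in arcs]
        df = overlay_traces(aligned)
        assert len(df) == sum(5 + s for s in range(3))
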