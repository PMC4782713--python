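import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.segmentation import find_boundaries

from crmsnake.crm import (
    CRMSchedule,
    CRMStage,
    boundary_error,
    build_stage_field,
    default_concave_schedule,
    regenerate_coordinates,
    run_crm,
)
from crmsnake.exceptions import InvalidParameterError
from crmsnake.snake_core import Contour, SnakeParams, evolve
from crmsnake.synthetic import PhantomSpec, make_initial_circle, make_phantom

UNIT_SQUARE = Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


class TestRegeneration:
    def test_unit_square_at_quarter_spacing(self):
        out = regenerate_coordinates(UNIT_SQUARE, 0.25)
        assert len(out) == 16
        # corners retained in order, each edge split into 4 equal parts
        assert np.allclose(out.points[::4], UNIT_SQUARE.points)
        gaps = np.hypot(*(np.roll(out.points, -1, axis=0) - out.points).T)
        assert np.allclose(gaps, 0.25, atol=1e-12)

    def test_already_dense_contour_returned_unchanged(self):
        dense = regenerate_coordinates(UNIT_SQUARE, 0.25)
        again = regenerate_coordinates(dense, 0.3)
        assert again is dense

    def test_degenerate_contour_rejected(self):
        with pytest.raises(InvalidParameterError):
            regenerate_coordinates(UNIT_SQUARE, 2.0)

    @given(st.integers(0, 10_000))
    def test_gap_bound_and_point_retention(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 20)
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        rad = rng.uniform(2.0, 12.0, n)
        poly = Contour(np.column_stack([rad * np.cos(ang), rad * np.sin(ang)]))
        spacing = rng.uniform(0.3, 2.0)
        out = regenerate_coordinates(poly, spacing)
        gaps = np.hypot(*(np.roll(out.points, -1, axis=0) - out.points).T)
        assert gaps.max() <= spacing + 1e-9
        # every original point present, in order
        idx = [np.argmin(np.hypot(*(out.points - p).T)) for p in poly.points]
        assert np.allclose(out.points[idx], poly.points)
        assert all(a < b for a, b in zip(idx, idx[1:]))

    def test_cubic_interpolation_keeps_original_points(self):
        circle = make_initial_circle(0, 0, 10, 8)
        out = regenerate_coordinates(circle, 1.0, interpolation="cubic")
        idx = [np.argmin(np.hypot(*(out.points - p).T)) for p in circle.points]
        assert np.allclose(out.points[idx], circle.points, atol=1e-12)
        # spline points bulge outward from the chords, toward the circle
        mid_radii = np.hypot(*out.points[[i + 2 for i in idx[:-1]]].T)
        assert np.all(mid_radii > 9.0)


class TestBoundaryError:
    @staticmethod
    def disc_mask(radius=50, size=121):
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2

    def test_contour_on_boundary_has_zero_error(self):
        mask = self.disc_mask()
        b = find_boundaries(mask, mode="inner")
        by, bx = np.nonzero(b)
        pts = np.column_stack([bx, by]).astype(float)
        order = np.argsort(np.arctan2(pts[:, 1] - 60, pts[:, 0] - 60))
        summary = boundary_error(Contour(pts[order]), mask)
        assert summary.mean_distance == 0.0
        assert summary.max_distance == 0.0
        assert summary.mean_pct_diameter_error == 0.0

    def test_oversized_circle_diameter_error(self):
        # radius-52 circle against a radius-50 disc: (104-100)/100 on the axes;
        # on the diagonals the rasterised truth is 99.0 (pixel-centre projections)
        summary = boundary_error(make_initial_circle(60, 60, 52, 720), self.disc_mask())
        assert summary.diameters["horizontal"][2] == pytest.approx(4.0, abs=1e-6)
        assert summary.diameters["vertical"][2] == pytest.approx(4.0, abs=1e-6)
        for d in ("diag_down", "diag_up"):
            est, true, pct = summary.diameters[d]
            assert est == pytest.approx(104.0, abs=1e-6)
            assert pct == pytest.approx((104.0 - true) / true * 100.0, abs=1e-9)
            assert true == pytest.approx(99.0, abs=0.1)

    def test_distances_match_brute_force_oracle(self):
        star = make_phantom(PhantomSpec(kind="star", seed=4))
        contour = make_initial_circle(127.5, 127.5, 40, 32)
        summary = boundary_error(contour, star.mask)
        b = find_boundaries(star.mask, mode="inner")
        by, bx = np.nonzero(b)
        d_oracle = np.array([
            np.sqrt(((bx - x) ** 2 + (by - y) ** 2).min()) for x, y in contour.points
        ])
        assert summary.mean_distance == pytest.approx(d_oracle.mean(), abs=1e-9)
        assert summary.max_distance == pytest.approx(d_oracle.max(), abs=1e-9)

    def test_empty_mask_rejected(self):
        from crmsnake.exceptions import InvalidInputError

        with pytest.raises(InvalidInputError):
            boundary_error(UNIT_SQUARE, np.zeros((8, 8), dtype=bool))


class TestRunCRM:
    def test_single_stage_without_regeneration_is_ordinary_snake(self, u_phantom):
        init = make_initial_circle(127.5, 127.5, 80, 48)
        stage = CRMStage(iterations=20,
                         snake=SnakeParams(alpha=0.05, beta=0, delta_t=1.0,
                                           iterations=20, tol=None),
                         blur_n=16, gain=5.0)
        schedule = CRMSchedule(stages=[stage], regeneration_spacing=None)
        crm_out, _ = run_crm(u_phantom.image, init, schedule)
        field = build_stage_field(u_phantom.image, stage)
        from dataclasses import replace

        plain, _ = evolve(init, field, replace(stage.snake, gain=5.0))
        assert np.array_equal(crm_out.points, plain.points)

    def test_zero_gain_single_stage_returns_regenerated_input(self, u_phantom):
        init = make_initial_circle(127.5, 127.5, 80, 16)
        stage = CRMStage(iterations=5,
                         snake=SnakeParams(alpha=0.0, beta=0.0, delta_t=1.0,
                                           iterations=5, tol=None),
                         blur_n=16, gain=0.0)
        out, traces = run_crm(u_phantom.image, init, CRMSchedule(stages=[stage]))
        expected = regenerate_coordinates(init.oriented_ccw(), 1.0)
        assert np.allclose(out.points, expected.points)
        assert traces[0].n_points_regenerated == len(expected)

    def test_increasing_scale_schedule_warns(self):
        snake = SnakeParams(iterations=1, tol=None)
        with pytest.warns(UserWarning, match="non-increasing"):
            CRMSchedule(stages=[
                CRMStage(iterations=1, snake=snake, blur_n=2),
                CRMStage(iterations=1, snake=snake, blur_n=16),
            ])

    def test_coarse_to_fine_error_is_monotone(self, u_phantom):
        cx, cy = u_phantom.spec.resolved_centre()
        rng = np.random.default_rng(11)
        for _ in range(3):
            r = rng.uniform(82, 90)
            off = rng.uniform(-4, 4, 2)
            init = make_initial_circle(cx + off[0], cy + off[1], r, 64)
            _, traces = run_crm(u_phantom.image, init, default_concave_schedule())
            means = [boundary_error(t.final, u_phantom.mask).mean_distance for t in traces]
            # non-increasing up to sub-pixel jitter of the settled contour
            assert all(b <= a + 0.01 for a, b in zip(means, means[1:]))

    def test_partly_inside_initialisation_converges(self, u_phantom):
        cx, cy = u_phantom.spec.resolved_centre()
        init = make_initial_circle(cx + 30, cy, 60, 64)  # crosses the boundary
        final, _ = run_crm(u_phantom.image, init, default_concave_schedule())
        err = boundary_error(final, u_phantom.mask)
        assert err.mean_distance <= 1.0
        assert err.max_distance <= 2.0

    def test_stage_failures_name_the_stage(self, u_phantom):
        init = make_initial_circle(127.5, 127.5, 80, 16)
        bad = CRMStage(iterations=2, snake=SnakeParams(iterations=2, tol=None),
                       log_size=301)  # kernel larger than the image
        with pytest.raises(InvalidParameterError, match="stage 0"):
            run_crm(u_phantom.image, init, CRMSchedule(stages=[bad]))
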