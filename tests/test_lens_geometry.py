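from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lensuse.fixation_detection import FixationEvent
from lensuse.lens_geometry import (
    DEFAULT_LEVER_ARM_MM,
    AngularDomainError,
    FrameGeometry,
    LensPoint,
    LensSurfaceModel,
    NoIntersectionError,
    angular_to_lens_mm,
    cre_position,
    intersect_gaze_with_surface,
    project_fixations,
    to_fitting_cross_frame,
)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def bisect_sphere_t(p, v, center, radius, lo=1e-9, hi=1e4, tol=1e-12):
    """Independent oracle: bisection on ||p + t v - c|| - r over a bracket."""
    p, v, c = map(np.asarray, (p, v, center))

    def f(t):
        return np.linalg.norm(p + t * v - c) - radius

    # walk up to find the first sign change (entry point)
    t_prev, f_prev = lo, f(lo)
    for t in np.linspace(lo, hi, 20001):
        ft = f(t)
        if f_prev * ft <= 0 and t > t_prev:
            lo, hi = t_prev, t
            break
        t_prev, f_prev = t, ft
    else:
        raise AssertionError("oracle found no sign change")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


def bisect_plane_t(p, v, plane_z, lo=1e-9, hi=1e4, tol=1e-12):
    """Independent oracle: bisection on the z-residual."""
    p, v = map(np.asarray, (p, v))

    def f(t):
        return p[2] + t * v[2] - plane_z

    if f(lo) * f(hi) > 0:
        raise AssertionError("oracle bracket does not straddle the plane")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


class TestPlaneIntersection:
    def test_axial_ray(self):
        hit = intersect_gaze_with_surface((0, 0, 0), (0, 0, 1), LensSurfaceModel.plane(25))
        np.testing.assert_allclose(hit, [0, 0, 25], atol=1e-12)

    def test_oblique_ray_against_substitution_oracle(self):
        v = _unit((0.1, -0.2, 1.0))
        p = np.array([1.0, 2.0, 0.0])
        hit = intersect_gaze_with_surface(p, v, LensSurfaceModel.plane(30))
        t = 30.0 / v[2]  # closed-form substitution
        np.testing.assert_allclose(hit, p + t * v, atol=1e-9)
        assert abs(hit[2] - 30.0) < 1e-9

    def test_parallel_ray_raises(self):
        with pytest.raises(NoIntersectionError):
            intersect_gaze_with_surface((0, 0, 0), (1, 0, 0), LensSurfaceModel.plane(25))

    def test_backward_ray_raises(self):
        with pytest.raises(NoIntersectionError):
            intersect_gaze_with_surface((0, 0, 0), (0, 0, -1), LensSurfaceModel.plane(25))

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            intersect_gaze_with_surface((0, 0, 0), (0, 0, 2), LensSurfaceModel.plane(25))


class TestSphereIntersection:
    def test_oblique_ray_against_bisection_oracle(self):
        v = _unit((math.sin(math.radians(5)), 0.0, math.cos(math.radians(5))))
        surface = LensSurfaceModel.sphere((0, 0, 92), 80)
        hit = intersect_gaze_with_surface((0, 0, 0), v, surface)
        t = bisect_sphere_t((0, 0, 0), v, (0, 0, 92), 80)
        np.testing.assert_allclose(hit, t * v, atol=1e-6)
        assert abs(np.linalg.norm(hit - np.array([0, 0, 92])) - 80) < 1e-6

    def test_smallest_positive_root_chosen(self):
        surface = LensSurfaceModel.sphere((0, 0, 92), 80)
        hit = intersect_gaze_with_surface((0, 0, 0), (0, 0, 1), surface)
        assert hit[2] == pytest.approx(12.0, abs=1e-9)  # 92 - 80, not 92 + 80

    def test_miss_raises(self):
        surface = LensSurfaceModel.sphere((0, 0, 92), 80)
        with pytest.raises(NoIntersectionError):
            intersect_gaze_with_surface((0, 0, 0), (0, 0.9, -0.43589), LensSurfaceModel.sphere((0, 0, 5), 1))

    def test_sphere_behind_raises(self):
        surface = LensSurfaceModel.sphere((0, 0, -92), 80)
        with pytest.raises(NoIntersectionError):
            intersect_gaze_with_surface((0, 0, 0), (0, 0, 1), surface)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10**6))
def test_plane_sphere_agree_in_large_radius_limit(seed):
    rng = np.random.default_rng(seed)
    v = _unit([rng.normal(0, 0.2), rng.normal(0, 0.2), 1.0])
    p = rng.uniform(-5, 5, size=3) * [1, 1, 0]
    radius = 1e6
    plane = LensSurfaceModel.plane(25.5)
    sphere = LensSurfaceModel.sphere((0, 0, 25.5 + radius), radius)
    hp = intersect_gaze_with_surface(p, v, plane)
    hs = intersect_gaze_with_surface(p, v, sphere)
    assert np.linalg.norm(hp - hs) < 1e-3


class TestFittingCrossFrame:
    def test_point_at_right_fitting_cross_is_origin(self, frame62):
        fc = frame62.fitting_cross("right")
        p = to_fitting_cross_frame([fc[0], fc[1], 25.5], frame62, "right")
        assert (p.x, p.y) == (0.0, 0.0)

    def test_vertical_offset(self, frame62):
        fc = frame62.fitting_cross("right")
        p = to_fitting_cross_frame([fc[0], fc[1] + 3.0, 25.5], frame62, "right")
        assert (p.x, p.y) == (0.0, 3.0)

    def test_left_eye_nasal_sign(self, frame62):
        # 2 mm toward the nose for the left eye: toward x = 0, i.e. -x
        fc = frame62.fitting_cross("left")
        p = to_fitting_cross_frame([fc[0] - 2.0, fc[1], 25.5], frame62, "left")
        assert p.x == pytest.approx(-2.0)
        assert p.x_nasal == pytest.approx(2.0)

    def test_unknown_eye(self, frame62):
        with pytest.raises(ValueError):
            to_fitting_cross_frame([0, 0, 25.5], frame62, "middle")

    def test_lens_point_nasal_convention(self):
        assert LensPoint(x=1.0, y=0.0, eye="right").x_nasal == 1.0
        assert LensPoint(x=1.0, y=0.0, eye="left").x_nasal == -1.0


def _fixation(eye, pupil, direction):
    return FixationEvent(
        t_start=0.0, t_end=0.25, mean_gaze_dir=_unit(direction),
        mean_pupil_pos=np.asarray(pupil, dtype=float), eye=eye, n_samples=12,
    )


class TestProjectFixations:
    def test_axial_fixation_through_fitting_cross(self, frame62, plane_surface):
        cre = cre_position(frame62, plane_surface, "right")
        (p,) = project_fixations([_fixation("right", cre, (0, 0, 1))], frame62, plane_surface)
        assert p.x == pytest.approx(0.0, abs=1e-12)
        assert p.y == pytest.approx(0.0, abs=1e-12)

    def test_identical_fixations_project_identically(self, frame62, plane_surface):
        cre = cre_position(frame62, plane_surface, "right")
        fx = _fixation("right", cre, (0.05, 0.02, 1.0))
        pts = project_fixations([fx] * 10, frame62, plane_surface)
        assert len(pts) == 10
        assert len({(p.x, p.y) for p in pts}) == 1

    def test_elevation_matches_trig_oracle(self, frame62, plane_surface):
        # target 0.317 m above primary gaze at 5.25 m
        el = math.atan(0.317 / 5.25)
        cre = cre_position(frame62, plane_surface, "right")
        fx = _fixation("right", cre, (0.0, math.sin(el), math.cos(el)))
        (p,) = project_fixations([fx], frame62, plane_surface)
        assert p.y == pytest.approx(frame62.cre_to_lens * math.tan(el), abs=1e-6)
        assert math.degrees(el) == pytest.approx(3.455, abs=2e-3)

    def test_no_intersection_collected_not_dropped(self, frame62, plane_surface):
        cre = cre_position(frame62, plane_surface, "right")
        good = _fixation("right", cre, (0, 0, 1))
        bad = _fixation("right", cre, (0, 0, -1))
        points, failures = project_fixations([good, bad], frame62, plane_surface, on_error="collect")
        assert len(points) == 1
        assert [i for i, _ in failures] == [1]
        with pytest.raises(NoIntersectionError):
            project_fixations([good, bad], frame62, plane_surface)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10**6))
def test_mirror_symmetry(seed):
    """Negating x of pupil and gaze while swapping eyes negates LensPoint.x
    and preserves x_nasal."""
    frame = FrameGeometry(ipd=62.0)
    surface = LensSurfaceModel.plane(frame.cre_to_lens)
    rng = np.random.default_rng(seed)
    pupil = np.array([rng.uniform(-35, -25), rng.uniform(-3, 3), rng.uniform(-2, 2)])
    v = _unit([rng.normal(0, 0.2), rng.normal(0, 0.2), 1.0])
    p_r = to_fitting_cross_frame(intersect_gaze_with_surface(pupil, v, surface), frame, "right")
    mirror_pupil = pupil * [-1, 1, 1]
    mirror_v = v * [-1, 1, 1]
    p_l = to_fitting_cross_frame(
        intersect_gaze_with_surface(mirror_pupil, mirror_v, surface), frame, "left"
    )
    assert p_l.x == pytest.approx(-p_r.x, abs=1e-9)
    assert p_l.y == pytest.approx(p_r.y, abs=1e-9)
    assert p_l.x_nasal == pytest.approx(p_r.x_nasal, abs=1e-9)


def test_rightward_rotation_sign_contract(frame62, plane_surface):
    """Gaze toward the wearer's right: temporal on the right lens, nasal on the left."""
    az = math.radians(-8.0)  # -x is the wearer's right
    v = np.array([math.sin(az), 0.0, math.cos(az)])
    for eye in ("left", "right"):
        cre = cre_position(frame62, plane_surface, eye)
        p = to_fitting_cross_frame(
            intersect_gaze_with_surface(cre, v, plane_surface), frame62, eye
        )
        if eye == "right":
            assert p.x_nasal < 0  # temporal
        else:
            assert p.x_nasal > 0  # nasal


class TestAngularToLensMm:
    def test_zero_angle(self):
        assert angular_to_lens_mm(0.0, 17.0) == 0.0

    def test_error_budget_worked_examples(self):
        assert round(angular_to_lens_mm(0.6, DEFAULT_LEVER_ARM_MM), 2) == 0.34
        assert round(angular_to_lens_mm(0.03, DEFAULT_LEVER_ARM_MM), 2) == 0.02

    def test_one_degree_at_30mm(self):
        assert angular_to_lens_mm(1.0, 30.0) == pytest.approx(30.0 * math.tan(math.radians(1.0)))
        assert angular_to_lens_mm(1.0, 30.0) == pytest.approx(0.5236, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(AngularDomainError):
            angular_to_lens_mm(90.0, 30.0)
        with pytest.raises(AngularDomainError):
            angular_to_lens_mm(-95.0, 30.0)
        with pytest.raises(ValueError):
            angular_to_lens_mm(1.0, 0.0)


class TestFrameGeometry:
    def test_validation(self):
        with pytest.raises(ValueError):
            FrameGeometry(ipd=0)
        with pytest.raises(ValueError):
            FrameGeometry(ipd=62, bvd=0)
        with pytest.raises(ValueError):
            FrameGeometry(ipd=62, bvd=12, cre_to_lens=10)

    def test_tilt_and_wrap_warn(self):
        with pytest.warns(UserWarning, match="ignored"):
            FrameGeometry(ipd=62, pantoscopic_tilt=8.0)

    def test_default_fitting_crosses_symmetric(self, frame62):
        r = frame62.fitting_cross("right")
        l = frame62.fitting_cross("left")
        assert r[0] == -31.0 and l[0] == 31.0 and r[1] == l[1]

    def test_cre_positions(self, frame62, plane_surface):
        r = cre_position(frame62, plane_surface, "right")
        np.testing.assert_allclose(r, [-31.0, 0.0, 0.0])
        l = cre_position(frame62, plane_surface, "left")
        np.testing.assert_allclose(l, [31.0, 0.0, 0.0])


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 10**6))
def test_returned_point_lies_on_ray_and_surface(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(-5, 5, 3) * [1, 1, 0.2]
    v = _unit([rng.normal(0, 0.3), rng.normal(0, 0.3), 1.0])
    for surface in (LensSurfaceModel.plane(25.5), LensSurfaceModel.sphere((0, 0, 92), 80)):
        hit = intersect_gaze_with_surface(p, v, surface)
        t = np.dot(hit - p, v)
        np.testing.assert_allclose(hit, p + t * v, atol=1e-9)
        if surface.kind == "plane":
            assert abs(hit[2] - 25.5) < 1e-9
        else:
            assert abs(np.linalg.norm(hit - np.array([0, 0, 92])) - 80) < 1e-6
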