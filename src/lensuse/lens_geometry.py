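"""Gaze-to-lens projection geometry.

Coordinate convention (binding for the whole package): right-handed headset
frame with origin at the eye-tracker reference point, ``+z`` forward along
primary gaze, ``+y`` up and ``+x`` toward the wearer's *left*.  The nose sits
near ``x = 0``; the right-eye rotation center (CRE) is at ``x = -ipd/2`` and
the left-eye CRE at ``x = +ipd/2``.  Under this triad, nasal is ``+x`` for the
right eye and ``-x`` for the left eye.

All lengths are millimetres, all angles degrees unless stated otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

Eye = Literal["left", "right"]
EYES: tuple[str, str] = ("left", "right")

#: Lever arm (mm) used when converting the device's angular error figures to
#: linear displacement on the lens.  Chosen so the documented worked examples
#: round to the published two-decimal values; note it exceeds the default
#: CRE-to-lens distance of 25.5 mm, which is deliberate and documented.
DEFAULT_LEVER_ARM_MM = 32.5

#: Default cornea-to-CRE distance (mm) used to build ``cre_to_lens`` when only
#: a back vertex distance is known.
CORNEA_TO_CRE_MM = 13.5


class GeometryError(ValueError):
    """Base class for geometry failures."""


class NoIntersectionError(GeometryError):
    """The sight line does not pierce the lens surface at positive range."""


class AngularDomainError(GeometryError):
    """Angle outside the valid (-90, 90) degree open interval."""


def _check_eye(eye: str) -> str:
    if eye not in EYES:
        raise ValueError(f"unknown eye label {eye!r}; expected 'left' or 'right'")
    return eye


@dataclass(frozen=True)
class FrameGeometry:
    """Per-subject fitting parameters locating the lens and fitting crosses.

    Parameters
    ----------
    ipd:
        Interpupillary distance, mm.
    pupil_height:
        Height (mm, headset y) of the fitting crosses; also the assumed CRE
        height so that primary gaze pierces the fitting cross.
    bvd:
        Back vertex distance, cornea apex to lens back surface, mm.
    cre_to_lens:
        Eye rotation center to lens plane along primary gaze, mm.  Default
        25.5 = 13.5 (cornea to CRE) + 12 (vertex distance).
    fitting_cross_right, fitting_cross_left:
        Optional (x, y) mm positions of the fitting crosses in the lens plane.
        Default: symmetric about the midline at ``x = -/+ ipd/2``,
        ``y = pupil_height``.
    pantoscopic_tilt, wrap_angle:
        Read from fitting files but *not* applied by the projection (a warning
        is emitted when nonzero).
    """

    ipd: float
    pupil_height: float = 0.0
    bvd: float = 12.0
    cre_to_lens: float = CORNEA_TO_CRE_MM + 12.0
    fitting_cross_right: tuple[float, float] | None = None
    fitting_cross_left: tuple[float, float] | None = None
    pantoscopic_tilt: float = 0.0
    wrap_angle: float = 0.0

    def __post_init__(self) -> None:
        if not self.ipd > 0:
            raise ValueError("ipd must be > 0")
        if not self.bvd > 0:
            raise ValueError("bvd must be > 0")
        if not self.cre_to_lens > self.bvd:
            raise ValueError("cre_to_lens must exceed bvd")
        if self.pantoscopic_tilt or self.wrap_angle:
            warnings.warn(
                "pantoscopic tilt / wrap angle are recorded but ignored by the "
                "projection model",
                stacklevel=2,
            )

    def fitting_cross(self, eye: str) -> np.ndarray:
        """(x, y) position of the eye's fitting cross in the lens plane."""
        _check_eye(eye)
        explicit = self.fitting_cross_right if eye == "right" else self.fitting_cross_left
        if explicit is not None:
            return np.asarray(explicit, dtype=float)
        x = -self.ipd / 2.0 if eye == "right" else self.ipd / 2.0
        return np.array([x, self.pupil_height])


@dataclass(frozen=True)
class LensSurfaceModel:
    """Back surface of the lens: a plane (default) or a sphere concave to the eye."""

    kind: Literal["plane", "sphere"]
    plane_z: float | None = None
    center: tuple[float, float, float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "plane":
            if self.plane_z is None or not self.plane_z > 0:
                raise ValueError("plane surface requires plane_z > 0")
        elif self.kind == "sphere":
            if self.center is None or self.radius is None or not self.radius > 0:
                raise ValueError("sphere surface requires center and radius > 0")
        else:
            raise ValueError(f"unknown surface kind {self.kind!r}")

    @classmethod
    def plane(cls, z: float) -> "LensSurfaceModel":
        return cls(kind="plane", plane_z=z)

    @classmethod
    def sphere(cls, center: Sequence[float], radius: float) -> "LensSurfaceModel":
        cx, cy, cz = (float(v) for v in center)
        return cls(kind="sphere", center=(cx, cy, cz), radius=float(radius))

    @property
    def vertex_z(self) -> float:
        """z of the surface point on the primary-gaze axis (its 'vertex')."""
        if self.kind == "plane":
            assert self.plane_z is not None
            return self.plane_z
        assert self.center is not None and self.radius is not None
        # concave toward the eye: center lies beyond the lens, vertex in front
        return self.center[2] - self.radius


@dataclass(frozen=True)
class LensPoint:
    """A point on the lens, expressed relative to the fitting cross by default.

    ``x`` is signed in the headset convention (+x toward the wearer's left);
    ``x_nasal`` re-expresses it nasal-positive: ``+x`` for the right eye,
    ``-x`` for the left eye.
    """

    x: float
    y: float
    eye: str
    relative_to: Literal["fitting_cross", "lens_plane_origin"] = "fitting_cross"

    def __post_init__(self) -> None:
        _check_eye(self.eye)

    @property
    def x_nasal(self) -> float:
        return self.x if self.eye == "right" else -self.x


def cre_position(frame: FrameGeometry, surface: LensSurfaceModel, eye: str) -> np.ndarray:
    """3-D position of the eye's center of rotation in the headset frame."""
    _check_eye(eye)
    x = -frame.ipd / 2.0 if eye == "right" else frame.ipd / 2.0
    return np.array([x, frame.pupil_height, surface.vertex_z - frame.cre_to_lens])


def intersect_gaze_with_surface(
    pupil_pos: Sequence[float],
    gaze_dir: Sequence[float],
    surface: LensSurfaceModel,
) -> np.ndarray:
    """Pierce point ``P' = P + t v`` of a sight line with the lens back surface.

    Returns the point with the smallest positive ray parameter ``t``.  Raises
    :class:`NoIntersectionError` when the ray is parallel to, points away
    from, or misses the surface.
    """
    p = np.asarray(pupil_pos, dtype=float)
    v = np.asarray(gaze_dir, dtype=float)
    if p.shape != (3,) or v.shape != (3,):
        raise ValueError("pupil_pos and gaze_dir must be 3-vectors")
    norm = float(np.linalg.norm(v))
    if not math.isclose(norm, 1.0, abs_tol=1e-6):
        raise ValueError(f"gaze_dir must be a unit vector (norm={norm:.6g})")

    if surface.kind == "plane":
        assert surface.plane_z is not None
        if abs(v[2]) < 1e-12:
            raise NoIntersectionError("gaze parallel to the lens plane")
        t = (surface.plane_z - p[2]) / v[2]
        if t <= 0:
            raise NoIntersectionError("lens plane lies behind the gaze direction")
        return p + t * v

    assert surface.center is not None and surface.radius is not None
    c = np.asarray(surface.center, dtype=float)
    r = float(surface.radius)
    d = p - c
    b = 2.0 * float(np.dot(v, d))
    cq = float(np.dot(d, d)) - r * r
    disc = b * b - 4.0 * cq
    if disc < 0:
        raise NoIntersectionError("sight line misses the spherical surface")
    sq = math.sqrt(disc)
    roots = sorted(((-b - sq) / 2.0, (-b + sq) / 2.0))
    t = next((root for root in roots if root > 1e-12), None)
    if t is None:
        raise NoIntersectionError("spherical surface lies behind the gaze direction")
    return p + t * v


def to_fitting_cross_frame(
    p_lens: Sequence[float], frame: FrameGeometry, eye: str
) -> LensPoint:
    """Express an on-surface point relative to the eye's fitting cross."""
    _check_eye(eye)
    p = np.asarray(p_lens, dtype=float)
    fc = frame.fitting_cross(eye)
    return LensPoint(x=float(p[0] - fc[0]), y=float(p[1] - fc[1]), eye=eye)


def project_fixations(
    fixations: Iterable,
    frame: FrameGeometry,
    surface: LensSurfaceModel,
    on_error: Literal["raise", "collect"] = "raise",
) -> list[LensPoint] | tuple[list[LensPoint], list[tuple[int, Exception]]]:
    """Project fixation events (mean pupil position / mean gaze direction) onto
    the lens and express each pierce point relative to the fitting cross.

    With ``on_error='collect'`` returns ``(points, failures)`` where failures
    pairs the fixation index with the raised :class:`NoIntersectionError`, so
    non-intersecting fixations are reported rather than silently dropped.
    """
    points: list[LensPoint] = []
    failures: list[tuple[int, Exception]] = []
    for i, fx in enumerate(fixations):
        try:
            hit = intersect_gaze_with_surface(fx.mean_pupil_pos, fx.mean_gaze_dir, surface)
        except NoIntersectionError as exc:
            if on_error == "raise":
                raise NoIntersectionError(f"fixation {i}: {exc}") from exc
            failures.append((i, exc))
            continue
        points.append(to_fitting_cross_frame(hit, frame, fx.eye))
    if on_error == "collect":
        return points, failures
    return points


def project_samples(
    samples: Iterable,
    frame: FrameGeometry,
    surface: LensSurfaceModel,
) -> list[LensPoint]:
    """Per-sample projection route (alternative to mean-first projection).

    Invalid samples are skipped; non-intersecting samples raise.
    """
    points = []
    for s in samples:
        if not s.valid:
            continue
        hit = intersect_gaze_with_surface(s.pupil_pos, s.gaze_dir, surface)
        points.append(to_fitting_cross_frame(hit, frame, s.eye))
    return points


def angular_to_lens_mm(angle_deg: float, lever_arm_mm: float) -> float:
    """Linear displacement on the lens corresponding to an angular error:
    ``lever_arm * tan(angle)``.
    """
    if not lever_arm_mm > 0:
        raise ValueError("lever_arm_mm must be > 0")
    if abs(angle_deg) >= 90.0:
        raise AngularDomainError("angle must satisfy |angle| < 90 degrees")
    return lever_arm_mm * math.tan(math.radians(angle_deg))
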