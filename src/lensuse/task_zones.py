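"""Theoretical regions of use on the lens computed from task geometry.

A task is a rectangle of text at a known distance and head-relative direction.
For each eye, sight lines from the eye rotation center to the four corners of
the rectangle are intersected with the lens back surface; the axis-aligned
bounding box of the pierce points, expanded on every edge by half the cohort
mean pupil diameter, is the theoretical zone for that eye and condition.

Azimuth sign convention: positive azimuth is toward the wearer's *left*
(+x in the headset frame).  A counterclockwise subject rotation with a fixed
screen therefore corresponds to a *negative* target azimuth (target toward
the wearer's right).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .lens_geometry import (
    EYES,
    FrameGeometry,
    LensSurfaceModel,
    NoIntersectionError,
    cre_position,
    intersect_gaze_with_surface,
)

#: cohort mean pupil diameters (mm) for distance- and near-reading tasks
DISTANCE_PUPIL_MM = 3.73
NEAR_PUPIL_MM = 2.88

#: default head-relative elevation (deg) of the near-reading screen; the
#: vertical placement of the near screen is an assumption (typical reading
#: posture), not a measured value, and must be stated in reports.
NEAR_ELEVATION_DEFAULT_DEG = -20.0


class ZoneUndefinedError(ValueError):
    """A zone corner direction fails to intersect the lens surface."""


@dataclass(frozen=True)
class TaskGeometry:
    """Geometry of one reading-task condition.

    ``target_distance`` is metres from the CRE plane to the target; angular
    extents and offsets are degrees.  Exactly one of ``elevation_offset`` /
    ``target_height`` (metres above primary gaze, negative below) must be
    given; the other is derived.
    """

    name: str
    target_distance: float
    azimuth_offset: float = 0.0
    elevation_offset: float | None = None
    target_height: float | None = None
    angular_width: float = 0.0
    angular_height: float = 0.0
    mean_pupil_diameter: float = 0.0

    def __post_init__(self) -> None:
        if not self.target_distance > 0:
            raise ValueError("target_distance must be > 0")
        if self.angular_width < 0 or self.angular_height < 0:
            raise ValueError("angular extents must be >= 0")
        if self.mean_pupil_diameter < 0:
            raise ValueError("mean_pupil_diameter must be >= 0")
        if (self.elevation_offset is None) == (self.target_height is None):
            if self.elevation_offset is None:
                object.__setattr__(self, "elevation_offset", 0.0)
            else:
                raise ValueError("give exactly one of elevation_offset / target_height")

    @property
    def elevation_deg(self) -> float:
        if self.elevation_offset is not None:
            return float(self.elevation_offset)
        assert self.target_height is not None
        return math.degrees(math.atan2(self.target_height, self.target_distance))


@dataclass(frozen=True)
class TheoreticalZone:
    """Axis-aligned rectangle on the lens plane expected to be used for a task.

    Bounds are mm relative to the fitting cross in the signed headset
    convention; nasal-positive bounds are derived per eye.
    """

    eye: str
    condition: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    margin: float

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"unknown eye label {self.eye!r}")
        # non-strict so a fully degenerate task (zero extents, zero pupil
        # margin) may collapse to its primary pierce point
        if not (self.x_min <= self.x_max and self.y_min <= self.y_max):
            raise ValueError("zone bounds must satisfy x_min <= x_max, y_min <= y_max")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def x_nasal_bounds(self) -> tuple[float, float]:
        """(min, max) bounds on the nasal-positive horizontal axis."""
        if self.eye == "right":
            return (self.x_min, self.x_max)
        return (-self.x_max, -self.x_min)


def direction_from_angles(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit sight direction from head-relative azimuth/elevation (degrees)."""
    az = math.radians(azimuth_deg)
    el = math.radians(elevation_deg)
    return np.array([math.cos(el) * math.sin(az), math.sin(el), math.cos(el) * math.cos(az)])


def target_center_offsets_mm(task: TaskGeometry) -> np.ndarray:
    """Target-center position (mm) relative to the cyclopean point between the
    CREs, at the task's distance along its head-relative direction.
    """
    d_mm = task.target_distance * 1000.0
    return d_mm * direction_from_angles(task.azimuth_offset, task.elevation_deg)


def per_eye_target_angles(
    task: TaskGeometry,
    frame: FrameGeometry,
    eye: str,
    mode: Literal["convergent", "head_relative"] = "convergent",
) -> tuple[float, float]:
    """(azimuth, elevation) in degrees of the line from the eye's CRE to the
    target center.

    ``convergent`` (default) accounts for the eye's lateral offset of
    ±ipd/2, so a symmetric target yields a small nasal azimuth for each eye;
    ``head_relative`` treats the eye as sitting at the cyclopean midpoint
    (optical-infinity behaviour).
    """
    if eye not in EYES:
        raise ValueError(f"unknown eye label {eye!r}")
    target = target_center_offsets_mm(task)
    if mode == "head_relative":
        eye_pos = np.zeros(3)
    elif mode == "convergent":
        x = -frame.ipd / 2.0 if eye == "right" else frame.ipd / 2.0
        eye_pos = np.array([x, 0.0, 0.0])
    else:
        raise ValueError(f"unknown vergence mode {mode!r}")
    d = target - eye_pos
    az = math.degrees(math.atan2(d[0], d[2]))
    el = math.degrees(math.atan2(d[1], math.hypot(d[0], d[2])))
    return az, el


def theoretical_zone(
    task: TaskGeometry,
    frame: FrameGeometry,
    eye: str,
    surface: LensSurfaceModel,
    mode: Literal["convergent", "head_relative"] = "convergent",
) -> TheoreticalZone:
    """Theoretical region of use for one eye and condition.

    Sight lines from the eye's CRE toward the four target-rectangle corner
    directions (center angles ± half extents) are intersected with the lens
    surface; the pierce-point bounding box, relative to the fitting cross and
    expanded by ``mean_pupil_diameter / 2`` on every edge, is the zone.
    """
    az_c, el_c = per_eye_target_angles(task, frame, eye, mode=mode)
    origin = cre_position(frame, surface, eye)
    fc = frame.fitting_cross(eye)
    xs, ys = [], []
    for daz in (-task.angular_width / 2.0, task.angular_width / 2.0):
        for del_ in (-task.angular_height / 2.0, task.angular_height / 2.0):
            v = direction_from_angles(az_c + daz, el_c + del_)
            try:
                hit = intersect_gaze_with_surface(origin, v, surface)
            except NoIntersectionError as exc:
                raise ZoneUndefinedError(
                    f"{task.name}/{eye}: corner ({az_c + daz:.2f}, {el_c + del_:.2f}) deg "
                    f"does not intersect the lens surface"
                ) from exc
            xs.append(hit[0] - fc[0])
            ys.append(hit[1] - fc[1])
    margin = task.mean_pupil_diameter / 2.0
    return TheoreticalZone(
        eye=eye,
        condition=task.name,
        x_min=min(xs) - margin,
        x_max=max(xs) + margin,
        y_min=min(ys) - margin,
        y_max=max(ys) + margin,
        margin=margin,
    )


# ---------------------------------------------------------------------------
# study task presets
# ---------------------------------------------------------------------------

def distance_reading_task(azimuth_offset_deg: float = 0.0, name: str | None = None) -> TaskGeometry:
    """Distance-reading condition: 5.25 m screen, text 4.2° x 2.3°, screen
    center 0.317 m above primary gaze, cohort pupil 3.73 mm.  Off-axis
    (counterclockwise-rotation) conditions use negative azimuth offsets.
    """
    if name is None:
        name = "distance_on_axis" if azimuth_offset_deg == 0 else f"distance_off_{abs(azimuth_offset_deg):g}"
    return TaskGeometry(
        name=name,
        target_distance=5.25,
        azimuth_offset=azimuth_offset_deg,
        target_height=0.317,
        angular_width=4.2,
        angular_height=2.3,
        mean_pupil_diameter=DISTANCE_PUPIL_MM,
    )


def near_reading_task(
    column: Literal["left", "center", "right", "full"] = "center",
    elevation_offset_deg: float = NEAR_ELEVATION_DEFAULT_DEG,
) -> TaskGeometry:
    """Near-reading condition: 0.37 m screen, three 3°-wide text columns of
    height 3.6° at azimuths +12.5° (left), 0° and -12.5° (right); ``full``
    covers the whole 28° x 3.6° text block.  Cohort pupil 2.88 mm.

    The screen's elevation is not a measured quantity; the default of -20°
    is a documented reading-posture assumption.
    """
    offsets = {"left": 12.5, "center": 0.0, "right": -12.5, "full": 0.0}
    if column not in offsets:
        raise ValueError(f"unknown near-task column {column!r}")
    return TaskGeometry(
        name=f"near_{column}",
        target_distance=0.37,
        azimuth_offset=offsets[column],
        elevation_offset=elevation_offset_deg,
        angular_width=28.0 if column == "full" else 3.0,
        angular_height=3.6,
        mean_pupil_diameter=NEAR_PUPIL_MM,
    )


def zone_table(zones) -> "pd.DataFrame":
    """Zones as a DataFrame matching the CSV export schema."""
    import pandas as pd

    rows = []
    for z in zones:
        nmin, nmax = z.x_nasal_bounds
        rows.append(
            {
                "condition": z.condition,
                "eye": z.eye,
                "x_min": z.x_min,
                "x_max": z.x_max,
                "y_min": z.y_min,
                "y_max": z.y_max,
                "x_nasal_min": nmin,
                "x_nasal_max": nmax,
                "margin": z.margin,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition", "eye", "x_min", "x_max", "y_min", "y_max",
            "x_nasal_min", "x_nasal_max", "margin",
        ],
    )
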