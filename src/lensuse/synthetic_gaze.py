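"""Seeded synthetic eye-tracker recordings.

Generates 50 Hz binocular gaze streams for a task scenario: a reading-like
scanpath of fixation targets raster-sweeping the task's text rectangle, true
per-eye convergent gaze directions from each eye rotation center (CRE) to the
current target, perturbed by a fixed-direction accuracy bias and per-sample
precision jitter, with independent sample dropout.  Identical scenario + seed
reproduce the recording bit-for-bit.

Also provides the pinhole validity-check scenario: every true sight line of
the right eye passes through a known point on the lens, so the projection
error of the full pipeline can be measured against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .lens_geometry import (
    EYES,
    FrameGeometry,
    LensPoint,
    LensSurfaceModel,
    cre_position,
    intersect_gaze_with_surface,
    to_fitting_cross_frame,
)
from .recordings_io import GazeSample, Recording
from .task_zones import TaskGeometry, direction_from_angles, target_center_offsets_mm

#: CRE-to-entrance-pupil distance (mm): pupil modeled at CRE + this offset
#: along the current gaze direction.
PUPIL_OFFSET_MM = 11.0

_SCANPATH_LINES = 5
_SCANPATH_COLS = 7


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to generate one synthetic recording."""

    task: TaskGeometry
    frame: FrameGeometry
    duration: float
    seed: int
    sample_rate: float = 50.0
    accuracy_bias: float = 0.6
    precision_sd: float = 0.03
    data_loss_p: float = 0.0
    fixation_rate: float = 4.0
    surface: LensSurfaceModel | None = None
    bias_direction_deg: float | None = None  # None -> random per eye
    pupil_diameter_mm: float | None = None
    subject_id: str = "sim"
    condition_id: str = ""

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        if not self.fixation_rate > 0:
            raise ValueError("fixation_rate must be > 0")
        if not 0 <= self.data_loss_p < 1:
            raise ValueError("data_loss_p must be in [0, 1)")
        if self.accuracy_bias < 0 or self.precision_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is required (reproducibility contract)")

    def resolved_surface(self) -> LensSurfaceModel:
        if self.surface is not None:
            return self.surface
        # default: lens plane with the CRE plane at z = 0
        return LensSurfaceModel.plane(self.frame.cre_to_lens)

    def resolved_pupil_diameter(self) -> float:
        if self.pupil_diameter_mm is not None:
            return self.pupil_diameter_mm
        return self.task.mean_pupil_diameter if self.task.mean_pupil_diameter > 0 else 3.5


def _perturb(v: np.ndarray, angle_deg: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate each row of ``v`` by ``angle_deg`` toward the in-plane direction
    ``phi`` (exact rotation; zero angle returns ``v`` unchanged)."""
    v = np.atleast_2d(v)
    up = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(np.broadcast_to(up, v.shape), v)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(v, e1)
    theta = np.radians(np.asarray(angle_deg, dtype=float)).reshape(-1, 1)
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    lateral = np.cos(phi) * e1 + np.sin(phi) * e2
    return np.cos(theta) * v + np.sin(theta) * lateral


def _fixation_schedule(sc: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    """Fixation end-times covering [0, duration]; exponential durations with
    mean 1/fixation_rate, floored at two sample intervals."""
    min_dur = 2.0 / sc.sample_rate
    ends = []
    t = 0.0
    while t < sc.duration:
        t += max(rng.exponential(1.0 / sc.fixation_rate), min_dur)
        ends.append(min(t, sc.duration))
    return np.array(ends)


def _scanpath_offsets(n_fix: int, task: TaskGeometry) -> np.ndarray:
    """(n_fix, 2) per-fixation (d_azimuth, d_elevation) raster offsets inside
    the text rectangle: left-to-right within a line, top line first."""
    lines = _SCANPATH_LINES if task.angular_height > 0 else 1
    cols = _SCANPATH_COLS if task.angular_width > 0 else 1
    i = np.arange(n_fix)
    colfrac = (i % cols) / (cols - 1) if cols > 1 else np.full(n_fix, 0.5)
    linefrac = ((i // cols) % lines) / (lines - 1) if lines > 1 else np.full(n_fix, 0.5)
    daz = (0.5 - colfrac) * task.angular_width  # +azimuth = wearer's left = line start
    del_ = (0.5 - linefrac) * task.angular_height
    return np.column_stack([daz, del_])


def _emit_samples(
    sc: SimulationScenario,
    eye: str,
    times: np.ndarray,
    v_true: np.ndarray,
    rng: np.random.Generator,
) -> list[GazeSample]:
    """Apply bias + jitter + dropout to a true direction stream and build samples."""
    n = len(times)
    bias_phi = (
        math.radians(sc.bias_direction_deg)
        if sc.bias_direction_deg is not None
        else rng.uniform(0.0, 2.0 * math.pi)
    )
    jitter_mag = rng.normal(0.0, sc.precision_sd, n) if sc.precision_sd > 0 else np.zeros(n)
    jitter_phi = rng.uniform(0.0, 2.0 * math.pi, n)
    loss_draw = rng.random(n)

    surface = sc.resolved_surface()
    cre = cre_position(sc.frame, surface, eye)
    pupil = cre + PUPIL_OFFSET_MM * v_true  # physical pupil rides the true axis

    v_meas = v_true
    if sc.accuracy_bias > 0:
        v_meas = _perturb(v_meas, np.full(n, sc.accuracy_bias), np.full(n, bias_phi))
    if sc.precision_sd > 0:
        v_meas = _perturb(v_meas, jitter_mag, jitter_phi)

    diam = sc.resolved_pupil_diameter()
    valid = loss_draw >= sc.data_loss_p
    return [
        GazeSample(
            t=float(times[k]),
            eye=eye,
            pupil_pos=pupil[k],
            gaze_dir=v_meas[k],
            pupil_diameter=diam if valid[k] else math.nan,
            valid=bool(valid[k]),
        )
        for k in range(n)
    ]


def simulate_with_truth(sc: SimulationScenario) -> tuple[Recording, pd.DataFrame]:
    """Generate a recording plus its truth table.

    The truth table has one row per fixation x eye with the true head/eye
    target angles and the true (noise-free) lens intersection in
    fitting-cross coordinates.
    """
    rng = np.random.default_rng(sc.seed)
    n = int(round(sc.duration * sc.sample_rate))
    times = np.arange(n) / sc.sample_rate

    ends = _fixation_schedule(sc, rng)
    starts = np.concatenate([[0.0], ends[:-1]])
    fix_idx = np.searchsorted(ends, times, side="right").clip(max=len(ends) - 1)
    offsets = _scanpath_offsets(len(ends), sc.task)

    surface = sc.resolved_surface()
    d_mm = sc.task.target_distance * 1000.0
    cyclops = np.array(
        [0.0, sc.frame.pupil_height, surface.vertex_z - sc.frame.cre_to_lens]
    )
    # per-fixation target points in the headset frame
    dirs = np.array(
        [
            direction_from_angles(sc.task.azimuth_offset + daz, sc.task.elevation_deg + del_)
            for daz, del_ in offsets
        ]
    )
    targets = cyclops + d_mm * dirs

    rec = Recording(
        subject_id=sc.subject_id,
        condition_id=sc.condition_id or sc.task.name,
        sample_rate=sc.sample_rate,
        duration=sc.duration,
    )
    truth_rows = []
    for eye in EYES:
        cre = cre_position(sc.frame, surface, eye)
        fc = sc.frame.fitting_cross(eye)
        v_fix = targets - cre
        v_fix /= np.linalg.norm(v_fix, axis=1, keepdims=True)
        v_true = v_fix[fix_idx]
        rec.samples[eye] = _emit_samples(sc, eye, times, v_true, rng)
        for j in range(len(ends)):
            hit = intersect_gaze_with_surface(cre, v_fix[j], surface)
            az = math.degrees(math.atan2(v_fix[j][0], v_fix[j][2]))
            el = math.degrees(math.asin(np.clip(v_fix[j][1], -1, 1)))
            truth_rows.append(
                {
                    "fixation": j,
                    "eye": eye,
                    "t_start": starts[j],
                    "t_end": ends[j],
                    "azimuth_deg": az,
                    "elevation_deg": el,
                    "x_true": hit[0] - fc[0],
                    "y_true": hit[1] - fc[1],
                }
            )
    truth = pd.DataFrame(truth_rows)
    return rec, truth


def simulate_recording(sc: SimulationScenario) -> Recording:
    """Generate a synthetic binocular recording (see :func:`simulate_with_truth`)."""
    rec, _ = simulate_with_truth(sc)
    return rec


def truth_spans(truth: pd.DataFrame, eye: str) -> list[tuple[float, float]]:
    """Fixation (t_start, t_end) spans for one eye from a truth table."""
    g = truth[truth["eye"] == eye].sort_values("fixation")
    return list(zip(g["t_start"], g["t_end"]))


@dataclass(frozen=True)
class PinholeTruth:
    """Ground truth of a pinhole scenario: the pinhole's lens coordinates
    (fitting-cross frame, right eye) and the simulated fixation spans."""

    lens_point: LensPoint
    spans: tuple[tuple[float, float], ...]


def _surface_z_at(surface: LensSurfaceModel, x: float, y: float) -> float:
    if surface.kind == "plane":
        assert surface.plane_z is not None
        return surface.plane_z
    assert surface.center is not None and surface.radius is not None
    cx, cy, cz = surface.center
    r2 = surface.radius**2 - (x - cx) ** 2 - (y - cy) ** 2
    if r2 <= 0:
        raise ValueError("pinhole position lies off the spherical surface")
    return cz - math.sqrt(r2)


def simulate_pinhole_check(
    pinhole_pos: Sequence[float], sc: SimulationScenario
) -> tuple[Recording, PinholeTruth]:
    """Pinhole validity-check scenario (right eye only).

    Every true sight line passes through the pinhole point, given in mm in
    the right-eye fitting-cross frame; noise and dropout are applied exactly
    as in :func:`simulate_recording`.
    """
    rng = np.random.default_rng(sc.seed)
    n = int(round(sc.duration * sc.sample_rate))
    times = np.arange(n) / sc.sample_rate

    ends = _fixation_schedule(sc, rng)
    starts = np.concatenate([[0.0], ends[:-1]])

    surface = sc.resolved_surface()
    fc = sc.frame.fitting_cross("right")
    px, py = float(pinhole_pos[0]) + fc[0], float(pinhole_pos[1]) + fc[1]
    pin3d = np.array([px, py, _surface_z_at(surface, px, py)])
    cre = cre_position(sc.frame, surface, "right")
    v = pin3d - cre
    v /= np.linalg.norm(v)
    v_true = np.tile(v, (n, 1))

    rec = Recording(
        subject_id=sc.subject_id,
        condition_id=sc.condition_id or "pinhole",
        sample_rate=sc.sample_rate,
        duration=sc.duration,
    )
    rec.samples["right"] = _emit_samples(sc, "right", times, v_true, rng)
    truth = PinholeTruth(
        lens_point=to_fitting_cross_frame(pin3d, sc.frame, "right"),
        spans=tuple(zip(starts, ends)),
    )
    return rec, truth


def cohort_scenarios(
    base: SimulationScenario, n_subjects: int, seed: int | None = None
) -> list[SimulationScenario]:
    """Spawn per-subject scenarios with independent child seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(base.seed if seed is None else seed)
    children = ss.spawn(n_subjects)
    return [
        replace(base, seed=int(child.generate_state(1)[0]), subject_id=f"S{i + 1:02d}")
        for i, child in enumerate(children)
    ]
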