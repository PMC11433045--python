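"""Velocity-threshold (I-VT) fixation classification.

Consecutive valid samples whose inter-sample angular velocity stays below a
threshold form one fixation run; invalid samples and timing gaps terminate the
current run; runs shorter than a minimum duration are discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lens_geometry import EYES
from .recordings_io import GazeSample, Recording

DEFAULT_VELOCITY_THRESHOLD_DEG_S = 30.0
DEFAULT_MIN_DURATION_S = 0.06

#: a gap longer than this many nominal sample intervals breaks a fixation run
GAP_FACTOR = 1.5


@dataclass(frozen=True)
class FixationEvent:
    """A classified fixation: time span plus representative gaze geometry."""

    t_start: float
    t_end: float
    mean_gaze_dir: np.ndarray
    mean_pupil_pos: np.ndarray
    eye: str
    n_samples: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two unit vectors, degrees."""
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _finish_run(run: list[GazeSample]) -> FixationEvent:
    dirs = np.mean([s.gaze_dir for s in run], axis=0)
    norm = np.linalg.norm(dirs)
    if norm < 1e-12:
        raise ValueError("degenerate fixation: mean gaze direction is null")
    return FixationEvent(
        t_start=run[0].t,
        t_end=run[-1].t,
        mean_gaze_dir=dirs / norm,
        mean_pupil_pos=np.mean([s.pupil_pos for s in run], axis=0),
        eye=run[0].eye,
        n_samples=len(run),
    )


def classify_fixations(
    rec: Recording,
    eye: str,
    velocity_threshold: float = DEFAULT_VELOCITY_THRESHOLD_DEG_S,
    min_duration: float = DEFAULT_MIN_DURATION_S,
) -> list[FixationEvent]:
    """I-VT classification of one eye's sample stream into fixation events.

    Angular velocity between consecutive valid samples below
    ``velocity_threshold`` (deg/s) keeps the run alive; a velocity at or above
    the threshold, an invalid sample, or a timing gap larger than
    ``GAP_FACTOR`` sample intervals closes it.  Runs with
    ``duration < min_duration`` are discarded.
    """
    if eye not in EYES:
        raise ValueError(f"unknown eye label {eye!r}")
    valid = rec.valid_samples(eye)
    if len(valid) < 2:
        warnings.warn(f"{rec.subject_id}/{eye}: fewer than 2 valid samples", stacklevel=2)
        return []

    max_gap = GAP_FACTOR / rec.sample_rate
    events: list[FixationEvent] = []
    run: list[GazeSample] = [valid[0]]

    def close() -> None:
        # 1 ns slack so spans of exactly min_duration survive float jitter
        if len(run) >= 2 and (run[-1].t - run[0].t) >= min_duration - 1e-9:
            events.append(_finish_run(run))

    for prev, cur in zip(valid, valid[1:]):
        dt = cur.t - prev.t
        if dt <= 0:
            raise ValueError(f"non-increasing timestamps for eye {eye!r} at t={cur.t}")
        gap = dt > max_gap
        vel = angle_between_deg(prev.gaze_dir, cur.gaze_dir) / dt
        if gap or vel >= velocity_threshold:
            close()
            run = [cur]
        else:
            run.append(cur)
    close()
    return events


def fixations_from_spans(
    rec: Recording, eye: str, spans: Sequence[tuple[float, float]]
) -> list[FixationEvent]:
    """Build fixation events from known time spans (e.g. a simulator's truth
    table or a device-classified fixation export) by averaging the valid
    samples within each closed span.  Spans with fewer than 2 valid samples
    are skipped.
    """
    if eye not in EYES:
        raise ValueError(f"unknown eye label {eye!r}")
    valid = rec.valid_samples(eye)
    events = []
    for t0, t1 in spans:
        run = [s for s in valid if t0 <= s.t <= t1]
        if len(run) >= 2:
            events.append(_finish_run(run))
    return events


def fixation_table(fixations: Sequence[FixationEvent], subject: str = "", condition: str = ""):
    """Fixation events as a DataFrame matching the CSV export schema."""
    import pandas as pd

    rows = [
        {
            "subject": subject,
            "condition": condition,
            "eye": f.eye,
            "t_start": f.t_start,
            "t_end": f.t_end,
            "duration": f.duration,
            "gx": f.mean_gaze_dir[0],
            "gy": f.mean_gaze_dir[1],
            "gz": f.mean_gaze_dir[2],
            "px": f.mean_pupil_pos[0],
            "py": f.mean_pupil_pos[1],
            "pz": f.mean_pupil_pos[2],
        }
        for f in fixations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "condition", "eye", "t_start", "t_end", "duration",
            "gx", "gy", "gz", "px", "py", "pz",
        ],
    )
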