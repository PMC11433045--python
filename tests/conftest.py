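from __future__ import annotations

import numpy as np
import pytest

from lensuse.lens_geometry import FrameGeometry, LensSurfaceModel
from lensuse.recordings_io import GazeSample, Recording


@pytest.fixture
def frame62() -> FrameGeometry:
    """Default study-like frame: ipd 62 mm, fitting crosses on the primary axes."""
    return FrameGeometry(ipd=62.0)


@pytest.fixture
def plane_surface(frame62) -> LensSurfaceModel:
    """Lens back-surface plane with the CRE plane at z = 0."""
    return LensSurfaceModel.plane(frame62.cre_to_lens)


def make_samples(
    eye: str,
    directions,
    rate: float = 50.0,
    t0: float = 0.0,
    pupil_pos=(0.0, 0.0, 0.0),
    valid=None,
) -> list[GazeSample]:
    """Build a uniformly sampled stream of gaze samples from raw directions."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    n = len(directions)
    if valid is None:
        valid = [True] * n
    return [
        GazeSample(
            t=t0 + k / rate,
            eye=eye,
            pupil_pos=np.asarray(pupil_pos, dtype=float),
            gaze_dir=directions[k],
            pupil_diameter=3.5,
            valid=bool(valid[k]),
        )
        for k in range(n)
    ]


def make_recording(
    samples_by_eye: dict[str, list[GazeSample]],
    rate: float = 50.0,
    duration: float | None = None,
    subject: str = "sub",
    condition: str = "cond",
) -> Recording:
    if duration is None:
        t_max = max((s.t for ss in samples_by_eye.values() for s in ss), default=0.0)
        duration = t_max + 1.0 / rate
    rec = Recording(
        subject_id=subject, condition_id=condition, sample_rate=rate, duration=duration
    )
    for eye, ss in samples_by_eye.items():
        rec.samples[eye] = list(ss)
    return rec
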