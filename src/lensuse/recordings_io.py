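"""Reading/writing gaze recordings and configuration files, plus recording QC.

Two on-disk dialects are supported:

* ``native_tsv`` — tab-separated, one sample per row, mandatory header with
  columns ``t  eye  px py pz  gx gy gz  pupil_mm  valid``.  Millimetres and
  seconds throughout.
* ``tobii_jsonl`` — JSON-lines in the style of a wearable glasses export:
  each line carries ``timestamp`` plus per-eye records ``eyeleft`` /
  ``eyeright`` with keys ``gazedirection``, ``pupilposition`` (3-arrays) and
  ``pupildiameter``.  Absent keys yield an invalid sample, never a dropped one.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .lens_geometry import EYES, FrameGeometry

_NATIVE_COLUMNS = ["t", "eye", "px", "py", "pz", "gx", "gy", "gz", "pupil_mm", "valid"]


class RecordingIOError(ValueError):
    """Base class for recording I/O failures."""


class ConfigurationError(RecordingIOError):
    """Unknown dialect or malformed configuration file."""


class EmptyRecordingError(RecordingIOError):
    """A recording with no valid samples at all."""


class UndefinedQCError(RecordingIOError):
    """QC statistic undefined (e.g. zero duration)."""


@dataclass
class GazeSample:
    """One eye-tracker sample.

    ``gaze_dir`` is renormalized to unit length on construction whenever the
    sample is valid; a valid sample whose direction is degenerate (zero or
    non-finite) is demoted to invalid.
    """

    t: float
    eye: str
    pupil_pos: np.ndarray
    gaze_dir: np.ndarray
    pupil_diameter: float
    valid: bool

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"unknown eye label {self.eye!r}")
        self.pupil_pos = np.asarray(self.pupil_pos, dtype=float).reshape(3)
        self.gaze_dir = np.asarray(self.gaze_dir, dtype=float).reshape(3)
        self.pupil_diameter = float(self.pupil_diameter)
        if self.valid:
            norm = float(np.linalg.norm(self.gaze_dir))
            if not np.isfinite(norm) or norm < 1e-12 or not np.all(np.isfinite(self.pupil_pos)):
                self.valid = False
            else:
                self.gaze_dir = self.gaze_dir / norm
            if self.valid and not self.pupil_diameter > 0:
                self.valid = False


@dataclass
class Recording:
    """A binocular gaze recording: per-eye ordered sample streams."""

    subject_id: str
    condition_id: str
    sample_rate: float
    duration: float
    samples: dict[str, list[GazeSample]] = field(default_factory=lambda: {e: [] for e in EYES})

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        for eye in EYES:
            self.samples.setdefault(eye, [])

    def valid_samples(self, eye: str) -> list[GazeSample]:
        return [s for s in self.samples[eye] if s.valid]

    def expected_samples(self, eye: str) -> int:
        return int(round(self.duration * self.sample_rate))


def _native_row_to_sample(row: Sequence[str]) -> GazeSample:
    t = float(row[0])
    eye = row[1].strip().lower()
    try:
        pos = [float(row[i]) for i in (2, 3, 4)]
        gaze = [float(row[i]) for i in (5, 6, 7)]
        diam = float(row[8])
        valid = row[9].strip().lower() in ("1", "true", "t", "yes")
    except (ValueError, IndexError):
        pos, gaze, diam, valid = [math.nan] * 3, [math.nan] * 3, math.nan, False
    return GazeSample(t=t, eye=eye, pupil_pos=pos, gaze_dir=gaze, pupil_diameter=diam, valid=valid)


def _read_native_tsv(path: Path) -> list[GazeSample]:
    lines = path.read_text().splitlines()
    if not lines:
        raise EmptyRecordingError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip() for h in header] != _NATIVE_COLUMNS:
        raise ConfigurationError(
            f"{path}: expected native TSV header {_NATIVE_COLUMNS}, got {header}"
        )
    samples = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = line.split("\t")
        try:
            samples.append(_native_row_to_sample(row))
        except (ValueError, IndexError):
            # row too malformed even for t/eye: cannot anchor it in the stream
            warnings.warn(f"{path}: dropping unparseable row {line!r}", stacklevel=2)
    return samples


def _tobii_eye_sample(t: float, eye: str, rec: object) -> GazeSample:
    if not isinstance(rec, dict):
        rec = {}
    gaze = rec.get("gazedirection")
    pos = rec.get("pupilposition")
    diam = rec.get("pupildiameter")
    ok = (
        isinstance(gaze, (list, tuple)) and len(gaze) == 3
        and isinstance(pos, (list, tuple)) and len(pos) == 3
        and isinstance(diam, (int, float))
    )
    if not ok:
        return GazeSample(t, eye, [math.nan] * 3, [math.nan] * 3, math.nan, False)
    return GazeSample(t, eye, list(pos), list(gaze), float(diam), True)


def _read_tobii_jsonl(path: Path) -> list[GazeSample]:
    samples = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            t = float(obj["timestamp"])
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            warnings.warn(f"{path}: dropping unparseable JSON line", stacklevel=2)
            continue
        for eye, key in (("left", "eyeleft"), ("right", "eyeright")):
            if key in obj:
                samples.append(_tobii_eye_sample(t, eye, obj[key]))
    return samples


def read_recording(
    path: str | Path,
    dialect: str = "native_tsv",
    subject_id: str = "",
    condition_id: str = "",
    sample_rate: float = 50.0,
    duration: float | None = None,
) -> Recording:
    """Read a gaze recording.

    Samples are sorted by time within each eye and gaze directions are
    renormalized; malformed rows are flagged invalid, not dropped.  ``duration``
    defaults to the last timestamp plus one sample interval.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native_tsv":
        samples = _read_native_tsv(path)
    elif dialect == "tobii_jsonl":
        samples = _read_tobii_jsonl(path)
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")

    if not any(s.valid for s in samples):
        raise EmptyRecordingError(f"{path}: no valid samples")

    by_eye: dict[str, list[GazeSample]] = {e: [] for e in EYES}
    for s in samples:
        by_eye[s.eye].append(s)
    for eye in EYES:
        by_eye[eye].sort(key=lambda s: s.t)

    if duration is None:
        t_max = max(s.t for s in samples)
        duration = t_max + 1.0 / sample_rate
    return Recording(
        subject_id=subject_id or path.stem,
        condition_id=condition_id,
        sample_rate=sample_rate,
        duration=float(duration),
        samples=by_eye,
    )


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording in the native TSV dialect (deterministic formatting)."""
    path = Path(path)
    rows = ["\t".join(_NATIVE_COLUMNS)]
    merged = sorted(
        (s for eye in EYES for s in rec.samples[eye]), key=lambda s: (s.t, s.eye)
    )
    for s in merged:
        rows.append(
            "\t".join(
                [
                    f"{s.t:.6f}",
                    s.eye,
                    f"{s.pupil_pos[0]:.6f}",
                    f"{s.pupil_pos[1]:.6f}",
                    f"{s.pupil_pos[2]:.6f}",
                    f"{s.gaze_dir[0]:.8f}",
                    f"{s.gaze_dir[1]:.8f}",
                    f"{s.gaze_dir[2]:.8f}",
                    f"{s.pupil_diameter:.6f}",
                    "1" if s.valid else "0",
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")
    return path


def data_loss_fraction(rec: Recording, eye: str) -> float:
    """Fraction of expected samples that are missing or invalid, in [0, 1].

    Expected count is the nominal grid ``round(duration * sample_rate)``;
    both invalid-flagged and absent samples count as loss.
    """
    if eye not in EYES:
        raise ValueError(f"unknown eye label {eye!r}")
    expected = rec.expected_samples(eye)
    if expected <= 0:
        raise UndefinedQCError("data loss undefined for zero-duration recording")
    n_valid = len(rec.valid_samples(eye))
    if n_valid > expected:
        warnings.warn(
            f"{rec.subject_id}/{eye}: {n_valid} valid samples exceed the expected "
            f"{expected} (duplicate timestamps?)",
            stacklevel=2,
        )
    return float(min(max((expected - n_valid) / expected, 0.0), 1.0))


def qc_filter(
    recs: Iterable[Recording],
    max_loss: float = 0.10,
    eyes: Sequence[str] = EYES,
) -> tuple[list[Recording], list[Recording]]:
    """Partition recordings into (kept, excluded) by per-eye data loss.

    A recording is kept iff ``data_loss_fraction < max_loss`` (strict) for
    every analyzed eye.
    """
    if not 0 < max_loss <= 1:
        raise ValueError("max_loss must be in (0, 1]")
    kept, excluded = [], []
    for rec in recs:
        if all(data_loss_fraction(rec, eye) < max_loss for eye in eyes):
            kept.append(rec)
        else:
            excluded.append(rec)
    return kept, excluded


# ---------------------------------------------------------------------------
# configuration files (YAML or JSON, unit-suffixed keys)
# ---------------------------------------------------------------------------

def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return data


def load_frame_geometry(path: str | Path) -> FrameGeometry:
    """Load a subject frame/fitting-parameter file (YAML or JSON).

    Recognized keys: ``ipd_mm`` (required), ``pupil_height_mm``, ``bvd_mm``,
    ``cre_to_lens_mm``, ``fitting_cross_right_mm`` / ``fitting_cross_left_mm``
    (2-arrays), ``pantoscopic_tilt_deg``, ``wrap_angle_deg``.
    """
    path = Path(path)
    data = _load_mapping(path)
    if "ipd_mm" not in data:
        raise ConfigurationError(f"{path}: missing required key ipd_mm")
    kwargs: dict = {"ipd": float(data["ipd_mm"])}
    for key, attr in [
        ("pupil_height_mm", "pupil_height"),
        ("bvd_mm", "bvd"),
        ("cre_to_lens_mm", "cre_to_lens"),
        ("pantoscopic_tilt_deg", "pantoscopic_tilt"),
        ("wrap_angle_deg", "wrap_angle"),
    ]:
        if key in data:
            kwargs[attr] = float(data[key])
    for key, attr in [
        ("fitting_cross_right_mm", "fitting_cross_right"),
        ("fitting_cross_left_mm", "fitting_cross_left"),
    ]:
        if key in data:
            kwargs[attr] = tuple(float(v) for v in data[key])
    return FrameGeometry(**kwargs)


def load_task_geometry(path: str | Path):
    """Load a task geometry file (YAML or JSON) into a :class:`TaskGeometry`.

    Recognized keys: ``name``, ``target_distance_m`` (required),
    ``azimuth_offset_deg``, ``elevation_offset_deg`` *or* ``target_height_m``,
    ``angular_width_deg``, ``angular_height_deg``, ``mean_pupil_diameter_mm``.
    """
    from .task_zones import TaskGeometry

    path = Path(path)
    data = _load_mapping(path)
    if "target_distance_m" not in data:
        raise ConfigurationError(f"{path}: missing required key target_distance_m")
    kwargs: dict = {
        "name": str(data.get("name", path.stem)),
        "target_distance": float(data["target_distance_m"]),
    }
    for key, attr in [
        ("azimuth_offset_deg", "azimuth_offset"),
        ("elevation_offset_deg", "elevation_offset"),
        ("target_height_m", "target_height"),
        ("angular_width_deg", "angular_width"),
        ("angular_height_deg", "angular_height"),
        ("mean_pupil_diameter_mm", "mean_pupil_diameter"),
    ]:
        if key in data:
            kwargs[attr] = float(data[key])
    return TaskGeometry(**kwargs)
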