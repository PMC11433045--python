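"""Region-of-use summaries and concordance with theoretical zones."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lens_geometry import LensPoint
from .task_zones import TheoreticalZone


class NoRegionError(ValueError):
    """Region of use requested for an empty point set."""


@dataclass(frozen=True)
class RegionOfUse:
    """Center of mass (cx, cy) of the fixation pierce points relative to the
    fitting cross, with spread and provenance."""

    subject: str
    condition: str
    eye: str
    cx: float
    cy: float
    sd_x: float
    sd_y: float
    n_fixations: int
    points: tuple[LensPoint, ...] = field(repr=False, default=())

    @property
    def cx_nasal(self) -> float:
        return self.cx if self.eye == "right" else -self.cx


@dataclass(frozen=True)
class ConcordanceResult:
    """Per subject x eye x condition containment counts."""

    subject: str
    eye: str
    condition: str
    n_inside: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or not 0 <= self.n_inside <= self.n_total:
            raise ValueError("need 0 <= n_inside <= n_total")

    @property
    def fraction_inside(self) -> float:
        if self.n_total == 0:
            raise ZeroDivisionError("no fixations in concordance result")
        return self.n_inside / self.n_total

    @property
    def all_inside(self) -> bool:
        return self.n_inside == self.n_total


def region_of_use(
    points: Sequence[LensPoint],
    weights: Sequence[float] | None = None,
    subject: str = "",
    condition: str = "",
) -> RegionOfUse:
    """Center of mass of lens points: unweighted arithmetic mean by default,
    duration-weighted mean when ``weights`` is supplied.  Sample standard
    deviations (unweighted, ddof=1; 0 for a single point) are reported
    alongside.
    """
    points = list(points)
    if not points:
        raise NoRegionError("region of use undefined for an empty point set")
    eyes = {p.eye for p in points}
    if len(eyes) != 1:
        raise ValueError(f"points mix eyes: {sorted(eyes)}")
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != xs.shape:
            raise ValueError("weights must match points one-to-one")
        if not np.all(w >= 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        cx = float(np.average(xs, weights=w))
        cy = float(np.average(ys, weights=w))
    else:
        cx = float(xs.mean())
        cy = float(ys.mean())
    n = len(points)
    sd_x = float(xs.std(ddof=1)) if n > 1 else 0.0
    sd_y = float(ys.std(ddof=1)) if n > 1 else 0.0
    return RegionOfUse(
        subject=subject,
        condition=condition,
        eye=points[0].eye,
        cx=cx,
        cy=cy,
        sd_x=sd_x,
        sd_y=sd_y,
        n_fixations=n,
        points=tuple(points),
    )


def point_in_zone(p: LensPoint, z: TheoreticalZone) -> bool:
    """Closed-boundary containment: edge points count as inside."""
    if p.eye != z.eye:
        raise ValueError(f"eye mismatch: point is {p.eye!r}, zone is {z.eye!r}")
    return z.x_min <= p.x <= z.x_max and z.y_min <= p.y <= z.y_max


def concordance(
    points: Sequence[LensPoint],
    zone: TheoreticalZone,
    subject: str = "",
) -> ConcordanceResult:
    """Count how many projected fixations fall inside the theoretical zone."""
    inside = sum(point_in_zone(p, zone) for p in points)
    return ConcordanceResult(
        subject=subject,
        eye=zone.eye,
        condition=zone.condition,
        n_inside=int(inside),
        n_total=len(points),
    )


def pooled_concordance(results: Iterable[ConcordanceResult]) -> float:
    """Fixation-pooled concordance percentage: sum of inside counts over sum
    of totals, x100."""
    results = list(results)
    if not results:
        raise ValueError("no concordance results")
    total = sum(r.n_total for r in results)
    if total == 0:
        raise ZeroDivisionError("zero total fixations: pooled concordance undefined")
    return 100.0 * sum(r.n_inside for r in results) / total


def mean_subject_fraction(results: Iterable[ConcordanceResult]) -> float:
    """Subject-averaged concordance percentage: mean of per-result fractions,
    x100.  Companion estimator to :func:`pooled_concordance`."""
    results = list(results)
    if not results:
        raise ValueError("no concordance results")
    return 100.0 * float(np.mean([r.fraction_inside for r in results]))


def strict_subject_percentage(results: Iterable[ConcordanceResult]) -> float:
    """Percentage of subjects with *all* fixations inside the zone."""
    results = list(results)
    if not results:
        raise ValueError("no concordance results")
    return 100.0 * sum(r.all_inside for r in results) / len(results)


def condition_summary(regions: Iterable[RegionOfUse]) -> pd.DataFrame:
    """Mean +/- sample SD of (cx, cy) per condition x eye, across subjects.

    Groups with a single region report SD 0 and ``single_subject=True``.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("no regions to summarize")
    df = pd.DataFrame(
        {
            "condition": [r.condition for r in regions],
            "eye": [r.eye for r in regions],
            "cx": [r.cx for r in regions],
            "cy": [r.cy for r in regions],
        }
    )
    rows = []
    for (condition, eye), g in df.groupby(["condition", "eye"], sort=True):
        n = len(g)
        rows.append(
            {
                "condition": condition,
                "eye": eye,
                "n": n,
                "cx_mean": g["cx"].mean(),
                "cx_sd": g["cx"].std(ddof=1) if n > 1 else 0.0,
                "cy_mean": g["cy"].mean(),
                "cy_sd": g["cy"].std(ddof=1) if n > 1 else 0.0,
                "single_subject": n == 1,
            }
        )
    return pd.DataFrame(rows)


def concordance_table(results: Iterable[ConcordanceResult]) -> pd.DataFrame:
    """Per-result concordance rows as a DataFrame (CSV export schema)."""
    rows = [
        {
            "subject": r.subject,
            "condition": r.condition,
            "eye": r.eye,
            "n_inside": r.n_inside,
            "n_total": r.n_total,
            "fraction_inside": r.fraction_inside if r.n_total else float("nan"),
            "all_inside": r.all_inside,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["subject", "condition", "eye", "n_inside", "n_total", "fraction_inside", "all_inside"],
    )
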