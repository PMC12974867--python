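"""Tie-point-constrained piecewise-linear age models.

Tie points are expert-assigned (ring sample number, calendar year) anchors
reconciled across trees; they are *inputs*, not estimates.  Between tie
points growth rate is constant, so ages come from linear interpolation on
sample number.  A growth hiatus appears as one sample number carrying two
years (the younger listed first): the mapped year drops discontinuously by
the hiatus duration at that ring, and no sample is dated inside the gap.

Validation compares model years for dated samples with the 1-sigma HPD
intervals of their calibrated radiocarbon dates; an acceptable model must
pass through every unflagged interval.  Stratigraphic age inversions —
pairs of dates whose calibrated ranges are disjoint and in the wrong
ring order — are detected so they can be flagged as probable labelling
errors and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .calibration import CalibratedDate
from .types import DatedSeries, IsotopeSeries, ValidationError

__all__ = [
    "TiePoint",
    "Hiatus",
    "AgeModel",
    "ValidationReport",
    "fit_age_model",
    "assign_ages",
    "validate_model",
    "detect_inversions",
]


@dataclass(frozen=True)
class TiePoint:
    """One (ring, calendar year) anchor for a tree's chronology."""

    tree_id: str
    sample_number: int
    year_ce: float


@dataclass(frozen=True)
class Hiatus:
    """A growth stop at one ring: the tree added no rings for
    ``year_resume − year_stop`` years.  Moving inward across
    ``sample_number`` the mapped year falls from ``year_resume`` (growth
    restart, younger) to ``year_stop`` (growth arrest, older)."""

    sample_number: int
    year_stop: float
    year_resume: float

    @property
    def duration(self) -> float:
        return self.year_resume - self.year_stop


@dataclass
class AgeModel:
    """Piecewise-linear sample-number → calendar-year map for one tree."""

    tree_id: str
    knots: List[TiePoint]
    hiatus: Optional[Hiatus] = None

    @property
    def domain(self) -> Tuple[int, int]:
        nums = [k.sample_number for k in self.knots]
        return min(nums), max(nums)

    def year_at(self, sample_numbers, extrapolate: str = "error"):
        """Calendar year(s) CE for (possibly fractional) sample numbers.

        A sample exactly at a hiatus ring receives the older age (growth
        arrest year), consistent with the inward segment it terminates.
        ``extrapolate``: ``"error"`` (default) rejects queries outside the
        tie-point domain; ``"clamp"`` returns the terminal knot years.
        """
        s = np.atleast_1d(np.asarray(sample_numbers, dtype=float))
        lo, hi = self.domain
        outside = (s < lo) | (s > hi)
        if outside.any():
            if extrapolate == "error":
                raise ValidationError(
                    f"{self.tree_id}: sample {s[outside][0]:g} outside age "
                    f"model domain [{lo}, {hi}]"
                )
            if extrapolate == "clamp":
                s = np.clip(s, lo, hi)
            else:
                raise ValidationError(f"unknown extrapolate mode {extrapolate!r}")
        xs = np.array([k.sample_number for k in self.knots], dtype=float)
        ys = np.array([k.year_ce for k in self.knots], dtype=float)
        # np.interp needs ascending x; years then come out descending.
        # At a hiatus two knots share x: perturb the younger (first) copy
        # infinitesimally left so interp picks the older year AT the ring.
        if self.hiatus is not None:
            dup = np.flatnonzero(np.diff(xs) == 0)
            for i in dup:
                xs = xs.copy()
                xs[i] -= 1e-9
        out = np.interp(s, xs, ys)
        if np.isscalar(sample_numbers) or np.ndim(sample_numbers) == 0:
            return float(out[0])
        return out


def fit_age_model(tie_points: Sequence[TiePoint]) -> AgeModel:
    """Build a piecewise-linear age model through a tree's tie points.

    Tie points may arrive in any order; they are sorted by sample number
    (younger years first at equal sample number, i.e. the hiatus pair keeps
    the larger year listed first).  At most one hiatus — a duplicated
    sample number with two distinct years — is supported, matching how
    such gaps are recorded in practice.

    Raises
    ------
    ValidationError
        Fewer than two points, mixed tree ids, a year that *increases*
        with ring depth without a hiatus flag, or more than one duplicated
        sample number.
    """
    pts = list(tie_points)
    if len(pts) < 2:
        raise ValidationError("need at least 2 tie points")
    tree_ids = {p.tree_id for p in pts}
    if len(tree_ids) != 1:
        raise ValidationError(f"tie points mix trees: {sorted(tree_ids)}")
    tree_id = pts[0].tree_id
    pts.sort(key=lambda p: (p.sample_number, -p.year_ce))
    hiatus = None
    for a, b in zip(pts, pts[1:]):
        if b.sample_number == a.sample_number:
            if a.year_ce == b.year_ce:
                raise ValidationError(
                    f"{tree_id}: duplicate tie point at sample "
                    f"{a.sample_number}"
                )
            if hiatus is not None:
                raise ValidationError(
                    f"{tree_id}: more than one hiatus pair (samples "
                    f"{hiatus.sample_number} and {a.sample_number})"
                )
            # larger year first after the sort: a is resume, b is stop
            hiatus = Hiatus(
                sample_number=a.sample_number,
                year_stop=b.year_ce,
                year_resume=a.year_ce,
            )
        elif b.year_ce >= a.year_ce:
            raise ValidationError(
                f"{tree_id}: year does not decrease from sample "
                f"{a.sample_number} ({a.year_ce} CE) to sample "
                f"{b.sample_number} ({b.year_ce} CE); an inversion must be "
                "declared as a hiatus pair at one sample number"
            )
    return AgeModel(tree_id=tree_id, knots=pts, hiatus=hiatus)


def assign_ages(model: AgeModel, series: IsotopeSeries,
                extrapolate: str = "error") -> DatedSeries:
    """Date every isotope sample through the age model.

    Returns a :class:`DatedSeries` sorted ascending by year.  Every sample
    must fall inside the model domain unless ``extrapolate="clamp"``.
    """
    years = model.year_at(series.sample_numbers, extrapolate=extrapolate)
    return DatedSeries(tree_id=series.tree_id, years=years,
                       values=series.delta13c.copy())


@dataclass
class ValidationReport:
    """Per-date agreement between an age model and calibrated intervals."""

    tree_id: str
    records: List[dict] = field(default_factory=list)

    @property
    def n_inside(self) -> int:
        return sum(1 for r in self.records
                   if r["inside_1sigma"] and not r["flagged_outlier"])

    @property
    def n_checked(self) -> int:
        return sum(1 for r in self.records if not r["flagged_outlier"])

    @property
    def fraction_inside(self) -> float:
        n = self.n_checked
        return self.n_inside / n if n else float("nan")


def validate_model(model: AgeModel, cal_dates: Sequence[CalibratedDate],
                   extrapolate: str = "clamp") -> ValidationReport:
    """Check that model years fall inside each date's HPD intervals.

    Flagged outlier dates are reported (with their distances) but excluded
    from the summary counts.  Dates outside the tie-point domain are
    clamped to the terminal knots by default so end-of-core dates still
    get a sensible comparison.
    """
    if not cal_dates:
        raise ValidationError("no calibrated dates supplied")
    report = ValidationReport(tree_id=model.tree_id)
    for cd in cal_dates:
        y = model.year_at(cd.sample_number, extrapolate=extrapolate)
        inside = cd.contains(y)
        report.records.append({
            "tree_id": cd.tree_id,
            "sample_number": cd.sample_number,
            "model_year_ce": y,
            "inside_1sigma": inside,
            "distance_to_nearest_interval": 0.0 if inside else cd.distance(y),
            "flagged_outlier": cd.flagged_outlier,
        })
    return report


def detect_inversions(cal_dates: Sequence[CalibratedDate]
                      ) -> List[Tuple[CalibratedDate, CalibratedDate]]:
    """Find stratigraphically impossible date pairs.

    Dates are ordered by sample number (shallower/younger ring first).  A
    pair is flagged when the shallower ring's entire 1-sigma calendar range
    is *older* than the deeper ring's entire range — disjoint intervals in
    reversed order, the signature of a mislabelled sample.  Overlapping
    ranges are never flagged.
    """
    dates = sorted(cal_dates, key=lambda d: d.sample_number)
    flagged = []
    for i, a in enumerate(dates):
        if not a.hpd_intervals:
            continue
        a_max = max(b for _, b in a.hpd_intervals)
        for b_ in dates[i + 1:]:
            if not b_.hpd_intervals:
                continue
            b_min = min(s for s, _ in b_.hpd_intervals)
            # shallower ring a should be younger (larger CE); flag if its
            # whole range predates the deeper ring's whole range
            if a_max < b_min:
                flagged.append((a, b_))
    return flagged
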