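"""Core domain types for tree-ring isotope proxy pipelines.

The pipeline's vocabulary:

* :class:`IsotopeSeries` — per-core δ13C measurements indexed by sample
  number counted from the bark (1 = outermost, youngest) inward.
* :class:`RadiocarbonDate` — an AMS measurement on one sample, either a
  conventional radiocarbon age (years BP) or an F14C ratio for the
  post-1950 bomb era.
* :class:`CalibrationCurve` — an IntCal/SHCal-style grid mapping calendar
  age to radiocarbon age (or F14C) with curve uncertainty.
* :class:`AnnualRecord` — any annual (year CE, value) series: atmospheric
  δ13C, CO2, rainfall, or a climate forcing index.
* :class:`DatedSeries` — δ13C values placed on the calendar after age
  modelling.

All user-facing years are CE.  Calibration internals use cal BP with
BP = 1950 − CE; the conversion lives in :func:`ce_to_bp` / :func:`bp_to_ce`
and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "BP_REFERENCE_CE",
    "ce_to_bp",
    "bp_to_ce",
    "IsotopeSeries",
    "RadiocarbonDate",
    "CalibrationCurve",
    "AnnualRecord",
    "DatedSeries",
    "ValidationError",
]

#: Calendar year CE corresponding to 0 BP.
BP_REFERENCE_CE = 1950


def ce_to_bp(year_ce):
    """Convert calendar years CE to cal BP (before 1950)."""
    return BP_REFERENCE_CE - np.asarray(year_ce, dtype=float)


def bp_to_ce(cal_bp):
    """Convert cal BP to calendar years CE."""
    return BP_REFERENCE_CE - np.asarray(cal_bp, dtype=float)


class ValidationError(ValueError):
    """An input violated a domain-type invariant."""


@dataclass
class IsotopeSeries:
    """Ordered per-core δ13C measurements.

    Parameters
    ----------
    tree_id
        Short core label (e.g. ``"DFL"``).
    sample_numbers
        Positive integers, 1 = outermost (bark-side) sample, increasing
        inward toward the pith (older wood).
    delta13c
        Per-mille values on the VPDB scale, one per sample.
    metadata
        Free-form core information (species, coordinates, core length).
    plausible_range
        Inclusive (low, high) window for δ13C plausibility checks.
    """

    tree_id: str
    sample_numbers: np.ndarray
    delta13c: np.ndarray
    metadata: dict = field(default_factory=dict)
    plausible_range: tuple = (-40.0, 0.0)

    def __post_init__(self):
        sn = np.asarray(self.sample_numbers)
        if sn.size and not np.issubdtype(sn.dtype, np.integer):
            as_int = sn.astype(int)
            if not np.array_equal(as_int, sn):
                raise ValidationError(
                    f"{self.tree_id}: sample numbers must be integers"
                )
            sn = as_int
        vals = np.asarray(self.delta13c, dtype=float)
        if sn.shape != vals.shape:
            raise ValidationError(
                f"{self.tree_id}: {sn.size} sample numbers vs {vals.size} values"
            )
        order = np.argsort(sn, kind="stable")
        sn, vals = sn[order], vals[order]
        if sn.size:
            if sn[0] < 1:
                raise ValidationError(
                    f"{self.tree_id}: sample numbers must be >= 1 (row with "
                    f"sample_number={sn[0]})"
                )
            dup = np.flatnonzero(np.diff(sn) == 0)
            if dup.size:
                raise ValidationError(
                    f"{self.tree_id}: duplicate sample_number {sn[dup[0]]}"
                )
        bad = ~np.isfinite(vals)
        if bad.any():
            raise ValidationError(
                f"{self.tree_id}: non-finite δ13C at sample_number "
                f"{sn[bad][0]}"
            )
        lo, hi = self.plausible_range
        out = (vals < lo) | (vals > hi)
        if out.any():
            raise ValidationError(
                f"{self.tree_id}: δ13C {vals[out][0]:g}‰ at sample_number "
                f"{sn[out][0]} outside plausible range [{lo}, {hi}]‰"
            )
        self.sample_numbers = sn
        self.delta13c = vals

    def __len__(self):
        return int(self.sample_numbers.size)

    def __eq__(self, other):
        if not isinstance(other, IsotopeSeries):
            return NotImplemented
        return (
            self.tree_id == other.tree_id
            and np.array_equal(self.sample_numbers, other.sample_numbers)
            and np.array_equal(self.delta13c, other.delta13c)
        )


@dataclass(frozen=True)
class RadiocarbonDate:
    """One AMS radiocarbon measurement keyed to a ring sample.

    ``measurement_type`` is ``"conventional_BP"`` (pre-bomb, years BP) or
    ``"F14C"`` (fraction modern, post-1950 bomb era).  ``flagged_outlier``
    marks dates dismissed as errors (e.g. stratigraphic age inversions);
    they are still calibrated but excluded from age-model validation
    summaries by default.
    """

    tree_id: str
    sample_number: int
    measurement_type: str
    value: float
    sigma: float
    flagged_outlier: bool = False

    def __post_init__(self):
        if self.measurement_type not in ("conventional_BP", "F14C"):
            raise ValidationError(
                f"unknown measurement_type {self.measurement_type!r}"
            )
        if not self.sigma > 0:
            raise ValidationError(
                f"{self.tree_id} sample {self.sample_number}: sigma must be "
                f"> 0, got {self.sigma}"
            )
        if self.measurement_type == "F14C" and not self.value > 0:
            raise ValidationError(
                f"{self.tree_id} sample {self.sample_number}: F14C must be > 0"
            )


@dataclass
class CalibrationCurve:
    """Calibration-curve grid.

    For ``era="pre_bomb"`` the response is conventional radiocarbon age
    (years BP); for ``era="post_bomb_F14C"`` it is F14C.  ``cal_bp`` must be
    strictly monotone; queries outside the grid raise.
    """

    cal_bp: np.ndarray
    c14_value: np.ndarray
    curve_sigma: np.ndarray
    era: str = "pre_bomb"
    name: str = "curve"

    def __post_init__(self):
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_value = np.asarray(self.c14_value, dtype=float)
        self.curve_sigma = np.asarray(self.curve_sigma, dtype=float)
        if self.era not in ("pre_bomb", "post_bomb_F14C"):
            raise ValidationError(f"unknown curve era {self.era!r}")
        if self.cal_bp.size < 2:
            raise ValidationError("calibration curve needs >= 2 grid points")
        d = np.diff(self.cal_bp)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):  # store ascending in cal BP
            self.cal_bp = self.cal_bp[::-1].copy()
            self.c14_value = self.c14_value[::-1].copy()
            self.curve_sigma = self.curve_sigma[::-1].copy()
        else:
            i = int(np.flatnonzero(d * d[0] <= 0)[0])
            raise ValidationError(
                f"calibration curve cal BP axis not monotone near row {i + 1}"
            )
        if (self.curve_sigma < 0).any():
            i = int(np.flatnonzero(self.curve_sigma < 0)[0])
            raise ValidationError(f"negative curve sigma at row {i}")

    @property
    def cal_bp_min(self):
        return float(self.cal_bp[0])

    @property
    def cal_bp_max(self):
        return float(self.cal_bp[-1])

    def _check_domain(self, cal_bp):
        cal_bp = np.asarray(cal_bp, dtype=float)
        if (cal_bp < self.cal_bp[0]).any() or (cal_bp > self.cal_bp[-1]).any():
            raise ValidationError(
                f"calibration query outside curve support "
                f"[{self.cal_bp[0]:g}, {self.cal_bp[-1]:g}] cal BP"
            )
        return cal_bp

    def mu(self, cal_bp):
        """Curve mean (14C age BP or F14C), linearly interpolated."""
        cal_bp = self._check_domain(cal_bp)
        return np.interp(cal_bp, self.cal_bp, self.c14_value)

    def sigma(self, cal_bp):
        """Curve 1-sigma uncertainty, linearly interpolated."""
        cal_bp = self._check_domain(cal_bp)
        return np.interp(cal_bp, self.cal_bp, self.curve_sigma)


@dataclass
class AnnualRecord:
    """Annual (year CE, value) series.

    ``kind`` tags the variable: ``d13c_atm`` (‰), ``co2`` (ppm),
    ``rainfall`` (mm/yr), ``forcing_index`` (unitless) or
    ``instrumental_rain`` (mm/yr).  Years are strictly increasing; for
    records used in corrections gaps larger than ``max_gap`` are rejected.
    """

    KINDS = ("d13c_atm", "co2", "rainfall", "forcing_index", "instrumental_rain")

    years: np.ndarray
    values: np.ndarray
    kind: str = "forcing_index"
    max_gap: Optional[int] = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown AnnualRecord kind {self.kind!r}")
        if self.years.shape != self.values.shape:
            raise ValidationError("years and values differ in length")
        if self.years.size == 0:
            raise ValidationError("empty annual record")
        d = np.diff(self.years)
        if (d <= 0).any():
            i = int(np.flatnonzero(d <= 0)[0])
            raise ValidationError(
                f"years not strictly increasing at row {i + 1} "
                f"(year {self.years[i + 1]})"
            )
        if self.max_gap is not None and d.size and d.max() > self.max_gap:
            i = int(np.argmax(d))
            raise ValidationError(
                f"gap of {d[i]} years after {self.years[i]} exceeds "
                f"max_gap={self.max_gap}"
            )
        if not np.isfinite(self.values).all():
            i = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValidationError(f"non-finite value at year {self.years[i]}")

    def __len__(self):
        return int(self.years.size)

    @property
    def span(self):
        return int(self.years[0]), int(self.years[-1])

    def at(self, years):
        """Value at (possibly fractional) years CE, linearly interpolated.

        Raises outside the record span.
        """
        years = np.asarray(years, dtype=float)
        if (years < self.years[0]).any() or (years > self.years[-1]).any():
            raise ValidationError(
                f"query year outside {self.kind} record span "
                f"{self.span[0]}–{self.span[1]} CE"
            )
        return np.interp(years, self.years.astype(float), self.values)


@dataclass
class DatedSeries:
    """δ13C samples placed on the calendar, sorted ascending by year.

    Years may be fractional (linear age interpolation between tie points).
    """

    tree_id: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValidationError("years and values differ in length")
        order = np.argsort(self.years, kind="stable")
        self.years = self.years[order]
        self.values = self.values[order]

    def __len__(self):
        return int(self.years.size)

    @property
    def span(self):
        return float(self.years[0]), float(self.years[-1])
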