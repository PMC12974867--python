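"""Radiocarbon calibration to calendar-year probability densities.

A measured radiocarbon age ``y ± σ_lab`` is compared with the calibration
curve μ(θ), σ_curve(θ): the likelihood of calendar age θ is Gaussian,

    L(θ) ∝ exp( −(y − μ(θ))² / (2 (σ_lab² + σ_curve²(θ))) ) / √(σ_lab² + σ_curve²(θ))

The posterior over an annual calendar grid assigns each grid year the
likelihood integrated across its one-year bin (Simpson quadrature on the
linearly interpolated curve), normalized to unit total mass.  The same
construction applies on the F14C scale for post-1950 bomb-era dates, where
the non-monotone bomb curve can produce multimodal densities.

Highest-posterior-density (HPD) intervals are built by greedy inclusion of
grid years in order of decreasing probability — the smallest set of years
holding the requested coverage — with contiguous runs merged to intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .types import (
    CalibrationCurve,
    RadiocarbonDate,
    ValidationError,
    bp_to_ce,
    ce_to_bp,
)

__all__ = ["CalibratedDate", "calibrate", "calibrate_postbomb", "hpd"]

# Simpson sub-intervals per one-year grid bin (even, >= 2).
_SIMPSON_K = 8


@dataclass
class CalibratedDate:
    """Posterior probability over calendar years for one radiocarbon date.

    ``density`` is probability *mass* per grid year (sums to 1);
    ``hpd_intervals`` is a sorted list of disjoint ``(start_CE, end_CE)``
    inclusive intervals at the stated ``coverage``.
    """

    tree_id: str
    sample_number: int
    year_ce: np.ndarray
    density: np.ndarray
    coverage: float = 0.683
    hpd_intervals: List[Tuple[float, float]] = field(default_factory=list)
    flagged_outlier: bool = False

    @property
    def mode_year(self) -> float:
        return float(self.year_ce[int(np.argmax(self.density))])

    def hpd_mass(self) -> float:
        """Total probability mass inside the HPD intervals."""
        m = 0.0
        for a, b in self.hpd_intervals:
            sel = (self.year_ce >= a) & (self.year_ce <= b)
            m += float(self.density[sel].sum())
        return m

    def contains(self, year_ce: float) -> bool:
        """True if ``year_ce`` lies inside any HPD interval."""
        return any(a <= year_ce <= b for a, b in self.hpd_intervals)

    def distance(self, year_ce: float) -> float:
        """Distance in years from ``year_ce`` to the nearest HPD interval."""
        if not self.hpd_intervals:
            return float("inf")
        return min(
            0.0 if a <= year_ce <= b else min(abs(year_ce - a), abs(year_ce - b))
            for a, b in self.hpd_intervals
        )


def _bin_masses(measured: float, sigma_lab: float, curve: CalibrationCurve,
                grid_bp: np.ndarray, step: float) -> np.ndarray:
    """Likelihood integrated over [θ−step/2, θ+step/2] per grid point.

    Composite Simpson with ``_SIMPSON_K`` sub-intervals per bin; bins are
    clipped to the curve support so no query leaves the grid.
    """
    k = _SIMPSON_K
    offs = np.linspace(-step / 2.0, step / 2.0, k + 1)
    # Simpson weights 1,4,2,...,4,1 (scaled later; only ratios matter after
    # normalisation, but keep the h/3 factor for true bin masses).
    w = np.ones(k + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    h = step / k
    theta = grid_bp[:, None] + offs[None, :]
    np.clip(theta, curve.cal_bp[0], curve.cal_bp[-1], out=theta)
    mu = np.interp(theta, curve.cal_bp, curve.c14_value)
    sc = np.interp(theta, curve.cal_bp, curve.curve_sigma)
    var = sigma_lab ** 2 + sc ** 2
    like = np.exp(-0.5 * (measured - mu) ** 2 / var) / np.sqrt(var)
    return (like * w[None, :]).sum(axis=1) * (h / 3.0)


def _calibrate_common(date: RadiocarbonDate, curve: CalibrationCurve,
                      grid_step: float, coverage: float) -> CalibratedDate:
    # keep whole bins inside the curve support
    lo = float(np.ceil(curve.cal_bp[0] + grid_step / 2.0))
    hi = float(np.floor(curve.cal_bp[-1] - grid_step / 2.0))
    if hi <= lo:
        raise ValidationError("curve support narrower than one grid step")
    grid_bp = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    mass = _bin_masses(date.value, date.sigma, curve, grid_bp, grid_step)
    total = mass.sum()
    if not total > 0:
        raise ValidationError(
            f"{date.tree_id} sample {date.sample_number}: date has zero "
            "posterior mass on the curve support"
        )
    density = mass / total
    year_ce = bp_to_ce(grid_bp)
    # present ascending in CE for downstream readability
    order = np.argsort(year_ce, kind="stable")
    year_ce, density = year_ce[order], density[order]
    cal = CalibratedDate(
        tree_id=date.tree_id,
        sample_number=date.sample_number,
        year_ce=year_ce,
        density=density,
        coverage=coverage,
        flagged_outlier=date.flagged_outlier,
    )
    cal.hpd_intervals = hpd(year_ce, density, coverage, grid_step=grid_step)
    return cal


def calibrate(date: RadiocarbonDate, curve: CalibrationCurve,
              grid_step: float = 1.0, coverage: float = 0.683) -> CalibratedDate:
    """Calibrate a pre-bomb conventional radiocarbon age.

    Parameters
    ----------
    date
        Measurement with ``measurement_type == "conventional_BP"``.
    curve
        Pre-bomb calibration curve (14C age BP vs cal BP).
    grid_step
        Calendar grid resolution in years (default 1).
    coverage
        HPD coverage level (default 0.683, the 1-sigma convention).
    """
    if date.measurement_type != "conventional_BP":
        raise ValidationError(
            "calibrate() expects a conventional_BP date; use "
            "calibrate_postbomb() for F14C measurements"
        )
    if curve.era != "pre_bomb":
        raise ValidationError("calibrate() requires a pre_bomb curve")
    return _calibrate_common(date, curve, grid_step, coverage)


def calibrate_postbomb(date: RadiocarbonDate, curve: CalibrationCurve,
                       grid_step: float = 1.0,
                       coverage: float = 0.683) -> CalibratedDate:
    """Calibrate a post-bomb F14C measurement against a bomb-era curve.

    The bomb curve is non-monotone (rapid rise to the mid-1960s peak, then
    decline), so the posterior is frequently multimodal and the HPD set
    splits into disjoint intervals.
    """
    if date.measurement_type != "F14C":
        raise ValidationError("calibrate_postbomb() expects an F14C date")
    if curve.era != "post_bomb_F14C":
        raise ValidationError(
            "calibrate_postbomb() requires a post_bomb_F14C curve"
        )
    return _calibrate_common(date, curve, grid_step, coverage)


def hpd(year_ce: np.ndarray, density: np.ndarray, coverage: float = 0.683,
        grid_step: float = 1.0) -> List[Tuple[float, float]]:
    """Highest-posterior-density intervals from a gridded density.

    Grid years are admitted in order of decreasing probability mass until
    the cumulative mass reaches ``coverage``; probability ties are broken
    toward earlier calendar years for determinism.  Contiguous admitted
    years merge into inclusive ``(start_CE, end_CE)`` intervals.
    """
    if not 0.0 < coverage < 1.0:
        raise ValidationError(f"coverage must be in (0, 1), got {coverage}")
    year_ce = np.asarray(year_ce, dtype=float)
    density = np.asarray(density, dtype=float)
    # sort by (-p, year): descending mass, earlier year on ties
    order = np.lexsort((year_ce, -density))
    csum = np.cumsum(density[order])
    n_in = int(np.searchsorted(csum, coverage - 1e-12) + 1)
    n_in = min(n_in, density.size)
    chosen = np.sort(year_ce[order[:n_in]])
    intervals: List[Tuple[float, float]] = []
    start = prev = chosen[0]
    tol = 1.5 * grid_step
    for y in chosen[1:]:
        if y - prev > tol:
            intervals.append((float(start), float(prev)))
            start = y
        prev = y
    intervals.append((float(start), float(prev)))
    return intervals


def calibrate_any(date: RadiocarbonDate, pre_curve: CalibrationCurve,
                  bomb_curve: CalibrationCurve = None,
                  grid_step: float = 1.0,
                  coverage: float = 0.683) -> CalibratedDate:
    """Dispatch a date to the pre-bomb or post-bomb calibration routine."""
    if date.measurement_type == "F14C":
        if bomb_curve is None:
            raise ValidationError(
                f"{date.tree_id} sample {date.sample_number} is F14C but no "
                "bomb curve supplied"
            )
        return calibrate_postbomb(date, bomb_curve, grid_step, coverage)
    return calibrate(date, pre_curve, grid_step, coverage)
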