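"""Robust windowed smoothing for irregularly dated proxy series.

The workhorse is a 21-year Tukey biweight mean: for each grid year the
robust location of all samples dated within the decade before and after.
The biweight downweights outliers smoothly to zero, which both suppresses
measurement blunders and absorbs small age-model errors, at the cost of
resolving nothing below the decadal scale.
"""

from __future__ import annotations

import numpy as np

from .types import DatedSeries, ValidationError

__all__ = ["biweight_location", "biweight_smooth", "moving_average"]

#: MAD → sigma consistency factor for the normal distribution.
MAD_SCALE = 0.6745


def biweight_location(x: np.ndarray, tuning_c: float = 9.0,
                      max_iter: int = 50, tol: float = 1e-12) -> float:
    """Tukey biweight location of a 1-D sample.

    Starting from the median M, iterate the weighted mean
    M ← Σ w_i x_i / Σ w_i with u_i = (x_i − M)/(c·MAD/0.6745) and
    w_i = (1 − u_i²)² for |u_i| < 1, else 0.  A zero MAD (more than half
    the window identical) returns the median.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("biweight of an empty sample")
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0.0:
        return m
    scale = tuning_c * mad / MAD_SCALE
    for _ in range(max_iter):
        u = (x - m) / scale
        w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        sw = w.sum()
        if sw == 0.0:  # pathological: everything beyond the cutoff
            return m
        m_new = float((w * x).sum() / sw)
        if abs(m_new - m) <= tol * max(1.0, abs(m)):
            return m_new
        m = m_new
    return m


def biweight_smooth(series: DatedSeries, window_years: int = 21,
                    tuning_c: float = 9.0, max_iter: int = 50,
                    grid=None):
    """Windowed biweight mean of a dated series on an annual grid.

    For each integer grid year Y the biweight location of all samples
    dated within [Y − h, Y + h] (h = (window−1)/2, default decade either
    side).  Years whose window holds no sample are omitted, so a growth
    hiatus leaves a gap rather than an interpolated bridge.

    Parameters
    ----------
    series
        Dated, corrected δ13C series (fractional years allowed).
    window_years
        Odd window width in years (default 21).
    grid
        Integer years to evaluate; default spans the series' rounded span.

    Returns
    -------
    (years, values) — integer grid years with at least one sample, and the
    biweight location per year.
    """
    if window_years % 2 != 1 or window_years < 1:
        raise ValidationError("window_years must be a positive odd integer")
    if len(series) == 0:
        raise ValidationError("cannot smooth an empty series")
    h = (window_years - 1) / 2.0
    ys = series.years
    vals = series.values
    if grid is None:
        grid = np.arange(int(np.ceil(ys[0])), int(np.floor(ys[-1])) + 1)
    else:
        grid = np.asarray(grid, dtype=int)
    out_years, out_vals = [], []
    lo_idx = np.searchsorted(ys, grid - h, side="left")
    hi_idx = np.searchsorted(ys, grid + h, side="right")
    for y, i0, i1 in zip(grid, lo_idx, hi_idx):
        if i1 <= i0:
            continue
        out_years.append(int(y))
        out_vals.append(biweight_location(vals[i0:i1], tuning_c, max_iter))
    return np.asarray(out_years, dtype=int), np.asarray(out_vals, dtype=float)


def moving_average(years: np.ndarray, values: np.ndarray,
                   window_years: int = 10):
    """Centered moving average on an annual series, truncated at the ends.

    Used to put short instrumental rainfall records on a comparable
    smoothness to the biweight proxy composite.  For even windows the
    window [y − w/2, y + w/2) is used.
    """
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    if years.size == 0:
        raise ValidationError("empty series")
    if window_years > years[-1] - years[0] + 1:
        raise ValidationError("window longer than the series span")
    half_lo = (window_years - 1) // 2
    half_hi = window_years // 2
    out = np.empty_like(values)
    for i, y in enumerate(years):
        sel = (years >= y - half_lo) & (years <= y + half_hi)
        out[i] = values[sel].mean()
    return years.copy(), out
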