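"""Trend, changepoint and forcing-correlation statistics.

* :func:`mann_kendall` — non-parametric monotone-trend test with the
  tie-corrected variance and a ±1 continuity correction on the normal
  approximation.
* :func:`ols_trend` — least-squares value-on-year regression with the
  F/R² summary.
* :func:`changepoint_mean` — mean-shift segmentation minimising
  Σ segment SSE + β·(number of changepoints), either exactly (PELT with
  pruning) or greedily (binary segmentation).
* :func:`correlate_with_forcing` — windowed Pearson correlation of the
  proxy composite against an annual climate index, with optional matched
  smoothing of both sides and lag-1 autocorrelations reported so the
  reader can judge the effective sample size (p-values carry no
  autocorrelation correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from .composite import CompositeRecord
from .smoothing import moving_average
from .types import AnnualRecord, ValidationError

__all__ = [
    "TrendResult",
    "ChangePointResult",
    "CorrelationResult",
    "mann_kendall",
    "ols_trend",
    "trend",
    "changepoint_mean",
    "correlate_with_forcing",
]


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall and OLS trend summaries for one series."""

    mk_s: int
    mk_var_s: float
    mk_z: float
    mk_p: float
    ols_slope: float
    ols_intercept: float
    ols_f: float
    ols_r2: float
    ols_p: float


def mann_kendall(x) -> Tuple[int, float, float, float]:
    """Mann-Kendall trend test.

    Returns ``(S, var_S, Z, p)`` with

    * S = Σ_{i<j} sgn(x_j − x_i) — positive for increasing series;
    * var_S = [n(n−1)(2n+5) − Σ_ties t(t−1)(2t+5)] / 18;
    * Z = (S ∓ 1)/√var_S (continuity-corrected; 0 when S = 0);
    * p — two-sided normal tail probability.

    A constant series returns (0, 0, 0, 1).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValidationError(f"Mann-Kendall needs n >= 4, got {n}")
    sgn = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(sgn, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:  # all values tied
        return s, 0.0, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(var_s), float(z), float(min(p, 1.0))


def ols_trend(years, values) -> Tuple[float, float, float, float, float]:
    """OLS regression of value on year.

    Returns ``(slope, intercept, F, R², p)`` where F = (n−2)·R²/(1−R²)
    and p is the two-sided slope test (equivalently the F test with 1 and
    n−2 degrees of freedom).
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size < 3:
        raise ValidationError("OLS trend needs n >= 3")
    if np.ptp(years) == 0:
        raise ValidationError("year vector is constant")
    res = stats.linregress(years, values)
    r2 = res.rvalue ** 2
    n = years.size
    if r2 >= 1.0:
        f = np.inf
    else:
        f = (n - 2) * r2 / (1.0 - r2)
    return (float(res.slope), float(res.intercept), float(f), float(r2),
            float(res.pvalue))


def trend(years, values) -> TrendResult:
    """Convenience wrapper running both trend tests on one series."""
    s, var_s, z, p = mann_kendall(values)
    slope, intercept, f, r2, olsp = ols_trend(years, values)
    return TrendResult(mk_s=s, mk_var_s=var_s, mk_z=z, mk_p=p,
                       ols_slope=slope, ols_intercept=intercept,
                       ols_f=f, ols_r2=r2, ols_p=olsp)


# ---------------------------------------------------------------------------
# changepoint detection


@dataclass
class ChangePointResult:
    """Mean-shift segmentation of an annual series."""

    change_years: List[int]
    segment_means: List[float]
    segment_lengths: List[int]
    penalty_value: float
    method: str


def _cumstats(x):
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    return c1, c2


def _seg_sse(c1, c2, i, j):
    """SSE of x[i:j] about its mean (j exclusive)."""
    n = j - i
    s = c1[j] - c1[i]
    return (c2[j] - c2[i]) - s * s / n


def _pelt(x, beta, min_size=1):
    """Exact penalised segmentation by PELT (pruned dynamic programming)."""
    n = x.size
    c1, c2 = _cumstats(x)
    f = np.full(n + 1, np.inf)
    f[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(min_size, n + 1):
        best, arg = np.inf, 0
        for s in candidates:
            if t - s < min_size:
                continue
            val = f[s] + _seg_sse(c1, c2, s, t) + beta
            if val < best:
                best, arg = val, s
        f[t] = best
        last[t] = arg
        # prune: s stays a candidate only if it could still win later
        candidates = [s for s in candidates
                      if f[s] + _seg_sse(c1, c2, s, t) <= f[t]]
        candidates.append(t)
    # backtrack
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def _binseg(x, beta, min_size=1):
    """Greedy binary segmentation under the same penalised objective."""
    n = x.size
    c1, c2 = _cumstats(x)
    segments = [(0, n)]
    cps = []
    improved = True
    while improved:
        improved = False
        best_gain, best_split, best_seg = 0.0, None, None
        for (i, j) in segments:
            if j - i < 2 * min_size:
                continue
            base = _seg_sse(c1, c2, i, j)
            for t in range(i + min_size, j - min_size + 1):
                gain = base - _seg_sse(c1, c2, i, t) - _seg_sse(c1, c2, t, j)
                if gain - beta > best_gain:
                    best_gain, best_split, best_seg = gain - beta, t, (i, j)
        if best_split is not None:
            i, j = best_seg
            segments.remove(best_seg)
            segments.extend([(i, best_split), (best_split, j)])
            cps.append(best_split)
            improved = True
    return sorted(cps)


def changepoint_mean(years, values, penalty="mbic", method="pelt",
                     min_size: int = 1) -> ChangePointResult:
    """Detect mean shifts in an annual series.

    The objective is Σ_segments SSE/σ̂² + β·m over segmentations with m
    changepoints, where σ̂² is a robust noise estimate from lag-1
    differences (median absolute difference, normal-consistent).  ``penalty``
    selects β: ``"bic"`` → 2·log n, ``"mbic"`` → 3·log n (the constant-
    penalty form of the modified BIC, the default of the standard R
    tooling), or a positive number used as a manual β.  ``method`` is
    ``"pelt"`` (exact, pruned) or ``"binseg"`` (greedy).

    Change years are reported as the first year of each new segment.
    """
    years = np.asarray(years, dtype=int)
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValidationError(f"changepoint detection needs n >= 10, got {n}")
    # robust noise scale from first differences: sd ≈ MAD(diff)/0.6745/√2
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / 0.6745 / np.sqrt(2.0)
    if sigma == 0.0:
        sigma = float(np.std(d)) / np.sqrt(2.0) if np.std(d) > 0 else 1.0
    xs = x / sigma
    if isinstance(penalty, str):
        if penalty == "bic":
            beta = 2.0 * np.log(n)
        elif penalty == "mbic":
            beta = 3.0 * np.log(n)
        else:
            raise ValidationError(f"unknown penalty {penalty!r}")
    else:
        beta = float(penalty)
        if beta <= 0:
            raise ValidationError("manual penalty must be positive")
    if method == "pelt":
        cps = _pelt(xs, beta, min_size)
    elif method == "binseg":
        cps = _binseg(xs, beta, min_size)
    else:
        raise ValidationError(f"unknown method {method!r}")
    bounds = [0] + cps + [n]
    seg_means = [float(x[i:j].mean()) for i, j in zip(bounds, bounds[1:])]
    seg_lens = [j - i for i, j in zip(bounds, bounds[1:])]
    return ChangePointResult(
        change_years=[int(years[c]) for c in cps],
        segment_means=seg_means,
        segment_lengths=seg_lens,
        penalty_value=float(beta),
        method=method,
    )


# ---------------------------------------------------------------------------
# forcing correlations


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of the composite against a forcing index."""

    window: Tuple[int, int]
    n: int
    r: float
    p: float
    smoothing: Optional[int]
    lag1_composite: float
    lag1_forcing: float


def _lag1(x):
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.std(x) == 0:
        return float("nan")
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


def correlate_with_forcing(composite: CompositeRecord, forcing: AnnualRecord,
                           window: Optional[Tuple[int, int]] = None,
                           pre_smoothing: Optional[int] = None
                           ) -> CorrelationResult:
    """Pearson correlation between the composite and a climate index.

    Both series are aligned on common integer years (pairwise-complete),
    optionally restricted to ``window = (start_CE, end_CE)`` inclusive and
    smoothed identically with a centered ``pre_smoothing``-year moving
    average before correlating.  Two-sided p comes from the usual t
    transform; lag-1 autocorrelations of both smoothed sides are attached
    because smoothing inflates apparent significance.
    """
    cy, cv = composite.years, composite.values
    fy, fv = forcing.years, forcing.values
    if pre_smoothing is not None:
        cy, cv = moving_average(cy, cv, pre_smoothing)
        fy, fv = moving_average(fy, fv, pre_smoothing)
    common, ci, fi = np.intersect1d(cy, fy, return_indices=True)
    if window is not None:
        keep = (common >= window[0]) & (common <= window[1])
        common, ci, fi = common[keep], ci[keep], fi[keep]
    a, b = cv[ci], fv[fi]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b, common = a[ok], b[ok], common[ok]
    if common.size < 3:
        raise ValidationError(
            f"only {common.size} overlapping years; need >= 3"
        )
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(
        window=(int(common[0]), int(common[-1])),
        n=int(common.size),
        r=float(r),
        p=float(p),
        smoothing=pre_smoothing,
        lag1_composite=_lag1(a),
        lag1_forcing=_lag1(b),
    )
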