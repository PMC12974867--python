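"""Multi-tree compositing on a common annual grid.

Each tree's smoothed series is an independent realisation of the regional
signal plus local site effects; the composite is the per-year mean across
trees with the standard error of that mean, recorded together with how
many trees contribute.  Years covered by no tree (e.g. inside a growth
hiatus affecting every core) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .types import ValidationError

__all__ = ["CompositeRecord", "build_composite"]


@dataclass
class CompositeRecord:
    """Annual multi-tree composite with standard errors.

    ``se`` is NaN where fewer than two trees contribute (a standard error
    of a single value is undefined).
    """

    years: np.ndarray
    values: np.ndarray
    se: np.ndarray
    n_trees: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n_trees = np.asarray(self.n_trees, dtype=int)
        if not (self.years.shape == self.values.shape == self.se.shape
                == self.n_trees.shape):
            raise ValidationError("composite arrays differ in length")
        if self.years.size and (np.diff(self.years) <= 0).any():
            raise ValidationError("composite grid not strictly increasing")
        finite = np.isfinite(self.se)
        if finite.any() and (self.se[finite] < 0).any():
            raise ValidationError("negative standard error")

    def __len__(self):
        return int(self.years.size)


def build_composite(
    smoothed: Dict[str, Tuple[np.ndarray, np.ndarray]],
) -> CompositeRecord:
    """Stack per-tree smoothed series into a composite record.

    Parameters
    ----------
    smoothed
        Mapping tree_id → (years, values) as returned by
        :func:`dendroiso.smoothing.biweight_smooth`.

    Returns
    -------
    CompositeRecord
        Per-year across-tree mean, standard error s/√k (k = contributing
        trees; NaN for k = 1) and tree count, on the union of the trees'
        annual grids restricted to years with at least one tree.
    """
    if not smoothed:
        raise ValidationError("no smoothed series supplied")
    all_years = np.unique(np.concatenate(
        [np.asarray(y, dtype=int) for y, _ in smoothed.values()]))
    n = all_years.size
    k = len(smoothed)
    stack = np.full((k, n), np.nan)
    for row, (tree_id, (yrs, vals)) in enumerate(smoothed.items()):
        yrs = np.asarray(yrs, dtype=int)
        idx = np.searchsorted(all_years, yrs)
        stack[row, idx] = vals
    count = np.sum(~np.isnan(stack), axis=0)
    keep = count >= 1
    stack = stack[:, keep]
    count = count[keep]
    years = all_years[keep]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    se = np.where(count >= 2, sd / np.sqrt(count), np.nan)
    return CompositeRecord(years=years, values=mean, se=se, n_trees=count)
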