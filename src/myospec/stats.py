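"""Pointwise spectral statistics: group means, confidence bands, and
wavelength-by-wavelength separability.

For each detection wavelength independently, a group of normalized spectra
yields a mean and a 95% confidence interval; two groups are "separable" at
a wavelength where their CIs do not overlap, or where a two-sample Welch
t-test rejects at alpha.  No correction is applied across wavelengths —
the bands are descriptive, highlighting where spectral shape differs, not
a family-wise inference.  Group sizes are small (a handful of animals with
triplicate probes), hence t-based rather than normal-based intervals by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .spectra import WavelengthGrid

__all__ = [
    "BandSummary",
    "SeparabilityBands",
    "pointwise_ci",
    "ci_separability",
    "pointwise_ttest",
]


@dataclass
class BandSummary:
    """Per-wavelength group mean with CI bounds for one class."""

    grid: WavelengthGrid
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: int
    level: float = 0.95


@dataclass
class SeparabilityBands:
    """Disjoint, sorted wavelength intervals where two groups separate."""

    intervals: list[tuple[float, float]]

    def contains(self, lam: float) -> bool:
        return any(lo <= lam <= hi for lo, hi in self.intervals)

    def total_width(self) -> float:
        return sum(hi - lo for lo, hi in self.intervals)


def pointwise_ci(
    matrix: np.ndarray,
    grid: WavelengthGrid,
    level: float = 0.95,
    method: str = "t",
) -> BandSummary:
    """Per-wavelength mean with a ``level`` CI: mean +/- q * sd/sqrt(n).

    ``method='t'`` uses the Student-t quantile with n-1 degrees of freedom
    (default, appropriate at small n); ``method='normal'`` the Gaussian
    quantile.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("confidence intervals need at least two spectra")
    if x.shape[1] != len(grid):
        raise ValueError("matrix width does not match grid")
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")

    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if method == "t":
        q = sps.t.ppf(0.5 + level / 2, df=n - 1)
    elif method == "normal":
        q = sps.norm.ppf(0.5 + level / 2)
    else:
        raise ValueError("method must be 't' or 'normal'")
    half = q * sd / np.sqrt(n)
    return BandSummary(grid=grid, mean=mean, ci_lo=mean - half, ci_hi=mean + half, n=n, level=level)


def _mask_to_intervals(mask: np.ndarray, grid: WavelengthGrid) -> list[tuple[float, float]]:
    """Merge a per-channel boolean mask into maximal contiguous nm intervals."""
    lam = grid.values
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(lam[start]), float(lam[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(lam[start]), float(lam[-1])))
    return intervals


def ci_separability(a: BandSummary, b: BandSummary) -> SeparabilityBands:
    """Wavelength intervals where the two groups' CIs do not overlap."""
    if a.grid != b.grid:
        raise ValueError("band summaries are not on the same grid")
    separated = (a.ci_hi < b.ci_lo) | (b.ci_hi < a.ci_lo)
    return SeparabilityBands(intervals=_mask_to_intervals(separated, a.grid))


def pointwise_ttest(
    a_matrix: np.ndarray,
    b_matrix: np.ndarray,
    grid: WavelengthGrid,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> SeparabilityBands:
    """Per-wavelength two-sample t-test (Welch by default); intervals where
    p < alpha.  No multiple-testing correction across wavelengths."""
    a = np.atleast_2d(np.asarray(a_matrix, dtype=float))
    b = np.atleast_2d(np.asarray(b_matrix, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least two spectra")
    if a.shape[1] != len(grid) or b.shape[1] != len(grid):
        raise ValueError("matrix width does not match grid")
    if alpha <= 0:
        return SeparabilityBands(intervals=[])

    result = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    pvalues = np.asarray(result.pvalue)
    flagged = np.where(np.isfinite(pvalues), pvalues < alpha, False)
    return SeparabilityBands(intervals=_mask_to_intervals(flagged, grid))
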