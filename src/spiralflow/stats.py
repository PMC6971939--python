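"""Bland-Altman and orthogonal (total least squares) regression.

Paired hemodynamic values — voxel-wise velocities or wall-point WSS
magnitudes from two reconstructions of the same anatomy — are compared
by (i) Bland-Altman bias and 1.96-SD limits of agreement and (ii) an
orthogonal regression line assuming equal error variance in both
variables, plus the conventional Pearson correlation.  The Bland-Altman
percent bias uses the grand mean of the pair averages as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "PairedSample",
    "BAResult",
    "RegressionResult",
    "bland_altman",
    "orthogonal_regression",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedSample:
    """Aligned (reference, test) value arrays with a descriptive label."""

    reference: np.ndarray
    test: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)
        if ref.shape != tst.shape or ref.ndim != 1:
            raise ValueError("reference and test must be 1D arrays of equal length")
        if len(ref) < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(tst))):
            raise ValueError("non-finite values in paired sample")

    @property
    def n(self) -> int:
        return len(self.reference)


@dataclass(frozen=True)
class BAResult:
    mean_difference: float
    mean_difference_percent: Optional[float]
    loa_low: float
    loa_high: float
    sd_difference: float
    n: int

    @property
    def loa_width(self) -> float:
        return self.loa_high - self.loa_low


def bland_altman(pairs: PairedSample) -> BAResult:
    """Bias and limits of agreement of test - reference differences.

    The percent bias divides the mean difference by the grand mean of
    the pair averages; it is None when that grand mean is zero.
    """
    diff = pairs.test - pairs.reference
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    grand_mean = float(((pairs.test + pairs.reference) / 2.0).mean())
    percent = None if grand_mean == 0 else 100.0 * mean_diff / grand_mean
    return BAResult(
        mean_difference=mean_diff,
        mean_difference_percent=percent,
        loa_low=mean_diff - LOA_MULTIPLIER * sd,
        loa_high=mean_diff + LOA_MULTIPLIER * sd,
        sd_difference=sd,
        n=pairs.n,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_rho: float


def orthogonal_regression(pairs: PairedSample) -> RegressionResult:
    """Total-least-squares line through the pairs (equal error variances).

    The slope comes from the principal direction of the centred 2-column
    data (closed form on the 2x2 covariance); Pearson rho is computed
    conventionally.
    """
    x = pairs.reference
    y = pairs.test
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0 or syy == 0:
        raise ValueError("degenerate sample: zero variance")
    if sxy == 0:
        slope = 0.0 if sxx >= syy else np.inf
    else:
        slope = (syy - sxx + np.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)
    intercept = float(y.mean() - slope * x.mean())
    rho = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(slope=float(slope), intercept=intercept, pearson_rho=rho)
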