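"""ROI containers and summary statistics for map comparisons.

Masks are supplied (drawn, imported, or thresholded); summaries are means
with standard errors, percent changes, two-tailed t-tests (Welch or
paired), and R-squared from linear regression -- the statistics used to
compare structure/dynamics maps between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "RoiMask",
    "roi_summary",
    "percent_change",
    "t_test",
    "r_squared",
    "threshold_mask",
]


@dataclass
class RoiMask:
    """A labeled boolean region over a map's spatial grid."""

    label: str                       # nucleus | cytoplasm | cell | background | custom
    mask: np.ndarray
    source: str = "manual"           # manual polygon, threshold, imported

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def roi_summary(map_values: np.ndarray, mask) -> tuple:
    """(mean, SEM, n) over finite masked pixels; requires >= 2 pixels."""
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    vals = np.asarray(map_values, dtype=np.float64)[m]
    vals = vals[np.isfinite(vals)]
    n = vals.size
    if n < 2:
        raise ValueError("ROI summary requires at least 2 valid pixels")
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n)), n


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / |before|: sign reflects direction of change."""
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (after - before) / abs(before)


def t_test(sample_a, sample_b, mode: str = "welch") -> tuple:
    """Two-tailed t-test: Welch (heteroscedastic, default) or paired.

    Returns ``(t, p)``.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if mode == "welch":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("both samples have zero variance")
        res = stats.ttest_ind(a, b, equal_var=False)
    elif mode == "paired":
        if a.size != b.size:
            raise ValueError("paired test requires equal-length samples")
        if np.all(a == b):
            return 0.0, 1.0   # zero differences everywhere: no effect
        res = stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown t-test mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def r_squared(x, y) -> float:
    """Square of the Pearson correlation (R^2 of the linear regression)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("R^2 undefined for a zero-variance variable")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def threshold_mask(map_values: np.ndarray, threshold: float,
                   fill_holes: bool = True, label: str = "custom") -> RoiMask:
    """Convenience threshold-plus-fill segmentation (not a claimed method)."""
    m = np.asarray(map_values) > threshold
    if fill_holes:
        m = ndimage.binary_fill_holes(m)
    return RoiMask(label=label, mask=m, source="threshold")
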