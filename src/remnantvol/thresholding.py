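"""Gray-level-histogram (GLH) machinery.

The GLH technique picks the intensity threshold that maximizes the
between-class variance of a two-class split (Otsu's criterion).  It is applied
twice in this package: first to SPECT uptake values inside a user VOI (a clear
bimodal split, since diagnostic background activity is only a few percent of
the hot volume), then to CT Hounsfield units inside the SPECT-derived mask,
where the two tissue classes differ by only a few tens of HU.  For the CT pass
the classification band is the minimum-to-maximum range of the volume-side
HU region (optionally tightened to inner percentiles for noisy clinical
data), making the HU threshold adaptive to the actual HU distribution inside
the VOI.

Both passes are invariant to adding a constant to all values (so the offset HU
convention with water at 1000 is harmless) and equivariant under positive
scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogram

#: Switch from exhaustive distinct-value candidates to 256-bin histogram
#: midpoints above this many distinct values (speed; both paths are tested
#: against the brute-force oracle).
MAX_EXACT_LEVELS = 4096
DEFAULT_BINS = 256


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of one Otsu threshold selection.

    ``threshold`` separates the low class (values <= threshold) from the high
    class (values > threshold); for non-degenerate input
    ``class_means[0] <= threshold < class_means[1]`` and
    ``n_low + n_high`` equals the input size.
    """

    threshold: float
    between_class_variance: float
    class_means: tuple[float, float]
    n_low: int
    n_high: int


@dataclass(frozen=True)
class HUBand:
    """Inclusive HU interval classifying voxels as volume.

    ``lo <= hi``; ``source_class_mean`` is the mean HU of the similar-HU
    region the band was derived from, ``percentiles`` the (p_lo, p_hi) pair
    used to trim it.
    """

    lo: float
    hi: float
    source_class_mean: float
    percentiles: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"band lo={self.lo} > hi={self.hi}")
        p_lo, p_hi = self.percentiles
        if not (0 <= p_lo < p_hi <= 100):
            raise ValueError(f"percentiles must satisfy 0 <= p_lo < p_hi <= 100")

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values inside [lo, hi] (inclusive)."""
        v = np.asarray(values)
        return (v >= self.lo) & (v <= self.hi)


def _candidate_levels(
    values: np.ndarray, max_exact: int, bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate thresholds and their weights.

    Up to ``max_exact`` distinct values: the sorted distinct values themselves.
    Beyond that: midpoints of a ``bins``-bin histogram.
    """
    levels, counts = np.unique(values, return_counts=True)
    if levels.size < 2:
        raise DegenerateHistogram(
            f"all {values.size} values equal ({levels[0] if levels.size else 'empty'})"
        )
    if levels.size <= max_exact:
        return levels, counts.astype(float)
    hist, edges = np.histogram(values, bins=bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return mids, hist.astype(float)


def otsu_threshold(
    values,
    *,
    max_exact: int = MAX_EXACT_LEVELS,
    bins: int = DEFAULT_BINS,
) -> ThresholdResult:
    """Threshold maximizing the between-class variance of a two-class split.

    Equivalent to an exhaustive search over the candidate thresholds (every
    distinct value when there are at most ``max_exact`` of them, otherwise the
    ``bins`` histogram-bin midpoints); ties are broken by the smallest
    qualifying threshold.  Classification convention: values strictly greater
    than the threshold are the high class.

    Raises
    ------
    DegenerateHistogram
        If the input has fewer than two distinct values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateHistogram("empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")

    levels, weights = _candidate_levels(v, max_exact, bins)
    total = weights.sum()
    cum_w = np.cumsum(weights)
    cum_s = np.cumsum(weights * levels)
    # A threshold at the last level would leave the high class empty, so the
    # candidates are all levels but the last.
    w0 = cum_w[:-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = cum_s[:-1] / w0
        m1 = (cum_s[-1] - cum_s[:-1]) / w1
        sigma_b = (w0 / total) * (w1 / total) * (m0 - m1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    best = int(np.argmax(sigma_b))  # first maximum = smallest threshold
    threshold = float(levels[best])

    low = v <= threshold
    n_low = int(low.sum())
    n_high = v.size - n_low
    return ThresholdResult(
        threshold=threshold,
        between_class_variance=float(sigma_b[best]),
        class_means=(float(v[low].mean()), float(v[~low].mean())),
        n_low=n_low,
        n_high=n_high,
    )


def classify_above(values, threshold: float) -> np.ndarray:
    """Boolean mask of values strictly greater than the threshold."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    return np.asarray(values) > threshold


def adaptive_hu_band(
    hu_values,
    volume_polarity: str = "lower",
    percentiles: tuple[float, float] = (0.0, 100.0),
    *,
    max_exact: int = MAX_EXACT_LEVELS,
    bins: int = DEFAULT_BINS,
) -> HUBand:
    """Adaptive HU band for the second GLH pass.

    The HU distribution inside the SPECT-derived VOI is split into two
    similar-HU regions with :func:`otsu_threshold`; the region on the
    ``volume_polarity`` side is selected (``"lower"`` by default -- in the
    neck phantom the volume cavity reads lower HU than its surround) and its
    (p_lo, p_hi) percentiles, linearly interpolated between order statistics,
    become the inclusive classification band.  The default (0, 100) band is
    the region's minimum-to-maximum range; inner percentiles can be given to
    trim outliers in noisy data.

    Raises
    ------
    DegenerateHistogram
        Propagated from the Otsu split when all HU values are equal.
    """
    if volume_polarity not in ("lower", "higher"):
        raise ValueError("volume_polarity must be 'lower' or 'higher'")
    p_lo, p_hi = percentiles
    if not (0 <= p_lo < p_hi <= 100):
        raise ValueError(f"invalid percentiles {percentiles}")
    v = np.asarray(hu_values, dtype=float).ravel()
    split = otsu_threshold(v, max_exact=max_exact, bins=bins)
    in_low = v <= split.threshold
    selected = v[in_low] if volume_polarity == "lower" else v[~in_low]
    lo, hi = np.percentile(selected, [p_lo, p_hi], method="linear")
    return HUBand(
        lo=float(lo),
        hi=float(hi),
        source_class_mean=float(selected.mean()),
        percentiles=(float(p_lo), float(p_hi)),
    )
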