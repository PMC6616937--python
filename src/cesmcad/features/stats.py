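"""First-order intensity statistics shared by several feature sets.

Conventions (fixed once, applied identically everywhere):

* moments are population moments (``ddof=0``);
* skewness and kurtosis are the standardized 3rd / 4th central moments,
  kurtosis non-excess (a Gaussian gives 3); both are defined as 0 for a
  constant input;
* entropy is Shannon entropy in bits of a 256-bin histogram spanning the
  data range (0 for a constant input);
* relative smoothness is the Gonzalez-Woods descriptor
  ``R = 1 - 1/(1 + sigma^2)`` with the variance computed on intensities
  min-max rescaled to [0, 1], so that R is bounded in [0, 1).
"""

from __future__ import annotations

import numpy as np

#: the 11 first-order statistics of the STAT set, in canonical order
STAT_ORDER = (
    "Mean",
    "StandardDeviation",
    "MeanStdRatio",
    "Variance",
    "Skewness",
    "Entropy",
    "RelativeSmoothness",
    "Kurtosis",
    "Minimum",
    "Maximum",
    "Range",
)

#: the 6-statistic subset reused by the GRAD and HAAR sets
TEXTURE_ORDER = (
    "Mean",
    "Variance",
    "Skewness",
    "Entropy",
    "RelativeSmoothness",
    "Kurtosis",
)


def rescale01(x: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant array maps to all zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def histogram_entropy(x: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram over the data range."""
    x = np.asarray(x, dtype=float).ravel()
    if x.min() == x.max():
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def relative_smoothness(x: np.ndarray) -> float:
    var = float(np.var(rescale01(x)))
    return 1.0 - 1.0 / (1.0 + var)


def _standardized_moment(x: np.ndarray, order: int) -> float:
    x = np.asarray(x, dtype=float).ravel()
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        return 0.0
    return float(np.mean(((x - mu) / sigma) ** order))


def first_order_stats(x: np.ndarray) -> dict[str, float]:
    """All 11 first-order statistics of a matrix, keyed by canonical name."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute statistics of an empty array")
    mean = float(x.mean())
    std = float(x.std())
    return {
        "Mean": mean,
        "StandardDeviation": std,
        "MeanStdRatio": mean / std if std > 0 else 0.0,
        "Variance": float(x.var()),
        "Skewness": _standardized_moment(x, 3),
        "Entropy": histogram_entropy(x),
        "RelativeSmoothness": relative_smoothness(x),
        "Kurtosis": _standardized_moment(x, 4),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
    }


def texture_stats(x: np.ndarray) -> dict[str, float]:
    """The 6-statistic subset (mean, variance, skewness, entropy,
    relative smoothness, kurtosis) used for gradient and wavelet sub-bands."""
    full = first_order_stats(x)
    return {k: full[k] for k in TEXTURE_ORDER}


def stat_features(roi: np.ndarray) -> dict[str, float]:
    """STAT set contribution of a single ROI: the 11 statistics in order."""
    stats = first_order_stats(roi)
    return {k: stats[k] for k in STAT_ORDER}
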