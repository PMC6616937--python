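"""Gray-level co-occurrence matrices and the 13 Haralick-style statistics.

A GLCM counts how often a pixel of quantized gray level *i* lies at a fixed
displacement from a pixel of level *j*.  Intensities are linearly quantized
from the image's own [min, max] range to ``n_levels`` bins (min-max rather
than fixed-range quantization because Haar detail coefficients are signed);
a constant image puts every pixel in bin 0.  Matrices are accumulated
symmetrically (each pair and its reverse) and normalized to sum to 1.

Directions follow the usual co-occurrence compass with a displacement D:

====  ===================
deg   (row, col) offset
====  ===================
0     (0, +D)
45    (-D, +D)
90    (-D, 0)
135   (-D, -D)
====  ===================

For the GLCM feature set, each level-1 Haar detail band (HL1, LH1, HH1) of
each source image is rescaled to 8-bit, quantized to 8 levels and measured
at D = 1 in all four directions, giving 13 x 3 x 4 = 156 features per image
and 312 per LE/RC pair.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.feature import graycomatrix

from cesmcad.features.haar import LEVEL1_DETAIL, haar_decompose
from cesmcad.features.stats import rescale01

DIRECTIONS_DEG = (0, 45, 90, 135)

#: the 13 co-occurrence statistics, in canonical order
GLCM_STATS_ORDER = (
    "Contrast",
    "Correlation",
    "ClusterProminence",
    "ClusterShade",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "DifferenceEntropy",
    "InverseDifferenceNormalized",
)


@dataclasses.dataclass
class GlcmSpec:
    """Quantization and displacement settings for co-occurrence analysis."""

    n_levels: int = 8
    distance: int = 1
    direction_deg: int = 0
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.direction_deg not in DIRECTIONS_DEG:
            raise ValueError(f"direction must be one of {DIRECTIONS_DEG}")


def quantize(roi: np.ndarray, n_levels: int) -> np.ndarray:
    """Linear min-max quantization to integer levels 0 .. n_levels-1."""
    scaled = rescale01(roi)
    return np.minimum((scaled * n_levels).astype(np.intp), n_levels - 1)


def glcm_matrix(roi: np.ndarray, spec: GlcmSpec) -> np.ndarray:
    """Co-occurrence matrix of a ROI under ``spec``."""
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2:
        raise ValueError("GLCM requires a 2-D ROI")
    d = spec.distance
    if (spec.direction_deg == 0 and roi.shape[1] <= d) or \
       (spec.direction_deg == 90 and roi.shape[0] <= d) or \
       (spec.direction_deg in (45, 135) and (roi.shape[0] <= d or roi.shape[1] <= d)):
        raise ValueError("ROI too small to contain any co-occurrence pair")
    levels = quantize(roi, spec.n_levels).astype(np.uint8)
    # skimage angles run clockwise on screen (rows grow downward); mapping
    # through 180 - deg realizes the standard compass (45 = up-right) whose
    # offsets are documented above, up to pair reversal
    angle = np.deg2rad(180.0 - spec.direction_deg)
    glcm = graycomatrix(
        levels, distances=[d], angles=[angle], levels=spec.n_levels,
        symmetric=spec.symmetric, normed=False,
    )[:, :, 0, 0].astype(float)
    if not spec.symmetric:
        glcm = glcm.T  # skimage counted the reversed offset
    if spec.normalized:
        total = glcm.sum()
        if total == 0:
            raise ValueError("no valid co-occurrence pairs")
        glcm = glcm / total
    return glcm


def glcm_stats(glcm: np.ndarray) -> dict[str, float]:
    """The 13 co-occurrence statistics of a normalized GLCM.

    With p(i, j) the normalized matrix over G levels, marginal means
    mu_x = sum_i i p_x(i) (and mu_y, sigma_x, sigma_y likewise), and the
    sum/difference distributions p_{x+y}(k) = sum_{i+j=k} p(i,j),
    p_{x-y}(k) = sum_{|i-j|=k} p(i,j):

    * Contrast              sum p(i,j) (i-j)^2
    * Correlation           sum (i-mu_x)(j-mu_y) p(i,j) / (sigma_x sigma_y),
                            0 when either marginal variance is 0
    * ClusterProminence     sum (i+j-mu_x-mu_y)^4 p(i,j)
    * ClusterShade          sum (i+j-mu_x-mu_y)^3 p(i,j)
    * Dissimilarity         sum p(i,j) |i-j|
    * Energy                sum p(i,j)^2  (angular second moment)
    * Entropy               -sum p log2 p          (0 log 0 = 0)
    * Homogeneity           sum p(i,j) / (1 + (i-j)^2)
    * SumAverage            sum k p_{x+y}(k)
    * SumVariance           sum (k - SumAverage)^2 p_{x+y}(k)
    * SumEntropy            -sum p_{x+y} log2 p_{x+y}
    * DifferenceEntropy     -sum p_{x-y} log2 p_{x-y}
    * InverseDifferenceNormalized   sum p(i,j) / (1 + |i-j| / G)
    """
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("GLCM must be normalized to sum 1")
    g = p.shape[0]
    i = np.arange(g)[:, None]
    j = np.arange(g)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(np.arange(g) * px))
    mu_y = float(np.sum(np.arange(g) * py))
    var_x = float(np.sum((np.arange(g) - mu_x) ** 2 * px))
    var_y = float(np.sum((np.arange(g) - mu_y) ** 2 * py))

    def entropy_of(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    # sum (k = i+j in 0..2G-2) and difference (k = |i-j| in 0..G-1) marginals
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (i + j).ravel(), p.ravel())
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(i - j).ravel(), p.ravel())
    k_sum = np.arange(2 * g - 1)
    sum_avg = float(np.sum(k_sum * p_sum))

    if var_x > 0 and var_y > 0:
        corr = float(np.sum((i - mu_x) * (j - mu_y) * p) / np.sqrt(var_x * var_y))
    else:
        corr = 0.0

    return {
        "Contrast": float(np.sum(p * (i - j) ** 2)),
        "Correlation": corr,
        "ClusterProminence": float(np.sum((i + j - mu_x - mu_y) ** 4 * p)),
        "ClusterShade": float(np.sum((i + j - mu_x - mu_y) ** 3 * p)),
        "Dissimilarity": float(np.sum(p * np.abs(i - j))),
        "Energy": float(np.sum(p ** 2)),
        "Entropy": entropy_of(p.ravel()),
        "Homogeneity": float(np.sum(p / (1.0 + (i - j) ** 2))),
        "SumAverage": sum_avg,
        "SumVariance": float(np.sum((k_sum - sum_avg) ** 2 * p_sum)),
        "SumEntropy": entropy_of(p_sum),
        "DifferenceEntropy": entropy_of(p_diff),
        "InverseDifferenceNormalized": float(np.sum(p / (1.0 + np.abs(i - j) / g))),
    }


def glcm_single(roi: np.ndarray, spec_base: GlcmSpec | None = None) -> dict[str, float]:
    """156 GLCM statistics of one image: 13 x {HL1, LH1, HH1} x 4 directions.

    Each level-1 Haar detail band is rescaled to 8-bit before quantization.
    """
    spec_base = spec_base or GlcmSpec()
    pyramid = haar_decompose(roi)
    out: dict[str, float] = {}
    for band in LEVEL1_DETAIL:
        sub = np.round(rescale01(pyramid[band]) * 255.0)
        for deg in DIRECTIONS_DEG:
            spec = dataclasses.replace(spec_base, direction_deg=deg)
            stats = glcm_stats(glcm_matrix(sub, spec))
            for stat in GLCM_STATS_ORDER:
                out[f"{stat}_{band}_{deg}"] = stats[stat]
    return out


def glcm_features(le: np.ndarray, rc: np.ndarray,
                  spec_base: GlcmSpec | None = None) -> dict[str, float]:
    """GLCM set: 13 statistics x 3 bands x 4 directions x {LE, RC} = 312."""
    out: dict[str, float] = {}
    for src, roi in (("LE", le), ("RC", rc)):
        for name, value in glcm_single(roi, spec_base).items():
            out[f"{name}_{src}"] = value
    return out
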