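"""Sobel gradient field and the GRAD feature set.

The image gradient is approximated with the unnormalized 3x3 Sobel kernels
(reflect padding at the borders).  Magnitude is ``sqrt(fx^2 + fy^2)``;
direction is the two-argument arctangent ``atan2(fy, fx)`` in radians, set
to 0 wherever the magnitude is 0 (atan of a ratio alone is undefined at
``fx = 0``).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from cesmcad.features.stats import TEXTURE_ORDER, texture_stats


@dataclasses.dataclass
class GradientField:
    fx: np.ndarray
    fy: np.ndarray
    gmag: np.ndarray
    gdir: np.ndarray


def sobel_gradient(roi: np.ndarray) -> GradientField:
    """Sobel partial derivatives, magnitude and direction of a 2-D ROI."""
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or min(roi.shape) < 3:
        raise ValueError("Sobel gradient requires a 2-D ROI of at least 3x3")
    # axis=1 differentiates along columns (x), axis=0 along rows (y)
    fx = ndimage.sobel(roi, axis=1, mode="reflect")
    fy = ndimage.sobel(roi, axis=0, mode="reflect")
    gmag = np.hypot(fx, fy)
    gdir = np.where(gmag > 0, np.arctan2(fy, fx), 0.0)
    return GradientField(fx=fx, fy=fy, gmag=gmag, gdir=gdir)


def grad_single(roi: np.ndarray) -> dict[str, float]:
    """12 GRAD statistics of one image: 6 statistics x {Gmag, Gdir}."""
    field = sobel_gradient(roi)
    out: dict[str, float] = {}
    for comp_name, comp in (("Gmag", field.gmag), ("Gdir", field.gdir)):
        stats = texture_stats(comp)
        for stat in TEXTURE_ORDER:
            out[f"{stat}_{comp_name}"] = stats[stat]
    return out


def grad_features(le: np.ndarray, rc: np.ndarray) -> dict[str, float]:
    """GRAD set: 6 statistics x {Gmag, Gdir} x {LE, RC} = 24 values."""
    out: dict[str, float] = {}
    for src, roi in (("LE", le), ("RC", rc)):
        for name, value in grad_single(roi).items():
            out[f"{name}_{src}"] = value
    return out
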