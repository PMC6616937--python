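"""Interest-point, corner and region counts (the COUNT feature set).

The feature is the *number* of detections each of five classical detectors
produces on a ROI (descriptors are never used):

* ``SIFT``     — difference-of-Gaussian scale-space extrema;
* ``MinEigen`` — Shi-Tomasi minimum-eigenvalue corners;
* ``FAST``     — accelerated segment-test corners;
* ``BRISK``    — the BRISK detection stage, i.e. FAST-style segment-test
  corners searched over a coarse scale pyramid with per-scale non-maximum
  suppression;
* ``MSER``     — maximally stable extremal regions, found on the component
  tree of both polarities by locating local minima of the area-variation
  ratio q(t) = (|R(t+delta)| - |R(t-delta)|) / |R(t)|.

Detectors run on the ROI linearly rescaled to 8-bit.  A ROI too small or
too flat for a detector yields a count of 0 (logged), never an exception.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage
from skimage import transform
from skimage.feature import SIFT, corner_fast, corner_peaks, corner_shi_tomasi

from cesmcad.features.stats import rescale01

logger = logging.getLogger(__name__)

COUNT_ORDER = ("SIFT", "MinEigen", "FAST", "BRISK", "MSER")


@dataclasses.dataclass
class KeypointConfig:
    """Detector thresholds; defaults documented here are used everywhere.

    ``fast_threshold`` is relative to the [0, 1] intensity scale; ``n=9``
    is the standard segment-test arc length.  ``brisk_scales`` are the
    downscale factors of the detection pyramid (1 octave + intra-octaves).
    MSER settings follow common practice for small ROIs: stability window
    ``delta`` gray levels, area limits in pixels / fraction of the ROI, and
    a maximum admissible variation ratio.
    """

    fast_n: int = 9
    fast_threshold: float = 0.15
    mineigen_threshold_rel: float = 0.01
    peak_min_distance: int = 1
    brisk_scales: tuple[float, ...] = (1.0, 1 / 1.5, 1 / 2, 1 / 3, 1 / 4)
    mser_delta: int = 5
    mser_min_area: int = 10
    mser_max_area_frac: float = 0.25
    mser_max_variation: float = 0.25


def _to_unit(roi: np.ndarray) -> np.ndarray:
    """ROI linearly rescaled to 8-bit then mapped back to [0, 1]."""
    return np.round(rescale01(np.asarray(roi, dtype=float)) * 255.0) / 255.0


def _count_sift(img: np.ndarray) -> int:
    det = SIFT()
    det.detect(img)
    return int(len(det.keypoints))


def _count_mineigen(img: np.ndarray, cfg: KeypointConfig) -> int:
    resp = corner_shi_tomasi(img)
    peaks = corner_peaks(resp, min_distance=cfg.peak_min_distance,
                         threshold_rel=cfg.mineigen_threshold_rel)
    return int(len(peaks))


def _count_fast(img: np.ndarray, cfg: KeypointConfig) -> int:
    resp = corner_fast(img, n=cfg.fast_n, threshold=cfg.fast_threshold)
    peaks = corner_peaks(resp, min_distance=cfg.peak_min_distance)
    return int(len(peaks))


def _count_brisk(img: np.ndarray, cfg: KeypointConfig) -> int:
    total = 0
    for scale in cfg.brisk_scales:
        if scale == 1.0:
            scaled = img
        else:
            scaled = transform.rescale(img, scale, anti_aliasing=True)
        if min(scaled.shape) < 8:  # segment test needs a 7x7 support
            continue
        resp = corner_fast(scaled, n=cfg.fast_n, threshold=cfg.fast_threshold)
        total += len(corner_peaks(resp, min_distance=cfg.peak_min_distance))
    return int(total)


def _mser_one_polarity(img_u8: np.ndarray, cfg: KeypointConfig) -> int:
    """Count stable extremal regions of {x <= t} as t sweeps the gray levels."""
    flat = img_u8.ravel()
    n = flat.size
    max_area = cfg.mser_max_area_frac * n
    # canonical seed of a component = its (value, index)-minimal pixel
    order = np.argsort(flat, kind="stable")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    history: dict[int, list[tuple[int, int]]] = {}
    levels_present = np.unique(img_u8)
    for t in levels_present:
        mask = img_u8 <= t
        labels, _ = ndimage.label(mask, structure=structure)
        lab_flat = labels.ravel()
        in_order = order[mask.ravel()[order]]
        _, first_idx = np.unique(lab_flat[in_order], return_index=True)
        seeds = in_order[first_idx]
        sizes = np.bincount(lab_flat)
        for seed in seeds:
            history.setdefault(int(seed), []).append(
                (int(t), int(sizes[lab_flat[seed]]))
            )
    delta = cfg.mser_delta
    count = 0
    for records in history.values():
        lvls = np.array([r[0] for r in records])
        areas = np.array([r[1] for r in records], dtype=float)
        t_lo = int(lvls[0])
        # the branch stays alive (with constant area) until the level at
        # which it merges into a component with a lower-priority seed,
        # i.e. just before the next populated gray level after its last
        # record; the root branch simply ends at the last record
        pos = int(np.searchsorted(levels_present, lvls[-1], side="right"))
        t_hi = int(levels_present[pos]) - 1 if pos < len(levels_present) \
            else int(lvls[-1])
        if t_hi - t_lo < 2 * delta:
            continue
        # area is a step function of the threshold within the branch;
        # evaluate the variation ratio at every level the branch spans
        def area_at(t: np.ndarray) -> np.ndarray:
            return areas[np.searchsorted(lvls, t, side="right") - 1]

        tv = np.arange(t_lo + delta, t_hi - delta + 1)
        q = (area_at(tv + delta) - area_at(tv - delta)) / area_at(tv)
        a = area_at(tv)
        admissible = (q < cfg.mser_max_variation) & \
                     (a >= cfg.mser_min_area) & (a <= max_area)
        # local minima of the variation ratio along the branch
        for k in range(len(q)):
            if not admissible[k]:
                continue
            if k > 0 and q[k - 1] <= q[k] - 1e-12:
                continue
            if k + 1 < len(q) and q[k + 1] < q[k] - 1e-12:
                continue
            if k > 0 and abs(q[k - 1] - q[k]) <= 1e-12:
                continue  # count plateaus once, at their first level
            count += 1
    return count


def _count_mser(img: np.ndarray, cfg: KeypointConfig) -> int:
    img_u8 = np.round(img * 255.0).astype(np.int64)
    dark = _mser_one_polarity(img_u8, cfg)
    bright = _mser_one_polarity(255 - img_u8, cfg)
    return dark + bright


def count_single(roi: np.ndarray, config: KeypointConfig | None = None) -> dict[str, int]:
    """The five detector counts of a single ROI."""
    cfg = config or KeypointConfig()
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or min(roi.shape) < 8:
        raise ValueError("keypoint counting requires a 2-D ROI of at least 8x8")
    img = _to_unit(roi)
    runners = {
        "SIFT": lambda: _count_sift(img),
        "MinEigen": lambda: _count_mineigen(img, cfg),
        "FAST": lambda: _count_fast(img, cfg),
        "BRISK": lambda: _count_brisk(img, cfg),
        "MSER": lambda: _count_mser(img, cfg),
    }
    out: dict[str, int] = {}
    for name in COUNT_ORDER:
        try:
            out[name] = runners[name]()
        except Exception as exc:  # flat or undersized input for this detector
            logger.info("%s detector produced no keypoints (%s); count set to 0",
                        name, exc)
            out[name] = 0
    return out


def count_features(le: np.ndarray, rc: np.ndarray,
                   config: KeypointConfig | None = None) -> dict[str, int]:
    """COUNT set: 5 detector counts x {LE, RC} = 10 values."""
    out: dict[str, int] = {}
    for src, roi in (("LE", le), ("RC", rc)):
        for name, value in count_single(roi, config).items():
            out[f"{name}_{src}"] = value
    return out
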