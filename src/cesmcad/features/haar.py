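"""Two-level orthonormal Haar wavelet pyramid and the HAAR feature set.

The 2-D Haar transform splits an image into an approximation (LL) and three
directional detail bands; iterating on LL1 yields the level-2 bands.  The
pyramid keeps all eight sub-bands LL1, HL1, LH1, HH1, LL2, HL2, LH2, HH2.

Conventions
-----------
* orthonormal filters: low = (u + v)/sqrt(2), high = (u - v)/sqrt(2), so the
  transform preserves energy (Parseval) and a constant image ``c`` has
  ``LL1 = 2c``;
* sub-band names are (row-filter, column-filter): ``LH`` is low-pass along
  rows and high-pass along columns, i.e. it responds to vertical edges;
* odd dimensions are edge-padded to even size before each level, after
  which the transform is the exact non-overlapping 2x2 block transform
  (PyWavelets ``haar`` with ``periodization`` mode).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pywt

from cesmcad.features.stats import TEXTURE_ORDER, texture_stats

SUBBANDS = ("LL1", "HL1", "LH1", "HH1", "LL2", "HL2", "LH2", "HH2")
LEVEL1_DETAIL = ("HL1", "LH1", "HH1")

# pywt.dwtn key -> (row, col) filter letters
_KEY_TO_NAME = {"aa": "LL", "da": "HL", "ad": "LH", "dd": "HH"}


@dataclasses.dataclass
class HaarPyramid:
    """Mapping of the eight sub-band names to coefficient matrices."""

    subbands: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.subbands[name]

    def energy(self, names: tuple[str, ...]) -> float:
        return float(sum(np.sum(self.subbands[n] ** 2) for n in names))


def _pad_even(x: np.ndarray) -> np.ndarray:
    pr = x.shape[0] % 2
    pc = x.shape[1] % 2
    if pr or pc:
        x = np.pad(x, ((0, pr), (0, pc)), mode="edge")
    return x


def _dwt_level(x: np.ndarray) -> dict[str, np.ndarray]:
    coeffs = pywt.dwtn(_pad_even(x), "haar", mode="periodization")
    return {_KEY_TO_NAME[k]: v for k, v in coeffs.items()}


def haar_decompose(roi: np.ndarray, levels: int = 2) -> HaarPyramid:
    """Two-level Haar pyramid of a 2-D ROI (sides >= 4)."""
    roi = np.asarray(roi, dtype=float)
    if levels != 2:
        raise ValueError("this pipeline uses exactly two decomposition levels")
    if roi.ndim != 2 or min(roi.shape) < 4:
        raise ValueError("Haar decomposition requires a 2-D ROI of at least 4x4")
    level1 = _dwt_level(roi)
    level2 = _dwt_level(level1["LL"])
    subbands = {f"{name}1": mat for name, mat in level1.items()}
    subbands.update({f"{name}2": mat for name, mat in level2.items()})
    return HaarPyramid(subbands={name: subbands[name] for name in SUBBANDS})


def haar_reconstruct(pyramid: HaarPyramid) -> np.ndarray:
    """Invert the two-level decomposition (exact for even-sized inputs)."""
    inv = {v: k for k, v in _KEY_TO_NAME.items()}
    ll1 = pywt.idwtn(
        {inv[n]: pyramid[f"{n}2"] for n in ("LL", "HL", "LH", "HH")},
        "haar", mode="periodization",
    )
    level1 = {inv["LL"]: ll1}
    level1.update({inv[n]: pyramid[f"{n}1"] for n in ("HL", "LH", "HH")})
    return pywt.idwtn(level1, "haar", mode="periodization")


def haar_single(roi: np.ndarray) -> dict[str, float]:
    """48 HAAR statistics of one image: 6 statistics x 8 sub-bands."""
    pyramid = haar_decompose(roi)
    out: dict[str, float] = {}
    for band in SUBBANDS:
        stats = texture_stats(pyramid[band])
        for stat in TEXTURE_ORDER:
            out[f"{stat}_{band}"] = stats[stat]
    return out


def haar_features(le: np.ndarray, rc: np.ndarray) -> dict[str, float]:
    """HAAR set: 6 statistics x 8 sub-bands x {LE, RC} = 96 values."""
    out: dict[str, float] = {}
    for src, roi in (("LE", le), ("RC", rc)):
        for name, value in haar_single(roi).items():
            out[f"{name}_{src}"] = value
    return out
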