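"""Assembly of the full 464-feature vector and its canonical naming.

Canonical feature names are ``SET:Statistic[_Subband][_direction]_SRC``,
e.g. ``STAT:Variance_RC``, ``HAAR:Variance_LL2_RC``, ``GRAD:Mean_Gmag_LE``,
``GLCM:ClusterProminence_HL1_90_RC``, ``COUNT:SIFT_LE`` — mirroring the
reporting style used in frequency-ranking tables (feature set, statistic,
Haar sub-band / GLCM direction, ROI type).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from cesmcad.features.glcm import (
    DIRECTIONS_DEG,
    GLCM_STATS_ORDER,
    GlcmSpec,
    glcm_features,
)
from cesmcad.features.gradient import grad_features
from cesmcad.features.haar import SUBBANDS, LEVEL1_DETAIL, haar_features
from cesmcad.features.keypoints import COUNT_ORDER, KeypointConfig, count_features
from cesmcad.features.stats import STAT_ORDER, TEXTURE_ORDER, stat_features
from cesmcad.io_roi import METADATA_COLUMNS, RoiPair

SOURCES = ("LE", "RC")
SET_SIZES = {"STAT": 22, "COUNT": 10, "GRAD": 24, "HAAR": 96, "GLCM": 312}
N_FEATURES = 464


@dataclasses.dataclass(frozen=True)
class FeatureName:
    """Structured decomposition of a canonical feature name."""

    set_tag: str
    statistic: str
    subband: str = "none"
    direction_deg: str = "none"
    source: str = "LE"
    gradient_component: str = "none"

    def display(self) -> str:
        """Human-readable form used in selection reports."""
        stat = self.statistic
        if self.gradient_component != "none":
            stat = f"{stat}_{self.gradient_component}"
        elif self.subband != "none":
            stat = f"{stat}_{self.subband}"
        if self.direction_deg != "none":
            stat = f"{stat} (θ={self.direction_deg}°)"
        return stat


def feature_names() -> list[str]:
    """The 464 canonical feature names in fixed STAT|COUNT|GRAD|HAAR|GLCM order."""
    names: list[str] = []
    for src in SOURCES:
        names += [f"STAT:{s}_{src}" for s in STAT_ORDER]
    for src in SOURCES:
        names += [f"COUNT:{d}_{src}" for d in COUNT_ORDER]
    for src in SOURCES:
        names += [f"GRAD:{s}_{c}_{src}" for c in ("Gmag", "Gdir") for s in TEXTURE_ORDER]
    for src in SOURCES:
        names += [f"HAAR:{s}_{b}_{src}" for b in SUBBANDS for s in TEXTURE_ORDER]
    for src in SOURCES:
        names += [
            f"GLCM:{s}_{b}_{deg}_{src}"
            for b in LEVEL1_DETAIL for deg in DIRECTIONS_DEG for s in GLCM_STATS_ORDER
        ]
    assert len(names) == N_FEATURES and len(set(names)) == N_FEATURES
    return names


def parse_feature_name(name: str) -> FeatureName:
    set_tag, rest = name.split(":", 1)
    parts = rest.split("_")
    source = parts[-1]
    body = parts[:-1]
    if set_tag in ("STAT", "COUNT"):
        return FeatureName(set_tag, "_".join(body), source=source)
    if set_tag == "GRAD":
        return FeatureName(set_tag, "_".join(body[:-1]), source=source,
                           gradient_component=body[-1])
    if set_tag == "HAAR":
        return FeatureName(set_tag, "_".join(body[:-1]), subband=body[-1],
                           source=source)
    if set_tag == "GLCM":
        return FeatureName(set_tag, "_".join(body[:-2]), subband=body[-2],
                           direction_deg=body[-1], source=source)
    raise ValueError(f"unrecognized feature name {name!r}")


def extract_all(pair: RoiPair,
                keypoint_config: KeypointConfig | None = None,
                glcm_spec: GlcmSpec | None = None) -> dict[str, float]:
    """All 464 named features of one LE/RC ROI pair, in canonical order.

    Deterministic for a fixed input and configuration; any extractor failure
    aborts the row with a diagnostic naming the feature set.
    """
    le, rc = pair.le, pair.rc
    blocks: dict[str, dict[str, float]] = {}
    extractors = {
        "STAT": lambda: {f"{k}_{src}": v for src, roi in (("LE", le), ("RC", rc))
                         for k, v in stat_features(roi).items()},
        "COUNT": lambda: {k: float(v)
                          for k, v in count_features(le, rc, keypoint_config).items()},
        "GRAD": lambda: grad_features(le, rc),
        "HAAR": lambda: haar_features(le, rc),
        "GLCM": lambda: glcm_features(le, rc, glcm_spec),
    }
    for set_tag, fn in extractors.items():
        try:
            blocks[set_tag] = fn()
        except Exception as exc:
            raise RuntimeError(f"{set_tag} feature extraction failed: {exc}") from exc
    row = {}
    for name in feature_names():
        set_tag, local = name.split(":", 1)
        row[name] = float(blocks[set_tag][local])
    return row


def extract_table(pairs: list[RoiPair],
                  keypoint_config: KeypointConfig | None = None,
                  glcm_spec: GlcmSpec | None = None) -> pd.DataFrame:
    """Feature table of many pairs: metadata columns then 464 feature columns."""
    rows = []
    for pair in pairs:
        row: dict[str, object] = {
            "patient_id": pair.patient_id,
            "label": pair.label,
            "bpe_class": pair.bpe_class,
        }
        row.update(extract_all(pair, keypoint_config, glcm_spec))
        rows.append(row)
    columns = METADATA_COLUMNS + feature_names()
    table = pd.DataFrame(rows, columns=columns)
    if rows:
        feats = table[feature_names()].to_numpy(dtype=float)
        if not np.all(np.isfinite(feats)):
            bad = np.array(feature_names())[~np.isfinite(feats).all(axis=0)]
            raise RuntimeError(f"non-finite features extracted: {bad[:5]}")
    return table
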