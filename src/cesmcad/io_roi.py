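"""Image input, ROI cropping and feature-table persistence.

ROIs are rectangular crops identified by a radiologist with a bounding box;
the same box is applied to the low-energy and the recombined image of the
same view (the two are acquired in one compression, so no registration is
attempted).  Coordinates are 0-based and half-open, matching array slicing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

VALID_LABELS = frozenset({"benign", "malignant", "normal", "abnormal"})
VALID_BPE = ("I", "II", "III-IV")
VALID_VIEWS = ("CC", "MLO", "unknown")

#: metadata columns that lead every feature table, in order
METADATA_COLUMNS = ["patient_id", "label", "bpe_class"]


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """0-based, half-open rectangle [row_start, row_stop) x [col_start, col_stop)."""

    row_start: int
    col_start: int
    row_stop: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("bounding box indices must be non-negative")
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("bounding box must satisfy stop > start on both axes")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)


@dataclasses.dataclass
class RoiPair:
    """One sample: matched LE and RC ROIs plus label and acquisition metadata.

    ``le`` and ``rc`` must have identical shape with both sides >= 8 px and
    finite non-negative intensities.  ``bpe_class`` follows the three-category
    background-parenchymal-enhancement scheme: minimal (I), mild (II),
    moderate-or-marked (III-IV).
    """

    patient_id: str
    le: np.ndarray
    rc: np.ndarray
    label: str
    bpe_class: str = "I"
    view: str = "unknown"

    def __post_init__(self) -> None:
        self.le = np.asarray(self.le, dtype=float)
        self.rc = np.asarray(self.rc, dtype=float)
        if self.le.ndim != 2 or self.rc.ndim != 2:
            raise ValueError("LE and RC ROIs must be 2-D")
        if self.le.shape != self.rc.shape:
            raise ValueError(
                f"LE shape {self.le.shape} != RC shape {self.rc.shape}"
            )
        if min(self.le.shape) < 8:
            raise ValueError("ROI sides must be at least 8 pixels")
        for name, arr in (("LE", self.le), ("RC", self.rc)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} ROI contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} ROI contains negative intensities")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label {self.label!r} not in {sorted(VALID_LABELS)}")
        if self.bpe_class not in VALID_BPE:
            raise ValueError(f"bpe_class {self.bpe_class!r} not in {VALID_BPE}")
        if self.view not in VALID_VIEWS:
            raise ValueError(f"view {self.view!r} not in {VALID_VIEWS}")

    def swapped(self) -> "RoiPair":
        """Return a copy with LE and RC exchanged (used for symmetry checks)."""
        return RoiPair(self.patient_id, self.rc.copy(), self.le.copy(),
                       self.label, self.bpe_class, self.view)


def read_image(path, format: str | None = None) -> np.ndarray:
    """Read a single-frame grayscale image as a float matrix.

    Supported formats: DICOM, PNG, TIFF.  The numeric values of the stored
    array are preserved (an 8-bit PNG reads back with max <= 255, a 16-bit
    DICOM with its stored integers).  Color or multi-frame inputs are
    rejected rather than converted: CESM ROIs are single-channel.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if format is None:
        ext = path.suffix.lower()
        format = {".dcm": "dicom", ".dicom": "dicom", ".png": "png",
                  ".tif": "tiff", ".tiff": "tiff"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer image format from suffix {ext!r}")
    if format == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise ValueError("color DICOM input is unsupported")
        if int(getattr(ds, "NumberOfFrames", 1)) != 1:
            raise ValueError("multi-frame DICOM input is unsupported")
        arr = ds.pixel_array
    elif format in ("png", "tiff"):
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[0] > 1 and format == "tiff":
            raise ValueError("multi-frame TIFF input is unsupported")
        if arr.ndim != 2:
            raise ValueError("color or multi-channel image input is unsupported")
    else:
        raise ValueError(f"unsupported format {format!r}")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a single-frame grayscale image")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("image contains non-finite or negative values")
    return arr


def write_image(image: np.ndarray, path) -> None:
    """Write a non-negative matrix as a 16-bit PNG/TIFF (rounded)."""
    import imageio.v3 as iio

    arr = np.asarray(image, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("image must be finite and non-negative")
    iio.imwrite(Path(path), np.round(np.clip(arr, 0, 65535)).astype(np.uint16))


def extract_roi(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Crop ``box`` out of ``image``; the result is a copy, never a view."""
    image = np.asarray(image)
    rows, cols = image.shape
    if box.row_stop > rows or box.col_stop > cols:
        raise IndexError(
            f"bounding box {box} exceeds image of shape {image.shape}"
        )
    return image[box.row_start:box.row_stop, box.col_start:box.col_stop].copy()


def validate_feature_table(table: pd.DataFrame) -> None:
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature-table columns: {dupes}")
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing metadata columns: {missing}")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV (one header row, metadata columns first)."""
    validate_feature_table(table)
    ordered = METADATA_COLUMNS + [c for c in table.columns if c not in METADATA_COLUMNS]
    table[ordered].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_feature_table(table)
    return table


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the metadata columns, leaving only numeric feature columns."""
    return table.drop(columns=[c for c in METADATA_COLUMNS if c in table.columns])
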