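"""Seeded phantom generator for LE/RC ROI pairs.

The generator emulates the data regime the pipeline is built for, without
any patient data:

* the low-energy (LE) channel is dense parenchyma: a smoothed Gaussian
  random field around a bright baseline;
* the recombined (RC) channel is a low baseline plus patchy background
  parenchymal enhancement (BPE) whose mean level and patch variance grow
  with the BPE class (I < II < III-IV);
* lesions are star-convex blobs (a random ellipse whose boundary radius is
  perturbed by a low-order Fourier series) added to RC at full contrast and
  to LE attenuated by a masking factor — on LE a lesion hides in the dense
  parenchyma, on RC it enhances;
* malignant lesions differ from benign ones in margin irregularity and
  intra-lesion texture heterogeneity, the two axes the radiomic features
  target; the enhancement amplitude itself is class-independent.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from cesmcad.io_roi import RoiPair, write_image, read_image

#: documented RC background mean targets (intensity units) per BPE class
RC_MEAN_TARGET = {"I": 30.0, "II": 55.0, "III-IV": 90.0}
_RC_BASE = 15.0
_LE_BASE = 120.0
_LE_TEXTURE_AMPLITUDE = 20.0

#: default BPE class mix (approximately the availability of all three
#: classes in a screening-recall population, minimal being the most common)
DEFAULT_BPE_PROPORTIONS = {"I": 0.5, "II": 0.25, "III-IV": 0.25}


@dataclasses.dataclass
class PhantomConfig:
    """Phantom study conditions.

    Defaults define the generator's documented operating point: 64 px ROIs,
    24 samples per class (the balanced design used throughout), lesion
    contrast 60 intensity units on RC with 70% masking on LE, additive
    noise sigma 6.  Margin irregularity is the relative radial-perturbation
    amplitude of the lesion boundary and texture heterogeneity the relative
    intra-lesion noise scale; malignant lesions use the higher values.
    """

    roi_size: int = 64
    n_per_class: int = 24
    class_mode: str = "benign_vs_malignant"  # or "lesion_vs_background"
    bpe_proportions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BPE_PROPORTIONS))
    lesion_contrast: float = 60.0
    margin_irregularity_benign: float = 0.08
    margin_irregularity_malignant: float = 0.35
    texture_heterogeneity_benign: float = 0.10
    texture_heterogeneity_malignant: float = 0.40
    le_masking: float = 0.7
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_size < 16:
            raise ValueError("roi_size must be at least 16")
        if self.class_mode not in ("benign_vs_malignant", "lesion_vs_background"):
            raise ValueError(f"unknown class_mode {self.class_mode!r}")
        for f in ("lesion_contrast", "margin_irregularity_benign",
                  "margin_irregularity_malignant", "texture_heterogeneity_benign",
                  "texture_heterogeneity_malignant", "noise_sigma"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if not 0.0 <= self.le_masking <= 1.0:
            raise ValueError("le_masking must lie in [0, 1]")


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance smoothed Gaussian random field."""
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_background(config: PhantomConfig, bpe_level: str = "I",
                        seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """LE and RC background fields (no lesion) for one phantom sample.

    The RC patch field is normalized so its pre-noise mean hits the
    documented :data:`RC_MEAN_TARGET` for the BPE class exactly.
    """
    if bpe_level not in RC_MEAN_TARGET:
        raise ValueError(f"unknown BPE class {bpe_level!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    size = config.roi_size
    le = (_LE_BASE + _LE_TEXTURE_AMPLITUDE * _smooth_field(rng, size, 4.0)
          + config.noise_sigma * rng.standard_normal((size, size)))
    patches = np.clip(_smooth_field(rng, size, 6.0), 0.0, None)
    if patches.mean() > 0:
        patches = patches / patches.mean()
    amplitude = RC_MEAN_TARGET[bpe_level] - _RC_BASE
    rc = (_RC_BASE + amplitude * patches
          + config.noise_sigma * rng.standard_normal((size, size)))
    return np.clip(le, 0.0, None), np.clip(rc, 0.0, None)


def _lesion_field(rng: np.random.Generator, size: int,
                  margin_irregularity: float,
                  texture_heterogeneity: float) -> np.ndarray:
    """Soft star-convex lesion mask times intra-lesion texture, in [0, ~]."""
    cy, cx = (size - 1) / 2 + rng.uniform(-size / 10, size / 10, size=2)
    r0 = size * rng.uniform(0.16, 0.22)
    aspect = rng.uniform(0.7, 1.0)
    phi = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    dist = np.hypot(u / 1.0, v / aspect)
    theta = np.arctan2(v / aspect, u)
    # low-order Fourier perturbation of the boundary radius
    harmonics = np.arange(2, 7)
    coeffs = rng.standard_normal((2, len(harmonics))) / np.sqrt(harmonics)
    norm = np.sqrt(np.sum(coeffs ** 2) / 2) or 1.0
    perturb = sum(
        coeffs[0, k] * np.cos(h * theta) + coeffs[1, k] * np.sin(h * theta)
        for k, h in enumerate(harmonics)
    ) / norm
    r_boundary = r0 * np.clip(1.0 + margin_irregularity * perturb, 0.2, None)
    soft = np.clip((r_boundary - dist) / 1.5 + 0.5, 0.0, 1.0)
    texture = 1.0 + texture_heterogeneity * _smooth_field(rng, size, 1.5)
    return soft * np.clip(texture, 0.0, None)


def generate_lesion_pair(config: PhantomConfig, class_label: str,
                         bpe_level: str = "I", seed: int | None = None,
                         patient_id: str = "P000") -> RoiPair:
    """One ROI pair with a lesion of the given class added to the background.

    ``benign``/``malignant`` (or ``abnormal``, which reuses the malignant
    morphology) lesions share the same RC contrast amplitude; they differ
    in margin irregularity and texture heterogeneity.  ``normal`` yields a
    pure background pair.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bg_seed = int(rng.integers(2 ** 31))
    lesion_seed = int(rng.integers(2 ** 31))
    le, rc = generate_background(config, bpe_level, seed=bg_seed)
    if class_label != "normal":
        if class_label == "benign":
            margin = config.margin_irregularity_benign
            texture = config.texture_heterogeneity_benign
        elif class_label in ("malignant", "abnormal"):
            margin = config.margin_irregularity_malignant
            texture = config.texture_heterogeneity_malignant
        else:
            raise ValueError(f"unknown class label {class_label!r}")
        lesion = _lesion_field(np.random.default_rng(lesion_seed),
                               config.roi_size, margin, texture)
        rc = rc + config.lesion_contrast * lesion
        le = le + config.lesion_contrast * (1.0 - config.le_masking) * lesion
    label = class_label if class_label != "abnormal" else "abnormal"
    return RoiPair(patient_id=patient_id, le=np.clip(le, 0, None),
                   rc=np.clip(rc, 0, None), label=label, bpe_class=bpe_level)


def _bpe_assignment(n: int, proportions: dict) -> list[str]:
    """Deterministic largest-remainder allocation of n samples to BPE classes."""
    classes = list(proportions)
    ideal = np.array([proportions[c] * n for c in classes])
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for k in np.argsort(-remainder)[: n - counts.sum()]:
        counts[k] += 1
    out: list[str] = []
    for c, k in zip(classes, counts):
        out += [c] * k
    return out


def generate_dataset(config: PhantomConfig) -> list[RoiPair]:
    """Balanced, reproducible list of phantom ROI pairs.

    ``benign_vs_malignant`` mode yields ``n_per_class`` lesion pairs per
    class; ``lesion_vs_background`` yields ``normal`` background-only pairs
    and ``abnormal`` lesion pairs.  BPE classes are assigned within each
    class by the configured proportions.
    """
    if config.n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if config.class_mode == "benign_vs_malignant":
        class_labels = ("benign", "malignant")
    else:
        class_labels = ("normal", "abnormal")
    sample_seeds = np.random.SeedSequence(config.seed) \
        .generate_state(2 * config.n_per_class) % (2 ** 31)
    pairs: list[RoiPair] = []
    idx = 0
    for label in class_labels:
        bpes = _bpe_assignment(config.n_per_class, config.bpe_proportions)
        for bpe in bpes:
            pairs.append(generate_lesion_pair(
                config, label, bpe_level=bpe, seed=int(sample_seeds[idx]),
                patient_id=f"P{idx:03d}"))
            idx += 1
    return pairs


# ---------------------------------------------------------------------------
# on-disk phantom datasets (paired PNGs plus a manifest CSV)

def write_dataset(pairs: list[RoiPair], outdir) -> Path:
    """Write phantom pairs as 16-bit PNGs plus a manifest CSV; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in pairs:
        le_path = outdir / f"{pair.patient_id}_LE.png"
        rc_path = outdir / f"{pair.patient_id}_RC.png"
        write_image(pair.le, le_path)
        write_image(pair.rc, rc_path)
        rows.append({"patient_id": pair.patient_id, "label": pair.label,
                     "bpe_class": pair.bpe_class, "le_path": le_path.name,
                     "rc_path": rc_path.name})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest_path) -> list[RoiPair]:
    """Read phantom pairs back from a manifest CSV (skips unreadable pairs
    with a warning)."""
    import logging

    logger = logging.getLogger(__name__)
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    pairs: list[RoiPair] = []
    for _, row in table.iterrows():
        try:
            le = read_image(base / row["le_path"])
            rc = read_image(base / row["rc_path"])
            pairs.append(RoiPair(patient_id=str(row["patient_id"]), le=le, rc=rc,
                                 label=row["label"], bpe_class=row["bpe_class"]))
        except Exception as exc:
            logger.warning("skipping %s: %s", row["patient_id"], exc)
    return pairs
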