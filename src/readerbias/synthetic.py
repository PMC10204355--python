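"""Seeded two-class grayscale image generator.

Emulates a "normal vs. lesion" contrast: both classes share a flat background
with additive Gaussian pixel noise; class 1 additionally carries a small number
of soft, isotropic Gaussian opacities at random positions. The contrast-to-noise
ratio (``blob_amplitude`` / ``noise_sd``) controls class separability, so the
achievable test AUC is tunable below 1.0 — mimicking a realistic radiological
task rather than a toy separable one.

Every image is a pure function of (dataset seed, row index), so regenerating a
dataset with one count changed does not reshuffle the other images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import ConfigurationError
from .manifest import validate_manifest, write_manifest


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and contrast of the synthetic images.

    Defaults are calibrated so that a small CNN trained on clean labels at
    desk scale reaches a test AUC in the mid-0.9s — discriminable but
    imperfect, like a real radiological task — leaving visible headroom for
    label noise to erode.
    """

    side_px: int = 32
    background_level: float = 0.3
    noise_sd: float = 0.10
    n_blobs_range: tuple[int, int] = (1, 3)
    blob_amplitude: float = 0.12
    blob_sigma_px: float = 3.0

    def __post_init__(self) -> None:
        if self.side_px < 8:
            raise ConfigurationError(f"side_px must be >= 8, got {self.side_px}")
        if not 0.0 <= self.background_level <= 1.0:
            raise ConfigurationError(
                f"background_level must be in [0,1], got {self.background_level}"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.blob_amplitude < 0:
            raise ConfigurationError(
                f"blob_amplitude must be >= 0, got {self.blob_amplitude}"
            )
        lo, hi = self.n_blobs_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(
                f"n_blobs_range must satisfy 1 <= lo <= hi, got {self.n_blobs_range}"
            )
        if self.blob_sigma_px <= 0:
            raise ConfigurationError(
                f"blob_sigma_px must be > 0, got {self.blob_sigma_px}"
            )


@dataclass(frozen=True)
class DatasetSpec:
    """Counts per split plus the image model and the master seed.

    The test split may be class-unbalanced (given as a per-class pair); AUC is
    prevalence-insensitive so this is safe for evaluation.
    """

    n_train_per_class: int = 500
    n_val_per_class: int = 109
    n_test: tuple[int, int] = (234, 390)  # (class 0, class 1)
    seed: int = 0
    image_spec: ImageSpec = field(default_factory=ImageSpec)

    def __post_init__(self) -> None:
        counts = (self.n_train_per_class, self.n_val_per_class, *self.n_test)
        if any(c < 1 for c in counts):
            raise ConfigurationError(f"all split counts must be >= 1, got {counts}")


def generate_image(
    class_label: int, image_spec: ImageSpec, rng: np.random.Generator
) -> np.ndarray:
    """One grayscale image in [0,1] for the given class.

    Class 0 is background plus noise; class 1 adds ``n`` Gaussian bumps with
    ``n`` drawn uniformly from ``n_blobs_range`` and centers uniform over the
    image. Pixel values are clipped to [0,1].
    """
    if class_label not in (0, 1):
        raise ConfigurationError(f"class_label must be 0 or 1, got {class_label}")
    s = image_spec.side_px
    img = np.full((s, s), image_spec.background_level, dtype=np.float64)
    img += rng.normal(0.0, image_spec.noise_sd, size=(s, s))
    if class_label == 1:
        lo, hi = image_spec.n_blobs_range
        n_blobs = int(rng.integers(lo, hi + 1))
        yy, xx = np.mgrid[0:s, 0:s]
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, s, size=2)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            img += image_spec.blob_amplitude * np.exp(
                -d2 / (2.0 * image_spec.blob_sigma_px**2)
            )
    return np.clip(img, 0.0, 1.0)


def _image_rng(dataset_seed: int, row_index: int) -> np.random.Generator:
    # per-image stream keyed by (seed, row); independent of all other rows
    return np.random.default_rng(np.random.SeedSequence([dataset_seed, row_index]))


def manifest_rows(spec: DatasetSpec) -> pd.DataFrame:
    """The deterministic (split, class, row-index) layout of a dataset.

    Row order is fixed: train 0s, train 1s, val 0s, val 1s, test 0s, test 1s.
    """
    layout = [
        ("train", 0, spec.n_train_per_class),
        ("train", 1, spec.n_train_per_class),
        ("val", 0, spec.n_val_per_class),
        ("val", 1, spec.n_val_per_class),
        ("test", 0, spec.n_test[0]),
        ("test", 1, spec.n_test[1]),
    ]
    records = []
    row = 0
    for split, label, count in layout:
        for _ in range(count):
            records.append(
                {
                    "image_path": f"images/{split}_{label}_{row:05d}.png",
                    "split": split,
                    "true_label": label,
                    "biased_label": pd.NA,
                }
            )
            row += 1
    return validate_manifest(pd.DataFrame.from_records(records))


def generate_dataset(spec: DatasetSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write PNG images plus ``manifest.csv`` under ``out_dir``; return the manifest.

    Deterministic: the same spec (including seed) yields byte-identical
    manifests and identical 8-bit image files.
    """
    out_dir = Path(out_dir)
    manifest = manifest_rows(spec)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    for row_index, rec in enumerate(manifest.itertuples(index=False)):
        img = generate_image(
            int(rec.true_label), spec.image_spec, _image_rng(spec.seed, row_index)
        )
        img8 = np.round(img * 255.0).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out_dir / rec.image_path)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image file back to a float array in [0,1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


def max_pixel_score(img: np.ndarray) -> float:
    """A model-free lesion score: the brightest pixel.

    Useful as an analytic benchmark of class separability — bright localized
    opacities raise the maximum, so higher values indicate class 1.
    """
    return float(np.max(img))
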