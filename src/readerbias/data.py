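"""Loading manifest images into preprocessed arrays, with a per-path cache."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .losses import preprocess
from .manifest import training_labels
from .synthetic import load_image


class ImageStore:
    """Reads and preprocesses manifest images, caching by path.

    The cache makes experiment grids cheap: bias injection changes labels only,
    so every cell of the grid shares the same preprocessed pixel arrays.
    """

    def __init__(self, root: str | Path, input_side_px: int):
        self.root = Path(root)
        self.input_side_px = input_side_px
        self._cache: dict[str, np.ndarray] = {}

    def image(self, rel_path: str) -> np.ndarray:
        if rel_path not in self._cache:
            self._cache[rel_path] = preprocess(
                load_image(self.root / rel_path), self.input_side_px
            )
        return self._cache[rel_path]

    def stack(self, manifest: pd.DataFrame, split: str) -> np.ndarray:
        """Preprocessed (N, 3, side, side) array for one split, in row order."""
        paths = manifest.loc[manifest["split"] == split, "image_path"]
        return np.stack([self.image(p) for p in paths]).astype(np.float32)


def split_labels(manifest: pd.DataFrame, split: str, *, true: bool) -> np.ndarray:
    """Labels of one split: the true labels, or the ones the model trains on."""
    if true:
        return (
            manifest.loc[manifest["split"] == split, "true_label"]
            .astype(int)
            .to_numpy()
        )
    return training_labels(manifest, split)["label"].to_numpy()
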