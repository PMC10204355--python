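"""Preprocessing, paired augmentation, and the loss functions.

The baseline classifier minimizes mean cross-entropy against the (possibly
biased) labels. The improved classifier adds paired softmax divergence
regularization (PSDR): the batch-mean KL divergence between the model's
predicted class distributions for two independently augmented views of each
training image, weighted by a hyperparameter alpha. Because the penalty never
consults the labels, it resists label noise: it rewards prediction consistency
under augmentation rather than agreement with (potentially wrong) annotations.

Total loss:  L = L_cross_entropy + alpha * L_PSDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .exceptions import ConfigurationError, ValidationError

#: Intensity normalization applied after resizing, v -> (v - MEAN) / SD.
NORM_MEAN = 0.5
NORM_SD = 0.2365


@dataclass(frozen=True)
class LossConfig:
    """PSDR weight plus augmentation settings.

    ``alpha = 0`` reduces the improved model to the baseline exactly. Flip
    probabilities of 0.5 give all four flip orientations equal mass.
    """

    alpha: float = 1.0
    horizontal_flip_p: float = 0.5
    vertical_flip_p: float = 0.5
    kl_epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha}")
        for name in ("horizontal_flip_p", "vertical_flip_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")
        if self.kl_epsilon <= 0:
            raise ConfigurationError(
                f"kl_epsilon must be > 0, got {self.kl_epsilon}"
            )


def preprocess(image: np.ndarray, input_side_px: int) -> np.ndarray:
    """Resize, replicate to 3 channels, and normalize one grayscale image.

    Input is a 2-D array in [0,1]; output is (3, side, side) float64 with
    values transformed v -> (v - 0.5) / 0.2365.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValidationError(f"expected a nonempty 2-D image, got shape {image.shape}")
    if not np.isfinite(image).all():
        raise ValidationError("image contains non-finite pixel values")
    if image.shape != (input_side_px, input_side_px):
        image = resize(
            image, (input_side_px, input_side_px), anti_aliasing=True, mode="reflect"
        )
    normed = (image - NORM_MEAN) / NORM_SD
    return np.broadcast_to(normed, (3, input_side_px, input_side_px)).copy()


def random_flips(
    batch: np.ndarray, config: LossConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply per-image random horizontal then vertical flips to (N,C,H,W)."""
    out = batch.copy()
    n = len(batch)
    h = rng.random(n) < config.horizontal_flip_p
    v = rng.random(n) < config.vertical_flip_p
    out[h] = out[h][:, :, :, ::-1]
    out[v] = out[v][:, :, ::-1, :]
    return out


def make_augmented_pair(
    image: np.ndarray, config: LossConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented views of one preprocessed image.

    Each view draws its flips from its own substream of ``rng``, so the views
    are independent given the source image.
    """
    batch = image[None]
    view_a = random_flips(batch, config, rng)[0]
    view_b = random_flips(batch, config, rng)[0]
    return view_a, view_b


def _check_prob(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D probability vector")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(f"{name} is not a probability vector: {p}")
    return p


def kl_divergence(p: np.ndarray, q: np.ndarray, epsilon: float = 1e-8) -> float:
    """KL(p || q) = sum_k p_k log(p_k / q_k), natural log, with epsilon clamping.

    Nonnegative (Gibbs' inequality); zero iff p == q up to the clamp.
    """
    p = _check_prob(p, "p")
    q = _check_prob(q, "q")
    if p.shape != q.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {q.shape}")
    pc = np.clip(p, epsilon, None)
    qc = np.clip(q, epsilon, None)
    return float(np.sum(p * (np.log(pc) - np.log(qc))))


def kl_divergence_rows(
    p: np.ndarray, q: np.ndarray, epsilon: float = 1e-8
) -> np.ndarray:
    """Row-wise KL(p_i || q_i) for two (N, K) probability arrays (vectorized)."""
    pc = np.clip(p, epsilon, None)
    qc = np.clip(q, epsilon, None)
    return np.sum(p * (np.log(pc) - np.log(qc)), axis=-1)


def psdr_loss(
    pairs: list[tuple[np.ndarray, np.ndarray]], epsilon: float = 1e-8
) -> float:
    """Batch-mean KL divergence between paired predicted distributions.

    Each element of ``pairs`` holds the model outputs for the two augmented
    views of one source image. Zero for an augmentation-invariant model.
    """
    if len(pairs) == 0:
        raise ValidationError("psdr_loss requires a nonempty batch of pairs")
    return float(
        np.mean([kl_divergence(pa, pb, epsilon) for pa, pb in pairs])
    )


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of (N,2) logits against binary labels."""
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError(f"labels must be 0/1, got {np.unique(labels)}")
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(labels)), labels].mean())


def total_loss(
    logits: np.ndarray, labels: np.ndarray, psdr_value: float, alpha: float
) -> float:
    """Cross-entropy + alpha * PSDR; the training objective."""
    if alpha < 0:
        raise ConfigurationError(f"alpha must be >= 0, got {alpha}")
    return cross_entropy(logits, labels) + alpha * psdr_value
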