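"""Training loop: Adam, fixed learning rate, epoch cap with a training-progress
early stop, and alpha tuning on the validation set.

The protocol mirrors common practice for small medical-image classifiers:
Adam at 1e-3, up to 50 epochs, stopping once neither the training loss nor the
training accuracy has improved for ``patience`` consecutive epochs. The PSDR
weight alpha is selected by grid search, refitting from identical seeds per
candidate and choosing the value that maximizes validation AUC (ties go to the
smaller, less regularized alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adam, SmallCNN, softmax
from .data import ImageStore, split_labels
from .exceptions import ConfigurationError, TrainingDivergenceError
from .losses import LossConfig, random_flips
from .metrics import roc_auc
from .models import ModelSpec, build_model


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 32
    patience: int = 5
    min_loss_delta: float = 1e-4
    alpha_grid: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 5.0)
    repetition_seed: int = 42

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ConfigurationError(f"lr must be > 0, got {self.lr}")
        if self.max_epochs < 1:
            raise ConfigurationError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.patience < 1:
            raise ConfigurationError(f"patience must be >= 1, got {self.patience}")
        if len(self.alpha_grid) == 0:
            raise ConfigurationError("alpha_grid must be nonempty")


@dataclass
class TrainResult:
    model: SmallCNN
    history: pd.DataFrame  # epoch, train_loss, train_accuracy, val_accuracy, val_auc


def _epoch_pass(
    model: SmallCNN,
    optimizer: Adam,
    x: np.ndarray,
    y: np.ndarray,
    loss_config: LossConfig,
    batch_size: int,
    rng_order: np.random.Generator,
    rng_aug_a: np.random.Generator,
    rng_aug_b: np.random.Generator,
    epoch: int,
) -> float:
    """One optimization epoch; returns the running mean training loss."""
    n = len(x)
    order = rng_order.permutation(n)
    total_loss_sum = 0.0
    alpha = loss_config.alpha
    eps = loss_config.kl_epsilon
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        xb, yb = x[idx], y[idx]
        b = len(idx)
        view_a = random_flips(xb, loss_config, rng_aug_a)
        logits_a, caches_a = model.forward(view_a)
        pa = softmax(logits_a)

        # mean cross-entropy and its gradient w.r.t. logits_a
        onehot = np.eye(2)[yb]
        zmax = logits_a.max(axis=1, keepdims=True)
        logp = logits_a - zmax - np.log(
            np.exp(logits_a - zmax).sum(axis=1, keepdims=True)
        )
        ce = float(-logp[np.arange(b), yb].mean())
        dlogits_a = ((pa - onehot) / b).astype(xb.dtype)

        psdr = 0.0
        grads_b = None
        if alpha > 0:
            view_b = random_flips(xb, loss_config, rng_aug_b)
            logits_b, caches_b = model.forward(view_b)
            pb = softmax(logits_b)
            log_ratio = np.log(np.clip(pa, eps, None)) - np.log(np.clip(pb, eps, None))
            kl_rows = np.sum(pa * log_ratio, axis=1)
            psdr = float(kl_rows.mean())
            # d KL(pa||pb) / d logits_a = pa * (log_ratio - KL_row)
            dlogits_a += (alpha * pa * (log_ratio - kl_rows[:, None]) / b).astype(
                xb.dtype
            )
            dlogits_b = (alpha * (pb - pa) / b).astype(xb.dtype)
            grads_b = model.backward(dlogits_b, caches_b)

        batch_loss = ce + alpha * psdr
        if not np.isfinite(batch_loss):
            raise TrainingDivergenceError(
                f"non-finite loss ({batch_loss}) at epoch {epoch}"
            )
        grads = model.backward(dlogits_a, caches_a)
        if grads_b is not None:
            grads = [ga + gb for ga, gb in zip(grads, grads_b)]
        optimizer.step(grads)

        total_loss_sum += batch_loss * b
    return total_loss_sum / n


def train_model(
    manifest: pd.DataFrame,
    model_spec: ModelSpec,
    loss_config: LossConfig,
    train_config: TrainConfig,
    images_root: str | Path | None = None,
    store: ImageStore | None = None,
) -> TrainResult:
    """Fit a model on the (image, biased-or-true label) pairs of the train split.

    Fully seeded: weight init from ``model_spec.weight_init_seed``; data order
    and the two augmentation streams from ``train_config.repetition_seed``.
    Validation metrics are recorded every epoch against the validation split's
    training-time labels (biased if the bias model targeted validation).
    """
    if store is None:
        if images_root is None:
            raise ConfigurationError("provide images_root or an ImageStore")
        store = ImageStore(images_root, model_spec.input_side_px)
    if not (manifest["split"] == "train").any():
        raise ConfigurationError("train split is empty")

    x_train = store.stack(manifest, "train")
    y_train = split_labels(manifest, "train", true=False)
    has_val = (manifest["split"] == "val").any()
    if has_val:
        x_val = store.stack(manifest, "val")
        y_val = split_labels(manifest, "val", true=False)

    model = build_model(model_spec)
    optimizer = Adam(model.params, lr=train_config.lr)
    ss = np.random.SeedSequence(train_config.repetition_seed)
    rng_order, rng_aug_a, rng_aug_b = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    records = []
    best_loss = np.inf
    best_acc = -np.inf
    stall = 0
    for epoch in range(1, train_config.max_epochs + 1):
        train_loss = _epoch_pass(
            model,
            optimizer,
            x_train,
            y_train,
            loss_config,
            train_config.batch_size,
            rng_order,
            rng_aug_a,
            rng_aug_b,
            epoch,
        )
        # end-of-epoch accuracy on the (un-augmented) training inputs against
        # the training-time labels — the curve a Fig-2-style plot shows
        train_proba = model.predict_proba(x_train)
        train_acc = float((train_proba.argmax(axis=1) == y_train).mean())
        val_acc = val_auc = np.nan
        if has_val:
            proba = model.predict_proba(x_val)
            val_acc = float((proba.argmax(axis=1) == y_val).mean())
            if 0 < y_val.sum() < len(y_val):
                val_auc = roc_auc(proba[:, 1], y_val)
        records.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_accuracy": train_acc,
                "val_accuracy": val_acc,
                "val_auc": val_auc,
            }
        )
        # early stop: no loss decrease >= delta AND no accuracy increase,
        # for `patience` consecutive epochs
        improved = (
            train_loss <= best_loss - train_config.min_loss_delta
            or train_acc > best_acc
        )
        best_loss = min(best_loss, train_loss)
        best_acc = max(best_acc, train_acc)
        stall = 0 if improved else stall + 1
        if stall >= train_config.patience:
            break
    return TrainResult(model=model, history=pd.DataFrame(records))


@dataclass
class AlphaSelection:
    selected_alpha: float
    table: pd.DataFrame  # alpha, val_auc — the evidence behind the selection
    result: TrainResult  # the fit at the selected alpha


def tune_alpha(
    manifest: pd.DataFrame,
    model_spec: ModelSpec,
    loss_config_template: LossConfig,
    train_config: TrainConfig,
    images_root: str | Path | None = None,
    store: ImageStore | None = None,
) -> AlphaSelection:
    """Grid-search alpha by validation AUC, refitting with identical seeds.

    Duplicate grid values are fitted once. Ties in validation AUC are broken
    toward the smaller alpha (the grid is scanned in ascending order and a
    candidate must strictly improve to replace the incumbent).
    """
    if not (manifest["split"] == "val").any():
        raise ConfigurationError("alpha tuning requires a nonempty validation split")
    if store is None:
        if images_root is None:
            raise ConfigurationError("provide images_root or an ImageStore")
        store = ImageStore(images_root, model_spec.input_side_px)

    grid = sorted(set(train_config.alpha_grid))
    x_val = store.stack(manifest, "val")
    y_val = split_labels(manifest, "val", true=False)

    rows = []
    best_alpha = best_auc = None
    best_result = None
    for alpha in grid:
        cfg = replace(loss_config_template, alpha=alpha)
        result = train_model(manifest, model_spec, cfg, train_config, store=store)
        proba = result.model.predict_proba(x_val)
        val_auc = roc_auc(proba[:, 1], y_val)
        rows.append({"alpha": alpha, "val_auc": val_auc})
        if best_auc is None or val_auc > best_auc:  # strict: ties keep smaller alpha
            best_alpha, best_auc, best_result = alpha, val_auc, result
    return AlphaSelection(
        selected_alpha=best_alpha, table=pd.DataFrame(rows), result=best_result
    )
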