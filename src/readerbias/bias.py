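"""Reader-error models: random and systematic (false-positive / false-negative)
label noise at controlled overall strengths.

The overall introduced-error level is defined on the whole (class-balanced)
split. A systematic error concentrates all flips in one class, so reaching an
overall level p requires flipping a 2p fraction of that class; random error
flips a p fraction of each class (an equal mixture of false positives and false
negatives). Flip counts are exact, not expectations: rows are sampled without
replacement within each (split, class) cell from a seeded stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .manifest import validate_manifest

BIAS_TYPES = ("random", "false_positive", "false_negative")

# stable split->integer keys for RNG stream derivation (str hash is not stable)
_SPLIT_KEY = {"train": 0, "val": 1, "test": 2}


@dataclass(frozen=True)
class BiasSpec:
    """Which error model to apply, how strongly, and to which splits."""

    bias_type: str
    overall_level: float
    seed: int = 42
    apply_to_splits: tuple[str, ...] = ("train", "val")

    def __post_init__(self) -> None:
        if self.bias_type not in BIAS_TYPES:
            raise ConfigurationError(
                f"bias_type must be one of {BIAS_TYPES}, got {self.bias_type!r}"
            )
        if not 0.0 <= self.overall_level < 0.5:
            raise ConfigurationError(
                f"overall_level must be in [0, 0.5), got {self.overall_level}"
            )
        bad = set(self.apply_to_splits) - {"train", "val"}
        if bad:
            raise ConfigurationError(f"apply_to_splits may not include {sorted(bad)}")


def n_flips(rate: float, n_class: int) -> int:
    """Number of labels to flip in a class of size ``n_class`` at ``rate``.

    Round-half-up of ``rate * n_class`` — e.g. 0.15 of 7 gives 1 (1.05 -> 1),
    0.15 of 10 gives 2 (1.5 -> 2).
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"rate must be in [0, 1], got {rate}")
    if n_class < 0:
        raise ConfigurationError(f"n_class must be >= 0, got {n_class}")
    return int(math.floor(rate * n_class + 0.5))


def _per_class_rates(spec: BiasSpec) -> dict[int, float]:
    """Flip rate applied within each true class, keyed by class label."""
    p = spec.overall_level
    if spec.bias_type == "random":
        return {0: p, 1: p}
    if spec.bias_type == "false_positive":
        return {0: 2.0 * p, 1: 0.0}
    return {0: 0.0, 1: 2.0 * p}  # false_negative


def inject_bias(manifest: pd.DataFrame, spec: BiasSpec) -> pd.DataFrame:
    """Fill ``biased_label`` according to the error model.

    Flips are sampled without replacement, independently per (split, class)
    cell, from an RNG stream keyed by (seed, split, class) — so the realization
    in one class never depends on the other. Splits outside
    ``apply_to_splits`` get ``biased_label = true_label``; the test split is
    always left clean. ``true_label`` is never modified, and any pre-existing
    ``biased_label`` is overwritten from ``true_label`` (injection never
    compounds).
    """
    manifest = validate_manifest(manifest)
    out = manifest.copy()
    out["biased_label"] = out["true_label"]
    rates = _per_class_rates(spec)
    for split in spec.apply_to_splits:
        for cls, rate in rates.items():
            idx = out.index[
                (out["split"] == split) & (out["true_label"] == cls)
            ].to_numpy()
            k = n_flips(rate, len(idx))
            if k > len(idx):
                raise ConfigurationError(
                    f"requested {k} flips in class {cls} of split '{split}' "
                    f"but only {len(idx)} rows exist"
                )
            if k == 0:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, _SPLIT_KEY[split], cls])
            )
            flip = rng.choice(idx, size=k, replace=False)
            out.loc[flip, "biased_label"] = 1 - cls
    return out


def error_report(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-split realized error table, recounted against the true labels.

    Columns: fp_count, fn_count, fp_rate (among true negatives), fn_rate
    (among true positives), overall_error_rate.
    """
    manifest = validate_manifest(manifest)
    if manifest["biased_label"].isna().any():
        missing = manifest.loc[manifest["biased_label"].isna(), "split"].unique()
        raise ValidationError(
            f"biased_label missing in split(s) {sorted(missing)}; "
            "run inject_bias first"
        )
    rows = []
    for split, g in manifest.groupby("split", sort=False):
        neg = g["true_label"] == 0
        pos = g["true_label"] == 1
        fp = int(((g["biased_label"] == 1) & neg).sum())
        fn = int(((g["biased_label"] == 0) & pos).sum())
        rows.append(
            {
                "split": split,
                "fp_count": fp,
                "fn_count": fn,
                "fp_rate": fp / neg.sum() if neg.any() else 0.0,
                "fn_rate": fn / pos.sum() if pos.any() else 0.0,
                "overall_error_rate": (fp + fn) / len(g),
            }
        )
    return pd.DataFrame(rows).set_index("split")
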