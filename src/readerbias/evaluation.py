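"""The bias-type x level x model experiment grid.

For every cell the runner injects the requested bias into the training (and
optionally validation) labels, trains the requested model variant, and scores
the test split — always against the TRUE test labels; the test set is never
biased. Each (bias type, level) pair uses one fixed bias realization, and the
repetitions rerun training with different seeds, so repeat-to-repeat spread
reflects optimization randomness, not relabeling.

Completed cells are persisted as small JSON files and skipped on rerun, so an
interrupted grid resumes where it stopped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bias import BIAS_TYPES, BiasSpec, inject_bias
from .data import ImageStore, split_labels
from .exceptions import ConfigurationError
from .losses import LossConfig
from .metrics import roc_auc
from .models import ModelSpec
from .training import TrainConfig, train_model, tune_alpha

MODEL_VARIANTS = ("baseline", "improved")


@dataclass(frozen=True)
class ExperimentGrid:
    bias_types: tuple[str, ...] = BIAS_TYPES
    levels: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)
    models: tuple[str, ...] = MODEL_VARIANTS
    n_repetitions: int = 5
    base_seed: int = 42
    clean_val: bool = True  # keep validation labels clean for alpha tuning

    def __post_init__(self) -> None:
        bad = set(self.bias_types) - set(BIAS_TYPES)
        if bad:
            raise ConfigurationError(f"unknown bias types: {sorted(bad)}")
        if any(not 0.0 <= lv < 0.5 for lv in self.levels):
            raise ConfigurationError(f"levels must lie in [0, 0.5): {self.levels}")
        bad = set(self.models) - set(MODEL_VARIANTS)
        if bad:
            raise ConfigurationError(f"unknown model variants: {sorted(bad)}")
        if self.n_repetitions < 1:
            raise ConfigurationError("n_repetitions must be >= 1")

    def cells(self):
        for bias_type in self.bias_types:
            for level in self.levels:
                for model in self.models:
                    for rep in range(self.n_repetitions):
                        yield bias_type, level, model, rep


def _bias_seed(base_seed: int, bias_type: str, level: float) -> int:
    key = [base_seed, BIAS_TYPES.index(bias_type), int(round(level * 10_000))]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % 2**31)


def _cell_name(bias_type: str, level: float, model: str, rep: int) -> str:
    return f"{bias_type}_l{int(round(level * 1000)):03d}_{model}_r{rep}.json"


def run_experiment(
    manifest: pd.DataFrame,
    grid: ExperimentGrid,
    model_spec: ModelSpec,
    loss_config: LossConfig,
    train_config: TrainConfig,
    images_root: str | Path,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Run (or resume) the grid; returns one record per cell.

    The baseline variant trains with alpha = 0; the improved variant tunes
    alpha over ``train_config.alpha_grid`` on the validation split. Repetition
    ``r`` trains with seed ``base_seed + r`` (data order, augmentation, and
    weight init all derive from it). Failed cells are recorded with an error
    message and a missing AUC instead of aborting the grid.
    """
    out_dir = Path(out_dir)
    cell_dir = out_dir / "cells"
    cell_dir.mkdir(parents=True, exist_ok=True)
    store = ImageStore(images_root, model_spec.input_side_px)
    x_test = store.stack(manifest, "test")
    y_test = split_labels(manifest, "test", true=True)

    apply_to = ("train",) if grid.clean_val else ("train", "val")
    records = []
    # at level 0 every bias model is the identity, so the cell outcome depends
    # only on (model variant, repetition); train once and share across types
    zero_level_cache: dict[tuple[str, int], dict] = {}
    for bias_type, level, model_variant, rep in grid.cells():
        cell_path = cell_dir / _cell_name(bias_type, level, model_variant, rep)
        if cell_path.exists():
            records.append(json.loads(cell_path.read_text()))
            continue
        if level == 0.0 and (model_variant, rep) in zero_level_cache:
            record = dict(
                zero_level_cache[(model_variant, rep)], bias_type=bias_type
            )
            cell_path.write_text(json.dumps(record))
            records.append(record)
            continue
        record = {
            "bias_type": bias_type,
            "level": level,
            "model": model_variant,
            "repetition": rep,
            "test_auc": None,
            "selected_alpha": None,
            "n_epochs": None,
            "error": None,
        }
        try:
            spec = BiasSpec(
                bias_type=bias_type,
                overall_level=level,
                seed=_bias_seed(grid.base_seed, bias_type, level),
                apply_to_splits=apply_to,
            )
            biased = inject_bias(manifest, spec)
            rep_seed = grid.base_seed + rep
            cell_train = replace(train_config, repetition_seed=rep_seed)
            cell_model = replace(model_spec, weight_init_seed=rep_seed)
            if model_variant == "baseline":
                result = train_model(
                    biased, cell_model, replace(loss_config, alpha=0.0),
                    cell_train, store=store,
                )
                alpha = 0.0
            else:
                selection = tune_alpha(
                    biased, cell_model, loss_config, cell_train, store=store
                )
                result = selection.result
                alpha = selection.selected_alpha
            proba = result.model.predict_proba(x_test)
            record["test_auc"] = roc_auc(proba[:, 1], y_test)
            record["selected_alpha"] = alpha
            record["n_epochs"] = int(len(result.history))
        except Exception as exc:  # noqa: BLE001 — cell failures must not abort the grid
            record["error"] = f"{type(exc).__name__}: {exc}"
        if level == 0.0 and record["error"] is None:
            zero_level_cache[(model_variant, rep)] = record
        cell_path.write_text(json.dumps(record))
        records.append(record)

    table = pd.DataFrame(records)
    table.to_csv(out_dir / "records.csv", index=False)
    return table


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample standard deviation of test AUC per grid cell group."""
    ok = records[records["test_auc"].notna()]
    summary = (
        ok.groupby(["bias_type", "level", "model"])["test_auc"]
        .agg(mean_auc="mean", sd_auc=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return summary


def plot_auc_trends(summary: pd.DataFrame, out_path: str | Path | None = None):
    """One panel per model variant: mean test AUC vs. error level per bias type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    models = sorted(summary["model"].unique())
    fig, axes = plt.subplots(1, len(models), figsize=(5 * len(models), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, model in zip(axes, models):
        sub = summary[summary["model"] == model]
        for bias_type, g in sub.groupby("bias_type"):
            g = g.sort_values("level")
            ax.errorbar(
                g["level"] * 100, g["mean_auc"], yerr=g["sd_auc"],
                marker="o", capsize=3, label=bias_type,
            )
        ax.set_title(model)
        ax.set_xlabel("introduced error level (%)")
        ax.set_ylabel("test AUC")
        ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
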