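"""Label manifests: the record of images, splits, and (possibly biased) labels.

A manifest is the unit of data that flows between every pipeline stage. Each
row describes one image: its path, which split it belongs to, the true label,
and — once a bias model has been applied — the label the simulated readers
assigned. True labels are never modified downstream; biased labels live in a
separate column so that every error can be recounted after the fact.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import ValidationError

SPLITS = ("train", "val", "test")
#: Exact column order of the manifest CSV. ``biased_label`` may be empty.
COLUMNS = ("image_path", "split", "true_label", "biased_label")


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a manifest DataFrame.

    Returns a copy with canonical dtypes (``biased_label`` as nullable Int64).
    Raises :class:`ValidationError` naming the offending column/row otherwise.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    _check(not missing, f"manifest is missing column(s): {missing}")
    df = df.loc[:, list(COLUMNS)].copy()

    dup = df["image_path"][df["image_path"].duplicated()]
    _check(dup.empty, f"duplicate image_path values: {sorted(dup.unique())}")

    bad_split = df.loc[~df["split"].isin(SPLITS), "split"]
    _check(bad_split.empty, f"invalid split values: {sorted(bad_split.unique())}")

    for col in ("true_label", "biased_label"):
        series = pd.to_numeric(df[col], errors="coerce")
        if col == "true_label":
            _check(
                series.notna().all(),
                f"non-numeric {col} at rows {df.index[series.isna()].tolist()}",
            )
        present = series.dropna()
        _check(
            present.isin((0, 1)).all(),
            f"{col} must be 0 or 1; offending rows "
            f"{df.index[~series.isin((0, 1)) & series.notna()].tolist()}",
        )
        df[col] = series.astype("Int64")

    # biased_label is all-or-none within each split
    has_bias = df["biased_label"].notna()
    for split, group in df.groupby("split", sort=False):
        n = has_bias[group.index].sum()
        _check(
            n == 0 or n == len(group),
            f"split '{split}' has biased_label on {n}/{len(group)} rows; "
            "must be all or none",
        )
    return df


def empty_manifest() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_path": pd.Series(dtype=str),
            "split": pd.Series(dtype=str),
            "true_label": pd.Series(dtype="Int64"),
            "biased_label": pd.Series(dtype="Int64"),
        }
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV and validate it."""
    df = pd.read_csv(path, dtype={"image_path": str, "split": str})
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    """Write a validated manifest to CSV (empty cell for absent biased_label)."""
    df = validate_manifest(manifest)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def training_labels(manifest: pd.DataFrame, split: str) -> pd.DataFrame:
    """Rows of one split with the label the model actually trains on.

    Uses ``biased_label`` when present (the readers' labels), else the true
    label. Test labels must always be taken from ``true_label`` directly.
    """
    rows = manifest[manifest["split"] == split].copy()
    rows["label"] = rows["biased_label"].fillna(rows["true_label"]).astype(int)
    return rows
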