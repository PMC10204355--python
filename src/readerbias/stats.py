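"""Slope analysis of AUC versus introduced-error level.

Two questions are answered. First, per bias type: how fast does test AUC fall
per percentage point of introduced labeling error (an ordinary least-squares
slope with a t-test of beta = 0)? Second, across bias types: do the slopes
differ (the classical ANCOVA homogeneity-of-slopes F-test, comparing the model
``auc ~ type + level + type:level`` against ``auc ~ type + level`` via their
residual sums of squares)?

Levels are expressed in percentage points (5, 10, ...), so slopes are on the
scale of a few thousandths of AUC per point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDesignError, ValidationError


@dataclass(frozen=True)
class SlopeFit:
    bias_type: str | None
    slope: float          # AUC change per percentage point of error
    intercept: float
    stderr: float
    p_value: float        # two-sided t-test of slope = 0
    residual_df: int


@dataclass(frozen=True)
class SlopeComparison:
    model: str | None     # which classifier variant the records came from
    f_stat: float         # interaction term (type x level) F statistic
    df_num: int
    df_den: int
    p_value: float
    fits: tuple[SlopeFit, ...]


def fit_slope(
    level_pct: np.ndarray, auc: np.ndarray, bias_type: str | None = None
) -> SlopeFit:
    """OLS of AUC on error level (percentage points), with the slope t-test."""
    x = np.asarray(level_pct, dtype=np.float64)
    y = np.asarray(auc, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("level_pct and auc must be matching 1-D arrays")
    n = len(x)
    if n < 3 or len(np.unique(x)) < 2:
        raise DegenerateDesignError(
            f"need >= 3 points spanning >= 2 distinct levels, "
            f"got n={n} with {len(np.unique(x))} level(s)"
        )
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    rss = np.sum((y - intercept - slope * x) ** 2)
    syy = np.sum((y - ybar) ** 2)
    if rss <= 1e-12 * max(syy, 1.0):  # numerically exact fit
        rss = 0.0
    df = n - 2
    se = np.sqrt(rss / df / sxx)
    if se == 0.0:
        # exact fit: p = 0 for a nonzero slope, 1 for perfectly flat data
        p = 0.0 if slope != 0.0 else 1.0
    else:
        p = 2.0 * sps.t.sf(abs(slope / se), df)
    return SlopeFit(
        bias_type=bias_type,
        slope=float(slope),
        intercept=float(intercept),
        stderr=float(se),
        p_value=float(p),
        residual_df=int(df),
    )


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    coef, residuals, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise DegenerateDesignError(
            f"singular design matrix (rank {rank} < {design.shape[1]} columns)"
        )
    return float(np.sum((y - design @ coef) ** 2))


def compare_slopes(
    records: pd.DataFrame,
    model: str | None = None,
    *,
    level_col: str = "level_pct",
    auc_col: str = "auc",
    group_col: str = "bias_type",
) -> SlopeComparison:
    """Homogeneity-of-slopes ANCOVA across bias types for one model variant.

    F = ((RSS_reduced - RSS_full) / (G - 1)) / (RSS_full / (n - 2G)) where the
    full model allows one slope per bias type and the reduced model shares a
    single slope; G is the number of bias types.
    """
    groups = sorted(records[group_col].unique())
    if len(groups) < 2:
        raise DegenerateDesignError(
            f"need >= 2 bias types to compare slopes, got {groups}"
        )
    fits = tuple(
        fit_slope(
            records.loc[records[group_col] == g, level_col].to_numpy(),
            records.loc[records[group_col] == g, auc_col].to_numpy(),
            bias_type=g,
        )
        for g in groups
    )
    x = records[level_col].to_numpy(dtype=np.float64)
    y = records[auc_col].to_numpy(dtype=np.float64)
    n, g = len(records), len(groups)
    dummies = np.column_stack(
        [(records[group_col] == grp).to_numpy(float) for grp in groups[1:]]
    )
    intercept = np.ones((n, 1))
    reduced = np.hstack([intercept, dummies, x[:, None]])
    full = np.hstack([reduced, dummies * x[:, None]])
    df_num = g - 1
    df_den = n - 2 * g
    if df_den < 1:
        raise DegenerateDesignError(f"not enough observations: residual df {df_den}")
    rss_r = _rss(reduced, y)
    rss_f = _rss(full, y)
    tiny = 1e-12 * max(float(np.sum((y - y.mean()) ** 2)), 1.0)
    num = max(0.0, rss_r - rss_f) / df_num
    if rss_f <= tiny:
        # numerically exact full fit: no evidence against shared slopes
        # unless the interaction strictly reduced a non-negligible RSS
        f_stat = 0.0 if rss_r - rss_f <= tiny else np.inf
    else:
        f_stat = num / (rss_f / df_den)
    p = float(sps.f.sf(f_stat, df_num, df_den))
    return SlopeComparison(
        model=model,
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        fits=fits,
    )


def slopes_from_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(model, bias_type) slope fits plus per-model slope comparisons,
    from an experiment records table (columns bias_type, level, model, test_auc).
    """
    ok = records[records["test_auc"].notna()].copy()
    ok["level_pct"] = ok["level"] * 100.0
    rows = []
    for model, g in ok.groupby("model"):
        comparison = compare_slopes(
            g, model=model, auc_col="test_auc", level_col="level_pct"
        )
        for fit in comparison.fits:
            rows.append(
                {
                    "model": model,
                    "bias_type": fit.bias_type,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "slope_p_value": fit.p_value,
                    "interaction_F": comparison.f_stat,
                    "interaction_p_value": comparison.p_value,
                }
            )
    return pd.DataFrame(rows)
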