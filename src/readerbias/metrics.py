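"""ROC-AUC via the Mann-Whitney statistic.

AUC is the probability that a randomly chosen positive scores higher than a
randomly chosen negative, with tied pairs counting one half. The rank form
below is exact and tie-robust, and is algebraically identical to counting
concordant pairs: (#concordant + 0.5 * #tied) / (n_pos * n_neg).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .exceptions import UndefinedMetricError, ValidationError


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError(
            f"scores/labels must be matching 1-D arrays, got "
            f"{scores.shape} vs {labels.shape}"
        )
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError(f"labels must be 0/1, got {np.unique(labels)}")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined: need both classes, got {n_pos} positives and "
            f"{n_neg} negatives"
        )
    ranks = rankdata(scores)  # midranks handle ties -> the 0.5 pair weight
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
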