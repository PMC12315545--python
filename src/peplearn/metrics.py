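"""Evaluation metrics: Spearman rank correlation and ROC AUC.

Thin wrappers with strict error contracts: a constant input makes the
rank correlation undefined and raises :class:`MetricError` instead of
propagating NaN; AUC requires both classes present.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import MetricError


def spearman(x, y) -> float:
    """Spearman correlation: Pearson correlation of average-rank vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise MetricError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve with tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    classes = np.unique(labels)
    if classes.size != 2:
        raise MetricError("AUC requires exactly two classes present")
    return float(roc_auc_score(labels, scores))
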