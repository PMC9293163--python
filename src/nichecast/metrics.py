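"""Model-evaluation metrics.

`auc_roc` is computed via the Mann-Whitney identity: the AUC equals the
probability that a randomly chosen positive outscores a randomly chosen
negative, with ties counting one half.  Implemented through midranks so it is
exact under ties and O(n log n).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auc_roc"]


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of `scores` against binary `labels`.

    Equals ``P(score+ > score-) + 0.5 P(tie)`` over all positive/negative
    pairs.  Raises if only one class is present.
    """
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)  # midranks handle ties exactly
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
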