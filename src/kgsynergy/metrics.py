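"""Relation-ranking and classification metrics.

``true_prediction_percentage`` reports, for a set of (head, tail) pairs
with known true relations, the percentage of pairs whose rank-k predicted
relation equals the truth:

    percentage at rank k = 100 * (# pairs whose rank-k prediction is true)
                                 / (# evaluated pairs)

Each pair contributes exactly one prediction per rank, so summing the
true counts over all ranks recovers the number of pairs.

``binary_roc_auc`` is the Mann-Whitney concordance probability (ties count
one half) — identical to the trapezoidal area under the ROC curve.
``multiclass_roc_auc`` macro-averages one-vs-rest binary AUCs over the
relation types present in the truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .embedding.training import RelationRanking

__all__ = [
    "RankEvalResult",
    "true_prediction_percentage",
    "rank_table",
    "binary_roc_auc",
    "multiclass_roc_auc",
]


@dataclass
class RankEvalResult:
    rank: int
    n_true: int
    n_total: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.n_true / self.n_total


def true_prediction_percentage(
    rankings: list[RelationRanking],
    truth: dict[tuple[str, str], str],
    k: int = 1,
) -> RankEvalResult:
    """Percentage of pairs whose rank-``k`` relation matches the truth."""
    if not rankings:
        raise ValueError("no rankings to evaluate (undefined denominator)")
    n_true = 0
    for ranking in rankings:
        key = (ranking.head, ranking.tail)
        if key not in truth:
            raise KeyError(f"no truth entry for pair {key}")
        if k < 1 or k > len(ranking.ranked):
            raise ValueError(f"rank {k} outside 1..{len(ranking.ranked)}")
        if ranking.relation_at(k) == truth[key]:
            n_true += 1
    return RankEvalResult(rank=k, n_true=n_true, n_total=len(rankings))


def rank_table(
    rankings: list[RelationRanking],
    truth: dict[tuple[str, str], str],
    max_rank: int = 3,
) -> list[RankEvalResult]:
    """``true_prediction_percentage`` for ranks 1..max_rank."""
    return [true_prediction_percentage(rankings, truth, k) for k in range(1, max_rank + 1)]


def binary_roc_auc(labels, scores) -> float:
    """ROC-AUC as the Mann-Whitney concordance probability.

    AUC = [ sum of positive ranks - n_pos(n_pos+1)/2 ] / (n_pos * n_neg),
    with average ranks for ties (each tied positive/negative pair counts
    one half).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D sequences")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC-AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def multiclass_roc_auc(
    truth: list[str],
    score_matrix: np.ndarray,
    classes: list[str],
    return_per_type: bool = False,
):
    """Macro-averaged one-vs-rest ROC-AUC over relation types.

    ``score_matrix[i, j]`` is the score of ``classes[j]`` for pair ``i``.
    Types absent from the truth have an undefined one-vs-rest AUC and are
    excluded from the mean with a warning.
    """
    truth = list(truth)
    score_matrix = np.asarray(score_matrix, dtype=float)
    if score_matrix.shape != (len(truth), len(classes)):
        raise ValueError("score_matrix must be (n_pairs, n_classes)")
    present = [c for c in classes if c in set(truth)]
    if len(present) < 2:
        raise ValueError("need at least two relation types present in truth")
    absent = sorted(set(classes) - set(present))
    if absent:
        warnings.warn(
            f"relation types absent from truth excluded from macro AUC: {absent}",
            stacklevel=2,
        )
    per_type: dict[str, float] = {}
    truth_arr = np.asarray(truth)
    for cls in present:
        binary = (truth_arr == cls).astype(int)
        per_type[cls] = binary_roc_auc(binary, score_matrix[:, classes.index(cls)])
    macro = float(np.mean(list(per_type.values())))
    if return_per_type:
        return macro, per_type
    return macro
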