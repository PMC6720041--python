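"""Benchmark metrics: ROC/PR curves on the concatenated score vector,
percent of clusters labelled correctly, and gold-label rank distributions.

All prediction scores over every tested (cell type, cluster) pair are
concatenated into one vector; an entry is a true positive when the gold
standard assigns exactly that type to that cluster.  Sweeping a score
threshold over this vector yields the ROC and precision-recall curves whose
areas summarise a method's performance.  Curve construction and integration
are delegated to scikit-learn: trapezoidal AUC for ROC, step-wise
average-precision for PR (an exactly reproducible convention; tools that
interpolate PR non-linearly will differ in the third decimal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .io import GeneSetDB

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledScores",
    "CurveResult",
    "concatenate_with_truth",
    "roc_curve",
    "pr_curve",
    "top_hit_accuracy",
    "gold_rank_distribution",
    "DEFAULT_SIZE_BINS",
]


@dataclass
class LabeledScores:
    """Parallel score/truth vectors over (cell type, cluster) pairs."""

    score: np.ndarray
    truth: np.ndarray
    cluster: list[str]
    cell_type: list[str]

    def __post_init__(self) -> None:
        if not (len(self.score) == len(self.truth) == len(self.cluster) == len(self.cell_type)):
            raise ValueError("score, truth, cluster and cell_type must have equal length")

    def __len__(self) -> int:
        return len(self.score)


@dataclass
class CurveResult:
    """An ROC or PR curve: ordered (x, y) points and the area under them."""

    points: np.ndarray  # (n, 2): (FPR, TPR) or (recall, precision)
    auc: float
    kind: str  # "ROC" | "PR"


def concatenate_with_truth(
    scores: pd.DataFrame,
    gold: Mapping[str, str],
    restrict: Sequence[str] | None = None,
) -> LabeledScores:
    """Flatten a score matrix into the labelled vector used for curve analysis.

    One entry per (type, cluster) pair; truth = 1 iff the gold standard maps
    the cluster to that type.  Clusters without a gold label are dropped
    (count logged), as are NaN score entries flagged missing upstream.
    ``restrict`` limits the evaluated cell types (the "expected cell types
    only" configuration); every remaining labelled cluster's gold type must
    lie inside the restricted set.
    """
    types = list(scores.index)
    if restrict is not None:
        restrict = list(restrict)
        unknown = set(restrict) - set(types)
        if unknown:
            raise ValueError(f"restriction names unknown cell types: {sorted(unknown)}")
        types = [t for t in types if t in set(restrict)]
    labelled = [c for c in scores.columns if c in gold]
    dropped = scores.shape[1] - len(labelled)
    if dropped:
        logger.info("dropping %d clusters without gold labels", dropped)
    if not labelled:
        raise ValueError("no cluster has a gold-standard label")
    for c in labelled:
        if gold[c] not in types:
            raise ValueError(
                f"cluster {c!r} gold label {gold[c]!r} is outside the evaluated cell types"
            )

    score, truth, cl, ty = [], [], [], []
    n_missing = 0
    for t in types:
        for c in labelled:
            s = scores.loc[t, c]
            if pd.isna(s):
                n_missing += 1
                continue
            score.append(float(s))
            truth.append(1 if gold[c] == t else 0)
            cl.append(c)
            ty.append(t)
    if n_missing:
        logger.info("excluding %d missing (NaN) score entries", n_missing)
    truth_arr = np.asarray(truth, dtype=int)
    if truth_arr.sum() == 0:
        raise ValueError("no positive (gold) pairs remain after restriction")
    return LabeledScores(np.asarray(score, dtype=float), truth_arr, cl, ty)


def _check_curve_input(ls: LabeledScores) -> None:
    pos = int(ls.truth.sum())
    if pos == 0 or pos == len(ls):
        raise ValueError("curve analysis needs at least one positive and one negative")


def roc_curve(ls: LabeledScores) -> CurveResult:
    """ROC curve over grouped score thresholds; AUC by trapezoid.

    Tied scores collapse into one threshold step, which makes the AUC equal
    the Mann-Whitney statistic with half credit for ties.
    """
    _check_curve_input(ls)
    fpr, tpr, _ = skm.roc_curve(ls.truth, ls.score)
    return CurveResult(np.column_stack([fpr, tpr]), float(skm.auc(fpr, tpr)), "ROC")


def pr_curve(ls: LabeledScores) -> CurveResult:
    """Precision-recall curve; AUC is the step-wise average precision."""
    _check_curve_input(ls)
    precision, recall, _ = skm.precision_recall_curve(ls.truth, ls.score)
    ap = float(skm.average_precision_score(ls.truth, ls.score))
    return CurveResult(np.column_stack([recall, precision]), ap, "PR")


def top_hit_accuracy(scores: pd.DataFrame, gold: Mapping[str, str]) -> float:
    """Percentage of labelled clusters whose best-scoring type is the gold one.

    A cluster counts as correct only when the gold type is the unique
    maximum; ties at the top are mispredictions.  Missing (NaN) entries do
    not compete.
    """
    labelled = [c for c in scores.columns if c in gold]
    if not labelled:
        raise ValueError("no cluster has a gold-standard label")
    correct = 0
    for c in labelled:
        col = scores[c].dropna()
        if col.empty or gold[c] not in col.index:
            continue
        top = col.max()
        winners = col.index[col == top]
        if len(winners) == 1 and winners[0] == gold[c]:
            correct += 1
    return 100.0 * correct / len(labelled)


DEFAULT_SIZE_BINS: tuple[tuple[int, float], ...] = (
    (1, 2), (3, 5), (6, 10), (11, 20), (21, 50), (51, float("inf")),
)


def gold_rank_distribution(
    scores: pd.DataFrame,
    gold: Mapping[str, str],
    db: GeneSetDB,
    size_bins: Sequence[tuple[int, float]] = DEFAULT_SIZE_BINS,
) -> pd.DataFrame:
    """Rank of the gold type per cluster, binned by its signature's gene count.

    Rank 1 is the best score in the cluster's column (average ranks on ties);
    a perfect method ranks every gold label 1.  Signature size is the number
    of genes in the gold type's gene set; the default bins follow the usual
    marker-list size strata (1-2, 3-5, 6-10, 11-20, 21-50, >50 genes).
    """
    rows = []
    for c in scores.columns:
        if c not in gold:
            continue
        g = gold[c]
        col = scores[c].dropna()
        if g not in col.index:
            raise ValueError(f"gold type {g!r} has no score for cluster {c!r}")
        ranks = stats.rankdata(-col.to_numpy(), method="average")
        rank = float(ranks[list(col.index).index(g)])
        size = len(db[g]) if g in db.sets else np.nan
        label = ""
        for lo, hi in size_bins:
            if not np.isnan(size) and lo <= size <= hi:
                label = f"{lo}-{int(hi)}" if np.isfinite(hi) else f">{lo - 1}"
                break
        rows.append({"cluster": c, "gold_type": g, "rank": rank,
                     "signature_size": size, "size_bin": label})
    return pd.DataFrame(rows, columns=["cluster", "gold_type", "rank", "signature_size", "size_bin"])
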