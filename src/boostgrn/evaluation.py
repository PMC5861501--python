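"""AUROC/AUPR scoring of inferred networks against gold standards.

Predicted edge scores are ranked and compared with a known edge set.
AUROC is the probability that a random true edge outranks a random
non-edge (ties counted half); AUPR is the area under the
precision-recall step curve swept in descending score order, with tied
scores processed as one block — i.e. sum over k of
(R_k - R_{k-1}) * Prec_k.  Both are delegated to scikit-learn
(``roc_auc_score`` / ``average_precision_score``), which implement
exactly these conventions.

Benchmark aggregation mirrors how multi-dataset method comparisons are
usually tabulated: per-method mean and population standard deviation of
each metric across datasets, plus the average within-dataset rank
(rank 1 = best, ties share the mean rank), with optional pre-averaging
of grouped sub-networks (e.g. the five DREAM4 networks of one size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_model import EdgeSet, WeightedAdjacency


@dataclass
class EvaluationResult:
    """AUROC/AUPR of one network against one gold standard."""

    auroc: float
    aupr: float
    n_positives: int
    n_negatives: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auroc <= 1.0 and 0.0 <= self.aupr <= 1.0):
            raise ValueError("AUROC and AUPR must lie in [0, 1]")
        if self.n_positives <= 0 or self.n_negatives <= 0:
            raise ValueError("both classes must be non-empty")


def score_edges(
    W: WeightedAdjacency, gold: EdgeSet
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (scores, labels) vectors over the candidate edge universe.

    With explicit negatives in the gold standard the universe is the
    listed positive and negative pairs; otherwise it is every ordered
    off-diagonal pair, unlisted pairs counting as negatives (the DREAM
    convention).  A positive absent from W's support contributes score 0.
    """
    if not gold.positives:
        raise ValueError("gold standard has no positive edges")
    p = W.n_genes
    if gold.negatives is not None and len(gold.negatives) > 0:
        universe = sorted(gold.positives | gold.negatives)
    else:
        universe = [(i, j) for i in range(p) for j in range(p) if i != j]
    labels = np.array([1 if pair in gold.positives else 0 for pair in universe])
    if labels.all():
        raise ValueError("candidate universe contains no negative edges")
    scores = np.array([W.scores[i, j] for i, j in universe], dtype=float)
    return scores, labels


def compute_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties count 1/2)."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both a positive and a negative class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def compute_aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (descending-score sweep)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def evaluate(W: WeightedAdjacency, gold: EdgeSet) -> EvaluationResult:
    """Score a weighted adjacency against a gold standard."""
    scores, labels = score_edges(W, gold)
    return EvaluationResult(
        auroc=compute_auroc(scores, labels),
        aupr=compute_aupr(scores, labels),
        n_positives=int(labels.sum()),
        n_negatives=int((1 - labels).sum()),
    )


def aggregate_benchmark(
    results: pd.DataFrame,
    method_col: str = "method",
    dataset_col: str = "dataset",
    group_col: str | None = None,
    metrics: tuple[str, ...] = ("aupr", "auroc"),
) -> pd.DataFrame:
    """Summarize a complete (method x dataset) grid of evaluation scores.

    Returns one row per method with, for each metric, the mean, population
    standard deviation and average within-dataset rank (1 = best; tied
    scores share the mean rank).  With ``group_col``, scores are first
    averaged within (method, group) and the groups then act as datasets.
    Rows are ordered by descending mean of the first metric.
    """
    df = results.copy()
    for col in (method_col, dataset_col, *metrics):
        if col not in df.columns:
            raise ValueError(f"results table lacks column {col!r}")
    if group_col is not None:
        df = (
            df.groupby([method_col, group_col], as_index=False)[list(metrics)].mean()
        )
        dataset_col = group_col

    summary = pd.DataFrame(index=sorted(df[method_col].unique()))
    summary.index.name = method_col
    for metric in metrics:
        grid = df.pivot_table(
            index=dataset_col, columns=method_col, values=metric, aggfunc="first"
        )
        if grid.isna().any().any():
            missing = [
                (d, m)
                for d in grid.index
                for m in grid.columns
                if pd.isna(grid.loc[d, m])
            ]
            raise ValueError(f"missing (dataset, method) cells: {missing}")
        ranks = grid.rank(axis=1, ascending=False, method="average")
        summary[f"{metric}_avg"] = grid.mean(axis=0)
        summary[f"{metric}_std"] = grid.std(axis=0, ddof=0)
        summary[f"{metric}_avg_rank"] = ranks.mean(axis=0)
    return summary.sort_values(f"{metrics[0]}_avg", ascending=False)
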