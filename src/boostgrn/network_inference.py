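"""Assemble per-target importance scores into a weighted regulatory network.

Network inference decomposes into P independent regression subproblems,
one per target gene.  For target j the candidate regulators' importance
scores become column j of the weighted adjacency matrix W; w[i, j] is the
evidence that gene i regulates gene j.  Thresholding W (default 0.25 on
per-target unit-normalized scores) yields the reconstructed network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .boosted_trees import ensemble_importance, fit_adaboost, fit_graboost
from .data_model import EdgeSet, TimeCourseDataset, WeightedAdjacency
from .lagging import build_lagged_problem, standardize_genes

DEFAULT_THRESHOLD = 0.25

_METHOD_DEFAULT_LEARNING_RATE = {"adaboost": 1.0, "graboost": 0.1}


@dataclass
class InferenceParams:
    """Hyperparameters of the boosted-tree scorer.

    ``learning_rate=None`` selects the per-method default (1.0 for
    AdaBoost, 0.1 for gradient boosting).
    """

    n_rounds: int = 100
    max_depth: int = 3
    learning_rate: float | None = None

    def resolved_learning_rate(self, method: str) -> float:
        if self.learning_rate is not None:
            return float(self.learning_rate)
        return _METHOD_DEFAULT_LEARNING_RATE[method]


def target_seed(master_seed: int, target_index: int) -> int:
    """Deterministic per-target sub-seed.

    Derived via a spawned :class:`numpy.random.SeedSequence` keyed on the
    target index, so results are independent of execution order and
    identical whether targets run sequentially or concurrently.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(int(target_index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _score_target(
    dataset: TimeCourseDataset,
    target_index: int,
    method: str,
    params: InferenceParams,
    master_seed: int,
    normalize_importance: bool,
    candidate_regulators: Sequence[int] | None,
) -> tuple[list[int], np.ndarray]:
    problem = build_lagged_problem(dataset, target_index, candidate_regulators)
    fitter = fit_adaboost if method == "adaboost" else fit_graboost
    try:
        ensemble = fitter(
            problem,
            n_rounds=params.n_rounds,
            learning_rate=params.resolved_learning_rate(method),
            max_depth=params.max_depth,
            seed=target_seed(master_seed, target_index),
        )
        vis = ensemble_importance(ensemble, normalize=normalize_importance)
    except Exception as exc:
        raise RuntimeError(
            f"fitting failed for target gene {dataset.gene_names[target_index]!r}"
        ) from exc
    return problem.regulator_indices, vis


def infer_network(
    dataset: TimeCourseDataset,
    method: str = "graboost",
    params: InferenceParams | None = None,
    seed: int = 0,
    standardize: bool = True,
    normalize_importance: bool = True,
    candidate_regulators: Sequence[int] | None = None,
    n_jobs: int = 1,
) -> WeightedAdjacency:
    """Infer the weighted adjacency matrix from a time-course dataset.

    Parameters
    ----------
    method
        ``"adaboost"`` or ``"graboost"``.
    standardize
        Scale each gene's pooled series to mean 0 / SD 1 before fitting
        (default on).
    normalize_importance
        Rescale each target's importance vector to unit sum (default on;
        makes the fixed 0.25 edge threshold meaningful across targets).
    n_jobs
        Targets are independent; with ``n_jobs != 1`` they run in parallel
        via joblib with results identical to sequential execution.
    """
    if method not in ("adaboost", "graboost"):
        raise ValueError(f"unknown method {method!r}")
    if dataset.n_genes < 2:
        raise ValueError("network inference needs at least 2 genes")
    params = params or InferenceParams()
    if standardize:
        dataset = standardize_genes(dataset)

    p = dataset.n_genes
    tasks = (
        delayed(_score_target)(
            dataset, j, method, params, seed, normalize_importance,
            candidate_regulators,
        )
        for j in range(p)
    )
    results = Parallel(n_jobs=n_jobs)(tasks)

    scores = np.zeros((p, p))
    for j, (regulators, vis) in enumerate(results):
        scores[regulators, j] = vis
    return WeightedAdjacency(scores=scores, gene_names=list(dataset.gene_names))


def threshold_network(
    W: WeightedAdjacency, threshold: float = DEFAULT_THRESHOLD
) -> EdgeSet:
    """Keep edges whose score strictly exceeds the threshold."""
    i_idx, j_idx = np.nonzero(W.scores > threshold)
    edges = {(int(i), int(j)) for i, j in zip(i_idx, j_idx) if i != j}
    return EdgeSet(positives=edges, n_genes=W.n_genes)


def export_dot(
    edges: EdgeSet, gene_names: Sequence[str], path: str | Path
) -> None:
    """Write the network as a Graphviz DOT digraph.

    Edges are emitted in (regulator, target) index order, so re-exporting
    the same edge set is byte-identical.
    """
    path = Path(path)
    lines = ["digraph grn {"]
    for i, j in sorted(edges.positives):
        lines.append(f'    "{gene_names[i]}" -> "{gene_names[j]}";')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
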