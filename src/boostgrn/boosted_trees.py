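"""Boosted regression trees with variance-reduction variable importance.

This module is the scoring engine of the package.  It provides:

* a greedy CART regression tree whose nodes retain the sample count,
  weight and (weighted, population) target variance needed for
  importance scoring;
* the AdaBoost.R2 boosting loop — adaptive resampling with a linear loss,
  per-round estimator weight ``learning_rate * log(1/beta)`` where
  ``beta = Lbar / (1 - Lbar)``;
* squared-loss gradient boosting — each round fits a tree to the current
  residuals and adds it scaled by a constant learning rate;
* the variable importance score (VIS).  For one tree, the importance of a
  feature G is the total variance reduction over the internal nodes that
  split on G:

      VIS(G) = sum over nodes  |S| Var(S) - |S_l| Var(S_l) - |S_r| Var(S_r)

  (weighted counts and weighted variances when sample weights are in
  play).  Ensemble importance is the estimator-weighted sum of per-tree
  VIS for AdaBoost and the plain average for gradient boosting.

Every routine is deterministic given its seed: split ties are broken by
lowest feature index then lowest threshold, and thresholds sit at the
midpoint between consecutive distinct sorted feature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .lagging import LaggedProblem

#: beta is floored at this value when a round attains zero maximal loss, so
#: the (otherwise infinite) estimator weight is capped at
#: ``learning_rate * log(1 / BETA_FLOOR)``.
BETA_FLOOR = 1e-10


class FitError(RuntimeError):
    """Raised when a boosting run cannot produce a valid ensemble."""


@dataclass
class TreeNode:
    """One node of a regression tree with the statistics VIS needs."""

    n_samples: int
    weight: float  # sum of sample weights reaching the node
    value: float  # weighted mean of the targets (the leaf prediction)
    variance: float  # weighted population variance of the targets
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    """Binary CART regression tree (axis-aligned splits, mean leaves)."""

    root: TreeNode
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected (n, {self.n_features}) feature matrix")
        out = np.empty(X.shape[0])

        def descend(node: TreeNode, idx: np.ndarray) -> None:
            if node.is_leaf:
                out[idx] = node.value
                return
            mask = X[idx, node.feature] <= node.threshold
            descend(node.left, idx[mask])
            descend(node.right, idx[~mask])

        descend(self.root, np.arange(X.shape[0]))
        return out

    def nodes(self) -> Iterator[TreeNode]:
        """Pre-order traversal over all nodes."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def internal_nodes(self) -> Iterator[TreeNode]:
        return (node for node in self.nodes() if not node.is_leaf)

    def leaves(self) -> Iterator[TreeNode]:
        return (node for node in self.nodes() if node.is_leaf)


@dataclass
class BoostedEnsemble:
    """Ordered trees plus per-round estimator weights.

    For AdaBoost the weights are ``learning_rate * log(1/beta_t)``; for
    gradient boosting every weight equals the learning rate and
    ``init_value`` holds the global target mean the additive model starts
    from.
    """

    trees: list[RegressionTree]
    estimator_weights: np.ndarray
    method: Literal["adaboost", "graboost"]
    learning_rate: float
    n_features: int
    init_value: float | None = None
    trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.estimator_weights = np.asarray(self.estimator_weights, dtype=float)
        if len(self.trees) != len(self.estimator_weights):
            raise ValueError("trees and estimator_weights must have equal length")
        if self.method == "adaboost" and np.any(self.estimator_weights < 0):
            raise ValueError("AdaBoost estimator weights must be non-negative")

    @property
    def n_rounds_completed(self) -> int:
        return len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Ensemble prediction.

        Gradient boosting: ``init + lr * sum(trees)``.  AdaBoost:
        the canonical weighted median of per-tree predictions.
        """
        X = np.asarray(X, dtype=float)
        if self.method == "graboost":
            pred = np.full(X.shape[0], self.init_value, dtype=float)
            for tree in self.trees:
                pred += self.learning_rate * tree.predict(X)
            return pred
        preds = np.stack([tree.predict(X) for tree in self.trees], axis=1)
        order = np.argsort(preds, axis=1, kind="stable")
        sorted_preds = np.take_along_axis(preds, order, axis=1)
        weights = np.maximum(self.estimator_weights, 1e-300)[order]
        cum = np.cumsum(weights, axis=1)
        pick = np.argmax(cum >= 0.5 * cum[:, -1:], axis=1)
        return sorted_preds[np.arange(X.shape[0]), pick]


# ---------------------------------------------------------------------------
# CART fitting


def _node_stats(w: float, wy: float, wy2: float) -> tuple[float, float]:
    """Weighted mean and population variance from moment sums."""
    mean = wy / w
    var = max(wy2 - wy * wy / w, 0.0) / w
    return mean, var


def _best_split(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, idx: np.ndarray
) -> tuple[float, int, float] | None:
    """Greedy best axis-aligned split of the samples in ``idx``.

    Returns ``(reduction, feature, threshold)`` maximizing the weighted
    variance reduction ``w(S)Var(S) - w(S_l)Var(S_l) - w(S_r)Var(S_r)``,
    or None if no split separates two distinct feature values.  Ties go to
    the lowest threshold value, then the lowest feature index: thresholds
    are data values unchanged by column reordering, which keeps tree
    fitting equivariant under gene permutations (ties across features are
    common — any 2-sample node is separated equally well by every
    feature).
    """
    ws = w[idx]
    total_w = ws.sum()
    # center the targets at the node mean: the variance reduction is
    # shift-invariant and centering avoids catastrophic cancellation in
    # the moment sums, keeping tie comparisons meaningful
    ys = y[idx] - (ws * y[idx]).sum() / total_w
    total_wy = (ws * ys).sum()
    total_wy2 = (ws * ys * ys).sum()
    g_total = total_wy2 - total_wy * total_wy / total_w
    # candidates within this relative band of the best are treated as exact
    # ties and resolved by (lowest threshold, lowest feature)
    tie_tol = 1e-10 * max(g_total, 0.0)

    best: tuple[float, int, float] | None = None  # (reduction, feature, threshold)
    for k in range(X.shape[1]):
        xv = X[idx, k]
        order = np.argsort(xv, kind="stable")
        xo = xv[order]
        valid = xo[:-1] < xo[1:]
        if not valid.any():
            continue
        yo = ys[order]
        wo = ws[order]
        cw = np.cumsum(wo)[:-1]
        cwy = np.cumsum(wo * yo)[:-1]
        cwy2 = np.cumsum(wo * yo * yo)[:-1]
        rw = total_w - cw
        with np.errstate(divide="ignore", invalid="ignore"):
            g_left = cwy2 - np.where(cw > 0, cwy * cwy / cw, 0.0)
            g_right = (total_wy2 - cwy2) - np.where(
                rw > 0, (total_wy - cwy) ** 2 / rw, 0.0
            )
        reduction = np.where(valid, g_total - g_left - g_right, -np.inf)
        red_max = float(reduction.max())
        if red_max == -np.inf:
            continue
        pos = int(np.argmax(reduction >= red_max - tie_tol))  # lowest threshold
        red_pos = float(reduction[pos])
        threshold = float((xo[pos] + xo[pos + 1]) / 2.0)
        if (
            best is None
            or red_pos > best[0] + tie_tol
            or (red_pos >= best[0] - tie_tol and threshold < best[2])
        ):
            best = (red_pos, k, threshold)
    return best


def fit_regression_tree(
    features: np.ndarray,
    targets: np.ndarray,
    sample_weights: np.ndarray | None = None,
    max_depth: int = 3,
    seed: int = 0,
) -> RegressionTree:
    """Fit a greedy CART regression tree.

    Growth stops at ``max_depth``, at a pure node (all targets equal), when
    fewer than 2 samples remain, or when no split reduces the weighted
    variance.  The ``seed`` argument is accepted for interface uniformity;
    the deterministic tie-breaking rules leave nothing random.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one sample")
    if y.shape != (n,):
        raise ValueError("targets length does not match features")
    if sample_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("sample_weights length does not match features")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("sample weights must be non-negative with positive sum")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        ws = w[idx]
        total_w = ws.sum()
        wy = (ws * y[idx]).sum()
        wy2 = (ws * y[idx] * y[idx]).sum()
        if total_w > 0:
            value, variance = _node_stats(total_w, wy, wy2)
        else:  # all-zero-weight subset: fall back to unweighted mean
            value, variance = float(y[idx].mean()), 0.0
        node = TreeNode(
            n_samples=len(idx), weight=float(total_w), value=value, variance=variance
        )
        if depth >= max_depth or len(idx) < 2 or np.all(y[idx] == y[idx[0]]):
            return node
        split = _best_split(X, y, w, idx) if total_w > 0 else None
        if split is None or split[0] <= 0:
            return node
        _, feature, threshold = split
        mask = X[idx, feature] <= threshold
        node.feature = feature
        node.threshold = threshold
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return RegressionTree(root=grow(np.arange(n), 0), n_features=X.shape[1])


def tree_variable_importance(tree: RegressionTree) -> np.ndarray:
    """Per-feature VIS: total variance reduction over a tree's splits.

    Each internal node splitting on feature G contributes
    ``w(S)Var(S) - w(S_l)Var(S_l) - w(S_r)Var(S_r)`` (non-negative up to
    rounding; tiny negative float residue is clipped to 0).  Features never
    split on get exactly 0.
    """
    importance = np.zeros(tree.n_features)
    for node in tree.internal_nodes():
        drop = (
            node.weight * node.variance
            - node.left.weight * node.left.variance
            - node.right.weight * node.right.variance
        )
        importance[node.feature] += max(drop, 0.0)
    return importance


# ---------------------------------------------------------------------------
# boosting loops


def fit_adaboost(
    problem: LaggedProblem,
    n_rounds: int = 100,
    learning_rate: float = 1.0,
    max_depth: int = 3,
    seed: int = 0,
) -> BoostedEnsemble:
    """AdaBoost.R2 with a linear loss and regression-tree base estimators.

    Per round: (1) sample weights start uniform at 1/N; (2) a bootstrap
    sample of size N is drawn with probability proportional to the weights;
    (3) a tree is fitted to the bootstrap sample; (4) normalized absolute
    errors ``err_i = |y_i - f(x_i)| / max_j |y_j - f(x_j)|`` are computed on
    the ORIGINAL N samples; (5) the average loss is ``Lbar = sum(err_i *
    w_i)`` with the weights renormalized to sum 1 before use; (6) ``beta =
    Lbar / (1 - Lbar)`` and ``w_i <- w_i * beta**(1 - err_i)``; (7) repeat.
    The round's estimator weight is ``learning_rate * log(1/beta)``.

    Stopping: a round with zero maximal loss (perfect fit) is kept with the
    capped weight ``learning_rate * log(1/BETA_FLOOR)`` and boosting halts;
    a round with ``Lbar > 0.5`` is discarded and boosting halts; ``Lbar ==
    0.5`` keeps the round with weight exactly 0 and halts.  If the first
    round is discarded no valid ensemble exists and :class:`FitError` is
    raised.
    """
    X, y = problem.features, problem.targets
    n = problem.n_samples
    if n < 2:
        raise FitError("AdaBoost needs at least 2 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise FitError("non-finite values in the training data")
    rng = np.random.default_rng(seed)

    w = np.full(n, 1.0 / n)
    trees: list[RegressionTree] = []
    est_weights: list[float] = []
    trace: list[dict] = []

    for t in range(int(n_rounds)):
        p = w / w.sum()
        bootstrap = rng.choice(n, size=n, replace=True, p=p)
        tree = fit_regression_tree(X[bootstrap], y[bootstrap], max_depth=max_depth)
        abs_err = np.abs(y - tree.predict(X))
        max_err = abs_err.max()
        record: dict = {"round": t, "max_abs_error": float(max_err)}
        if max_err == 0:
            weight = learning_rate * np.log(1.0 / BETA_FLOOR)
            trees.append(tree)
            est_weights.append(weight)
            record.update(
                avg_loss=0.0, beta=BETA_FLOOR, estimator_weight=weight,
                sample_weights=w.copy(), halted="zero_loss",
            )
            trace.append(record)
            break
        err = abs_err / max_err
        avg_loss = float((err * p).sum())
        record.update(err=err.copy(), avg_loss=avg_loss)
        if avg_loss > 0.5:
            record["halted"] = "discarded"
            trace.append(record)
            break
        beta = avg_loss / (1.0 - avg_loss)
        weight = learning_rate * np.log(1.0 / beta) if beta > 0 else (
            learning_rate * np.log(1.0 / BETA_FLOOR)
        )
        trees.append(tree)
        est_weights.append(weight)
        w = w * beta ** (1.0 - err)
        record.update(
            beta=beta, estimator_weight=weight, sample_weights=w.copy()
        )
        if avg_loss == 0.5:
            record["halted"] = "beta_one"
            trace.append(record)
            break
        trace.append(record)

    if not trees:
        raise FitError(
            "no boosting round retained (first round had average loss > 0.5)"
        )
    return BoostedEnsemble(
        trees=trees,
        estimator_weights=np.asarray(est_weights),
        method="adaboost",
        learning_rate=float(learning_rate),
        n_features=problem.n_regulators,
        trace=trace,
    )


def fit_graboost(
    problem: LaggedProblem,
    n_rounds: int = 100,
    learning_rate: float = 0.1,
    max_depth: int = 3,
    seed: int = 0,
) -> BoostedEnsemble:
    """Gradient boosting with squared loss and regression-tree learners.

    The model starts from the target mean and, each round, fits a tree to
    the residuals of the current additive model on the full data (no
    resampling), then adds it scaled by the learning rate.  The ``seed`` is
    accepted for interface uniformity; the procedure is deterministic.
    """
    X, y = problem.features, problem.targets
    if problem.n_samples < 2:
        raise FitError("gradient boosting needs at least 2 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise FitError("non-finite values in the training data")

    init = float(y.mean())
    pred = np.full(problem.n_samples, init)
    trees: list[RegressionTree] = []
    for _ in range(int(n_rounds)):
        residuals = y - pred
        tree = fit_regression_tree(X, residuals, max_depth=max_depth)
        pred = pred + learning_rate * tree.predict(X)
        trees.append(tree)

    return BoostedEnsemble(
        trees=trees,
        estimator_weights=np.full(len(trees), float(learning_rate)),
        method="graboost",
        learning_rate=float(learning_rate),
        n_features=problem.n_regulators,
        init_value=init,
    )


def ensemble_importance(
    ensemble: BoostedEnsemble, normalize: bool = True
) -> np.ndarray:
    """Aggregate per-tree VIS into the ensemble regulatory score vector.

    AdaBoost: estimator-weighted sum of per-tree VIS.  Gradient boosting:
    plain average of per-tree VIS.  With ``normalize`` (the default) the
    vector is scaled to unit sum when any entry is positive, which makes
    scores comparable across target genes.
    """
    if ensemble.n_rounds_completed < 1:
        raise ValueError("cannot score an empty ensemble")
    per_tree = np.stack([tree_variable_importance(t) for t in ensemble.trees])
    if ensemble.method == "adaboost":
        vis = ensemble.estimator_weights @ per_tree
    else:
        vis = per_tree.mean(axis=0)
    if normalize:
        total = vis.sum()
        if total > 0:
            vis = vis / total
    return vis
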