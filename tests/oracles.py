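"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by the most transparent possible route
(naive enumeration, explicit loops, direct formula transcription) so the
vectorized production code can be checked against it.
"""

from __future__ import annotations

import numpy as np

from boostgrn.boosted_trees import BETA_FLOOR, fit_regression_tree

# ---------------------------------------------------------------------------
# CART by naive exhaustive split search


class OracleNode:
    def __init__(self, n_samples, value, variance):
        self.n_samples = n_samples
        self.value = value
        self.variance = variance
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None


def _weighted_stats(y, w):
    mean = np.average(y, weights=w)
    var = np.average((y - mean) ** 2, weights=w)
    return mean, var


def oracle_cart(X, y, w=None, max_depth=2):
    """Greedy CART where every node's best split is found by brute force.

    At each node, every (feature, candidate threshold) pair is scored
    naively as w(S)Var(S) - w(S_l)Var(S_l) - w(S_r)Var(S_r); ties go to
    the lowest threshold value, then the lowest feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)

    def build(idx, depth):
        mean, var = _weighted_stats(y[idx], w[idx])
        node = OracleNode(len(idx), mean, var)
        if depth >= max_depth or len(idx) < 2 or np.all(y[idx] == y[idx[0]]):
            return node
        parent_score = w[idx].sum() * var
        # reductions this close are mathematical ties obscured by float
        # summation order (e.g. mirrored partitions from different features)
        tie_tol = 1e-9 * max(parent_score, 1e-300)
        best = None  # (reduction, feature, threshold)
        for k in range(X.shape[1]):
            values = np.unique(X[idx, k])
            for a, b in zip(values[:-1], values[1:]):
                thr = (a + b) / 2.0
                left = idx[X[idx, k] <= thr]
                right = idx[X[idx, k] > thr]
                _, lvar = _weighted_stats(y[left], w[left])
                _, rvar = _weighted_stats(y[right], w[right])
                reduction = (
                    parent_score - w[left].sum() * lvar - w[right].sum() * rvar
                )
                if (
                    best is None
                    or reduction > best[0] + tie_tol
                    or (reduction >= best[0] - tie_tol and thr < best[2])
                ):
                    best = (reduction, k, thr)
        if best is None or best[0] <= 0:
            return node
        _, k, thr = best
        node.feature = k
        node.threshold = thr
        node.left = build(idx[X[idx, k] <= thr], depth + 1)
        node.right = build(idx[X[idx, k] > thr], depth + 1)
        return node

    return build(np.arange(len(y)), 0)


def assert_same_tree(prod_node, oracle_node, rtol=1e-9):
    """Recursively compare a production tree with an oracle tree."""
    assert prod_node.n_samples == oracle_node.n_samples
    np.testing.assert_allclose(prod_node.value, oracle_node.value, rtol=rtol)
    if oracle_node.feature is None:
        assert prod_node.feature is None, (
            f"production split on {prod_node.feature} where oracle is a leaf"
        )
        return
    assert prod_node.feature == oracle_node.feature
    np.testing.assert_allclose(prod_node.threshold, oracle_node.threshold, rtol=rtol)
    assert_same_tree(prod_node.left, oracle_node.left, rtol)
    assert_same_tree(prod_node.right, oracle_node.right, rtol)


# ---------------------------------------------------------------------------
# variable importance recomputed from raw partitions


def oracle_tree_importance(tree, X, y, w=None):
    """Walk a fitted tree, re-partition the raw data at every split, and
    recompute per-feature variance reduction from scratch."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    importance = np.zeros(tree.n_features)

    def visit(node, idx):
        if node.is_leaf:
            return
        _, var = _weighted_stats(y[idx], w[idx])
        left = idx[X[idx, node.feature] <= node.threshold]
        right = idx[X[idx, node.feature] > node.threshold]
        _, lvar = _weighted_stats(y[left], w[left])
        _, rvar = _weighted_stats(y[right], w[right])
        importance[node.feature] += (
            w[idx].sum() * var - w[left].sum() * lvar - w[right].sum() * rvar
        )
        visit(node.left, left)
        visit(node.right, right)

    visit(tree.root, np.arange(len(y)))
    return importance


# ---------------------------------------------------------------------------
# AdaBoost.R2 transcript: a straight-line transcription of the seven steps


def oracle_adaboost_transcript(X, y, n_rounds, learning_rate, max_depth, seed):
    """Run the AdaBoost.R2 recipe step by step and record every round.

    Returns (rounds, halted) where each round dict carries the per-sample
    normalized errors, average loss, beta, estimator weight and the
    sample-weight vector after the update.  Raises ValueError if the first
    round is rejected (average loss > 0.5), mirroring the stated policy.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    # step 1: uniform initial sample weights
    w = np.full(n, 1.0 / n)
    rounds = []
    halted = None
    for t in range(n_rounds):
        # step 2: bootstrap of size N with probability proportional to w
        p = w / w.sum()
        sample = rng.choice(n, size=n, replace=True, p=p)
        # step 3: fit the base tree on the bootstrap sample
        tree = fit_regression_tree(X[sample], y[sample], max_depth=max_depth)
        # step 4: linear loss on the ORIGINAL samples, normalized by the max
        abs_err = np.abs(y - tree.predict(X))
        max_err = abs_err.max()
        if max_err == 0:
            weight = learning_rate * np.log(1.0 / BETA_FLOOR)
            rounds.append(
                dict(avg_loss=0.0, beta=BETA_FLOOR, estimator_weight=weight,
                     sample_weights=w.copy())
            )
            halted = "zero_loss"
            break
        err = abs_err / max_err
        # step 5: average loss under the renormalized weights
        avg_loss = float(np.sum(err * p))
        if avg_loss > 0.5:
            halted = "discarded"
            break
        # step 6: beta and the multiplicative weight update
        beta = avg_loss / (1.0 - avg_loss)
        if beta > 0:
            weight = learning_rate * np.log(1.0 / beta)
        else:
            weight = learning_rate * np.log(1.0 / BETA_FLOOR)
        w = w * beta ** (1.0 - err)
        rounds.append(
            dict(err=err, avg_loss=avg_loss, beta=beta,
                 estimator_weight=weight, sample_weights=w.copy())
        )
        if avg_loss == 0.5:
            halted = "beta_one"
            break
        # step 7: repeat
    if not rounds:
        raise ValueError("first round rejected")
    return rounds, halted


# ---------------------------------------------------------------------------
# ranking metrics by brute force


def oracle_auroc(scores, labels):
    """Pair counting: P(score_pos > score_neg) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_aupr(scores, labels):
    """Descending-score sweep with tied scores as one block:
    sum over blocks of (R_k - R_{k-1}) * Prec_k."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    tp = 0
    fp = 0
    prev_recall = 0.0
    area = 0.0
    for value in sorted(set(scores), reverse=True):
        block = labels[scores == value]
        tp += int(block.sum())
        fp += int(len(block) - block.sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
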