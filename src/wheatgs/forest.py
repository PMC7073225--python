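"""Seeded regression forest for genomic prediction (model id ``RForest``).

Each tree is grown on a bootstrap sample of the lines by recursive binary
splitting: at every node a random subset of ``mtry`` markers is drawn and
the split maximizing the reduction in within-node variance is taken
(evaluated in vectorized form over all candidate markers at once).  Growth
stops at ``min_node_size`` samples or ``max_depth``.  The forest prediction
is the mean of the per-tree predictions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin


class _Tree:
    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []

    def add_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(np.nan)
        return len(self.value) - 1

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        node_of = np.zeros(X.shape[0], dtype=int)
        active = np.arange(X.shape[0])
        feature = np.asarray(self.feature)
        threshold = np.asarray(self.threshold)
        left = np.asarray(self.left)
        right = np.asarray(self.right)
        value = np.asarray(self.value)
        while active.size:
            nodes = node_of[active]
            leaf = feature[nodes] < 0
            if leaf.any():
                idx = active[leaf]
                out[idx] = value[node_of[idx]]
                active = active[~leaf]
                nodes = node_of[active]
            if not active.size:
                break
            go_left = (
                X[active, feature[nodes]] <= threshold[nodes]
            )
            node_of[active] = np.where(
                go_left, left[nodes], right[nodes]
            )
        return out


def _best_split(Xn, yn, feats, min_leaf):
    """Vectorized best variance-reduction split over candidate features.

    Returns (feature, threshold, left_mask) or None when no valid split
    exists.  Score maximized: sum_L^2/n_L + sum_R^2/n_R (equivalent to
    minimizing within-node SSE).
    """
    n = yn.size
    sub = Xn[:, feats]
    order = np.argsort(sub, axis=0, kind="stable")
    ys = yn[order]  # n x f, y sorted per feature
    xs = np.take_along_axis(sub, order, axis=0)
    csum = np.cumsum(ys, axis=0)
    total = csum[-1, :]
    k = np.arange(1, n)[:, None]  # left counts for split after row k-1
    sum_l = csum[:-1, :]
    score = sum_l**2 / k + (total[None, :] - sum_l) ** 2 / (n - k)
    valid = xs[1:, :] > xs[:-1, :]  # boundary must separate distinct values
    if min_leaf > 1:
        valid[: min_leaf - 1, :] = False
        if min_leaf - 1 > 0:
            valid[-(min_leaf - 1):, :] = False
    score = np.where(valid, score, -np.inf)
    flat = int(np.argmax(score))
    if not np.isfinite(score.flat[flat]):
        return None
    row, col = np.unravel_index(flat, score.shape)
    base = total[col] ** 2 / n
    if score[row, col] <= base + 1e-12:
        return None
    thr = 0.5 * (xs[row, col] + xs[row + 1, col])
    feat = int(feats[col])
    left_mask = Xn[:, feat] <= thr
    return feat, float(thr), left_mask


class RandomForestGS(BaseEstimator, RegressorMixin):
    """Regression forest over marker codes.

    Parameters
    ----------
    n_trees
        Number of bootstrap trees (default 500).
    mtry
        Markers sampled per node; default max(1, m // 3).
    min_node_size
        Minimum samples per leaf (default 5).
    max_depth
        Depth cap; ``None`` grows to purity / node-size limits, 0 makes each
        tree the bootstrap-sample mean.
    random_state
        Seed; fixed seed gives an identical forest.
    """

    model_id = "RForest"

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 min_node_size: int = 5, max_depth: int | None = None,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        n, m = X.shape
        mtry = self.mtry if self.mtry is not None else max(1, m // 3)
        if not 1 <= mtry <= m:
            raise ValueError(f"mtry must be in [1, {m}]")
        root_seq = np.random.SeedSequence(self.random_state)
        self.trees_ = []
        for seq in root_seq.spawn(self.n_trees):
            rng = np.random.default_rng(seq)
            boot = rng.integers(0, n, size=n)
            self.trees_.append(
                self._grow(X[boot], y[boot], rng, mtry)
            )
        self.n_features_in_ = m
        return self

    def _grow(self, Xb, yb, rng, mtry) -> _Tree:
        tree = _Tree()
        m = Xb.shape[1]
        stack = [(tree.add_node(), np.arange(Xb.shape[0]), 0)]
        while stack:
            node, idx, depth = stack.pop()
            yn = yb[idx]
            tree.value[node] = float(yn.mean())
            if (
                (self.max_depth is not None and depth >= self.max_depth)
                or yn.size < 2 * self.min_node_size
                or np.ptp(yn) == 0.0
            ):
                continue
            feats = rng.choice(m, size=min(mtry, m), replace=False)
            split = _best_split(Xb[idx], yn, feats, self.min_node_size)
            if split is None:
                continue
            feat, thr, left_mask = split
            tree.feature[node] = feat
            tree.threshold[node] = thr
            l_id, r_id = tree.add_node(), tree.add_node()
            tree.left[node], tree.right[node] = l_id, r_id
            stack.append((l_id, idx[left_mask], depth + 1))
            stack.append((r_id, idx[~left_mask], depth + 1))
        return tree

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        preds = np.zeros(X.shape[0])
        for tree in self.trees_:
            preds += tree.predict(X)
        return preds / len(self.trees_)
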