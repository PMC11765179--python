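"""Regression tree surrogate: greedy CART with variance-reduction splits.

Each internal node holds a (feature, threshold) rule; each leaf predicts
the mean response of its training subset.  Splits minimize the summed
squared error of the two children; candidate thresholds are midpoints
between consecutive sorted unique feature values.  Ties are broken
deterministically: lowest feature index first, then lowest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FEATURE_NAMES

__all__ = ["RegressionTree", "fit_tree", "select_depth_cv"]

_LEAF = -1


@dataclass
class RegressionTree:
    """Flat-array binary regression tree.

    ``feature[i] == -1`` marks node i as a leaf with prediction
    ``value[i]``; otherwise samples with x[feature[i]] <= threshold[i]
    go to ``left[i]`` and the rest to ``right[i]``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_samples: np.ndarray
    max_depth: int | None
    min_leaf: int
    importance_raw: np.ndarray = field(default_factory=lambda: np.zeros(len(FEATURE_NAMES)))

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature == _LEAF))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            feat = self.feature[node]
            active = feat != _LEAF
            if not active.any():
                break
            idx = np.nonzero(active)[0]
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
        return self.value[node]

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index reached by each row (for leaf-identity checks)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        node = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            feat = self.feature[node]
            active = feat != _LEAF
            if not active.any():
                break
            idx = np.nonzero(active)[0]
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
        return node

    def to_dict(self) -> dict:
        def node_dict(i: int) -> dict:
            if self.feature[i] == _LEAF:
                return {"value": float(self.value[i]), "n": int(self.n_samples[i])}
            return {
                "feature": FEATURE_NAMES[self.feature[i]],
                "threshold": float(self.threshold[i]),
                "n": int(self.n_samples[i]),
                "left": node_dict(int(self.left[i])),
                "right": node_dict(int(self.right[i])),
            }

        return {
            "kind": "tree",
            "max_depth": self.max_depth,
            "min_leaf": self.min_leaf,
            "root": node_dict(0),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        feature, threshold, left, right, value, n_samples = [], [], [], [], [], []

        def add(node: dict) -> int:
            i = len(feature)
            feature.append(0)
            threshold.append(0.0)
            left.append(_LEAF)
            right.append(_LEAF)
            value.append(0.0)
            n_samples.append(node.get("n", 0))
            if "feature" in node:
                feature[i] = FEATURE_NAMES.index(node["feature"])
                threshold[i] = node["threshold"]
                left[i] = add(node["left"])
                right[i] = add(node["right"])
            else:
                feature[i] = _LEAF
                value[i] = node["value"]
            return i

        add(d["root"])
        return cls(
            np.array(feature), np.array(threshold), np.array(left, dtype=np.int64),
            np.array(right, dtype=np.int64), np.array(value), np.array(n_samples),
            d.get("max_depth"), d.get("min_leaf", 1),
        )


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (threshold, sse) for one feature, or None if unsplittable.

    Uses prefix sums over the sorted order; among equal-SSE splits the
    lowest threshold wins (argmin returns the first, thresholds ascend).
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    n = xs.size
    s1 = np.cumsum(ys)
    s2 = np.cumsum(ys * ys)
    # split after position i (left gets i+1 samples), i in [min_leaf-1, n-min_leaf-1]
    i = np.arange(min_leaf - 1, n - min_leaf)
    if i.size == 0:
        return None
    valid = xs[i] < xs[i + 1]
    if not valid.any():
        return None
    i = i[valid]
    nl = (i + 1).astype(float)
    nr = n - nl
    sse_l = s2[i] - s1[i] ** 2 / nl
    sse_r = (s2[-1] - s2[i]) - (s1[-1] - s1[i]) ** 2 / nr
    total = sse_l + sse_r
    k = int(np.argmin(total))
    thr = 0.5 * (xs[i[k]] + xs[i[k] + 1])
    return float(thr), float(total[k])


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int | None = None,
    min_leaf: int = 1,
    _feature_sampler=None,
) -> RegressionTree:
    """Grow a regression tree by greedy variance-reduction splitting.

    ``max_depth=0`` yields a single leaf predicting the global mean.
    ``_feature_sampler(rng_state) -> array of feature indices`` hooks the
    per-split feature subsampling used by the random forest; by default
    every feature is a candidate at every split.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, n_feat = X.shape
    if n < max(1, min_leaf):
        raise ValueError("not enough samples")

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []
    counts: list[int] = []
    importance = np.zeros(n_feat)

    def new_node() -> int:
        feature.append(_LEAF)
        threshold.append(0.0)
        left.append(_LEAF)
        right.append(_LEAF)
        value.append(0.0)
        counts.append(0)
        return len(feature) - 1

    def build(idx: np.ndarray, depth: int) -> int:
        node = new_node()
        yi = y[idx]
        counts[node] = idx.size
        value[node] = float(yi.mean())
        sse_parent = float(np.sum((yi - yi.mean()) ** 2))
        if (
            (max_depth is not None and depth >= max_depth)
            or idx.size < 2 * min_leaf
            or sse_parent <= 1e-300
        ):
            return node

        candidates = (
            np.arange(n_feat) if _feature_sampler is None else np.sort(_feature_sampler())
        )
        best = None  # (sse, feature, threshold)
        for f in candidates:
            res = _best_split(X[idx, f], yi, min_leaf)
            if res is None:
                continue
            thr, sse = res
            if best is None or sse < best[0]:  # strict: lower feature index wins ties
                best = (sse, int(f), thr)
        if best is None or not (best[0] < sse_parent):
            return node

        sse, f, thr = best
        go_left = X[idx, f] <= thr
        feature[node] = f
        threshold[node] = thr
        importance[f] += sse_parent - sse
        left[node] = build(idx[go_left], depth + 1)
        right[node] = build(idx[~go_left], depth + 1)
        return node

    build(np.arange(n), 0)
    tree = RegressionTree(
        np.array(feature), np.array(threshold), np.array(left, dtype=np.int64),
        np.array(right, dtype=np.int64), np.array(value), np.array(counts),
        max_depth, min_leaf, importance,
    )
    return tree


def select_depth_cv(
    X: np.ndarray,
    y: np.ndarray,
    depths=range(1, 16),
    n_folds: int = 5,
    min_leaf: int = 1,
    seed: int = 0,
) -> tuple[int, dict[int, tuple[float, float]]]:
    """Choose the tree depth by k-fold cross-validation with a 1-SE rule.

    Returns the smallest depth whose mean CV R² is within one standard
    error of the best depth's mean, plus per-depth (mean, se) scores.
    """
    from .evaluation import evaluate

    depths = sorted(set(depths))
    if not depths:
        raise ValueError("depth range must be non-empty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2 * n_folds:
        raise ValueError(f"{n_folds}-fold CV needs at least {2 * n_folds} samples")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    scores: dict[int, tuple[float, float]] = {}
    for d in depths:
        r2s = []
        for k in range(n_folds):
            test_idx = folds[k]
            train_idx = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            if test_idx.size < 2:
                raise ValueError("fold with fewer than 2 points")
            tree = fit_tree(X[train_idx], y[train_idx], max_depth=d, min_leaf=min_leaf)
            r2s.append(evaluate(tree, X[test_idx], y[test_idx]).r2)
        r2s = np.asarray(r2s)
        scores[d] = (float(r2s.mean()), float(r2s.std(ddof=1) / np.sqrt(n_folds)))

    best_depth = max(scores, key=lambda d: scores[d][0])
    best_mean, best_se = scores[best_depth]
    for d in depths:  # ascending: smallest depth within one SE wins
        if scores[d][0] >= best_mean - best_se:
            return d, scores
    return best_depth, scores
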