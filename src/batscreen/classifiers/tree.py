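"""Binary decision tree with Gini impurity and exhaustive midpoint splits.

Candidate thresholds are the midpoints of consecutive sorted unique values
of each feature.  Ties in Gini gain break toward the lowest feature index,
then the lowest threshold, so the grown tree is fully deterministic.
Default stopping hyperparameters: max depth 10, min samples to split 2,
min samples per leaf 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TreeNode:
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: int | None = None
    counts: tuple[int, int] | None = None  # (n class 0, n class 1)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"label": self.label, "counts": list(self.counts)}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def gini_impurity(class_counts) -> float:
    """1 - sum p_i^2; 0 for a pure node, 0.5 at a balanced binary node."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.sum() <= 0 or (counts < 0).any():
        raise ValueError("class counts must be nonnegative with positive total")
    p = counts / counts.sum()
    return float(1.0 - np.sum(p**2))


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    min_samples_leaf: int = 1,
) -> tuple[int, float, float] | None:
    """Exhaustive best (feature, threshold, gain); None without positive gain."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    parent = gini_impurity(np.bincount(y, minlength=2))
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        cum_pos = np.cumsum(ys)
        # split after position i (left size i + 1), threshold at the midpoint
        for i in range(n - 1):
            if xs[i] == xs[i + 1]:
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_samples_leaf or n_right < min_samples_leaf:
                continue
            pos_left = cum_pos[i]
            pos_right = cum_pos[-1] - pos_left
            g_left = gini_impurity((n_left - pos_left, pos_left))
            g_right = gini_impurity((n_right - pos_right, pos_right))
            gain = parent - (n_left * g_left + n_right * g_right) / n
            # strict improvement keeps the lowest feature index / threshold
            if gain > 1e-15 and (best is None or gain > best[2] + 1e-15):
                best = (j, float((xs[i] + xs[i + 1]) / 2.0), float(gain))
    return best


def _majority(y: np.ndarray) -> tuple[int, tuple[int, int]]:
    counts = np.bincount(y, minlength=2)
    # argmax returns the first maximum, so a tie yields class 0
    return int(np.argmax(counts)), (int(counts[0]), int(counts[1]))


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int = 10,
    min_samples_split: int = 2,
    min_samples_leaf: int = 1,
    _depth: int = 0,
) -> TreeNode:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("cannot grow a tree from no rows")
    label, counts = _majority(y)
    if (
        _depth >= max_depth
        or len(y) < min_samples_split
        or len(np.unique(y)) == 1
    ):
        return TreeNode(label=label, counts=counts)
    found = best_split(X, y, min_samples_leaf)
    if found is None:
        return TreeNode(label=label, counts=counts)
    j, thr, _ = found
    mask = X[:, j] <= thr
    kwargs = dict(
        max_depth=max_depth,
        min_samples_split=min_samples_split,
        min_samples_leaf=min_samples_leaf,
        _depth=_depth + 1,
    )
    return TreeNode(
        feature=j,
        threshold=thr,
        left=grow_tree(X[mask], y[mask], **kwargs),
        right=grow_tree(X[~mask], y[~mask], **kwargs),
    )


def _predict_one(node: TreeNode, x: np.ndarray, proba: bool):
    while not node.is_leaf:
        node = node.left if x[node.feature] <= node.threshold else node.right
    if proba:
        n0, n1 = node.counts
        return n1 / (n0 + n1)
    return node.label


def tree_predict(root: TreeNode, X: np.ndarray, proba: bool = False) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.array([_predict_one(root, row, proba) for row in X])
    return out if proba else out.astype(int)
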