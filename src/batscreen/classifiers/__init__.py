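"""From-scratch screening classifiers.

Four binary classifiers implemented directly on numpy:

* :func:`~batscreen.classifiers.nn.ann_fit` — feed-forward network (ReLU
  hidden layers, sigmoid output) trained with mini-batch Adam on binary
  cross-entropy;
* :func:`~batscreen.classifiers.nn.wo_ann_fit` — the same network trained
  by a teaching-learning population search over flattened weight vectors
  instead of gradients;
* :func:`~batscreen.classifiers.tree.grow_tree` — Gini decision tree with
  exhaustive midpoint splits;
* :class:`~batscreen.classifiers.knn.KNNModel` — Euclidean k-nearest
  neighbours with deterministic tie-breaking.

`make_classifier` gives them a uniform fit/predict surface for the tuner.
"""

from .knn import KNNModel, knn_predict
from .nn import (
    MLPParams,
    TrainConfig,
    WeightOptConfig,
    ann_fit,
    ann_forward,
    ann_predict,
    flatten_params,
    init_params,
    unflatten_params,
    wo_ann_fit,
)
from .tree import TreeNode, best_split, gini_impurity, grow_tree, tree_predict

__all__ = [
    "KNNModel",
    "knn_predict",
    "MLPParams",
    "TrainConfig",
    "WeightOptConfig",
    "ann_fit",
    "ann_forward",
    "ann_predict",
    "flatten_params",
    "init_params",
    "unflatten_params",
    "wo_ann_fit",
    "TreeNode",
    "best_split",
    "gini_impurity",
    "grow_tree",
    "tree_predict",
    "make_classifier",
]


class _KNNWrapper:
    kind = "knn"

    def __init__(self, k=5):
        self.k = int(k)
        self.model = None

    def fit(self, X, y):
        self.model = KNNModel(k=self.k).fit(X, y)
        return self

    def predict(self, X):
        return self.model.predict(X)

    def scores(self, X):
        return self.model.vote_fractions(X)


class _TreeWrapper:
    kind = "dt"

    def __init__(self, max_depth=10, min_samples_split=2, min_samples_leaf=1):
        self.max_depth = int(max_depth)
        self.min_samples_split = int(min_samples_split)
        self.min_samples_leaf = int(min_samples_leaf)
        self.root = None

    def fit(self, X, y):
        self.root = grow_tree(
            X, y,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
        )
        return self

    def predict(self, X):
        return tree_predict(self.root, X)

    def scores(self, X):
        return tree_predict(self.root, X, proba=True)


class _ANNWrapper:
    kind = "ann"

    def __init__(self, hidden=(15, 15), learning_rate=0.001, epochs=100,
                 batch_size=64, seed=0):
        self.hidden = tuple(int(h) for h in hidden)
        self.cfg = TrainConfig(
            learning_rate=float(learning_rate),
            epochs=int(epochs),
            batch_size=int(batch_size),
            seed=int(seed),
        )
        self.params = None

    def fit(self, X, y):
        self.params = ann_fit(X, y, hidden=self.hidden, cfg=self.cfg)
        return self

    def predict(self, X):
        return (ann_predict(self.params, X) >= 0.5).astype(int)

    def scores(self, X):
        return ann_predict(self.params, X)


class _WOANNWrapper:
    kind = "wo_ann"

    def __init__(self, hidden=(50, 15), pop_size=20, generations=50, seed=0):
        self.hidden = tuple(int(h) for h in hidden)
        self.cfg = WeightOptConfig(
            pop_size=int(pop_size), generations=int(generations), seed=int(seed)
        )
        self.params = None

    def fit(self, X, y):
        self.params, _ = wo_ann_fit(X, y, hidden=self.hidden, cfg=self.cfg)
        return self

    def predict(self, X):
        return (ann_predict(self.params, X) >= 0.5).astype(int)

    def scores(self, X):
        return ann_predict(self.params, X)


_REGISTRY = {
    "knn": _KNNWrapper,
    "dt": _TreeWrapper,
    "ann": _ANNWrapper,
    "wo_ann": _WOANNWrapper,
}


def make_classifier(kind: str, **params):
    """Instantiate a classifier by name with keyword hyperparameters."""
    try:
        cls = _REGISTRY[kind]
    except KeyError:
        raise ValueError(
            f"unknown classifier {kind!r}; choose from {sorted(_REGISTRY)}"
        ) from None
    return cls(**params)
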