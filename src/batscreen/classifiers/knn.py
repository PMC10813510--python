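"""k-nearest neighbours with Euclidean distance and majority vote.

Tie-breaking is deterministic: equal distances prefer the lower training
index, equal votes prefer the lower class label.  Default k = 5.
"""

from __future__ import annotations

import numpy as np


class KNNModel:
    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = int(k)
        self.X: np.ndarray | None = None
        self.y: np.ndarray | None = None

    def fit(self, X, y) -> "KNNModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("features and labels differ in length")
        if self.k > len(X):
            raise ValueError(f"k={self.k} exceeds the {len(X)} training rows")
        self.X, self.y = X, y
        return self

    def _neighbour_labels(self, X_query: np.ndarray) -> np.ndarray:
        if self.X is None:
            raise ValueError("model is not fitted")
        X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
        d2 = ((X_query[:, None, :] - self.X[None, :, :]) ** 2).sum(axis=2)
        # stable sort: equal distances keep ascending training-index order
        order = np.argsort(d2, axis=1, kind="stable")[:, : self.k]
        return self.y[order]

    def predict(self, X_query) -> np.ndarray:
        labels = self._neighbour_labels(X_query)
        out = np.empty(len(labels), dtype=int)
        for i, row in enumerate(labels):
            counts = np.bincount(row, minlength=2)
            out[i] = int(np.argmax(counts))  # vote tie -> lower label
        return out

    def vote_fractions(self, X_query) -> np.ndarray:
        """Fraction of the k neighbours voting class 1 (a soft score)."""
        return self._neighbour_labels(X_query).mean(axis=1)


def knn_predict(model: KNNModel, x) -> int:
    """Predict a single query point."""
    return int(model.predict(np.asarray(x, dtype=float)[None, :])[0])
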