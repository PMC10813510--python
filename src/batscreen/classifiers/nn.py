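"""Feed-forward networks: gradient training and population weight training.

The network is a fully connected multilayer perceptron with ReLU hidden
activations and a single sigmoid output unit giving P(class = 1).  Two
trainers are provided:

``ann_fit``
    mini-batch Adam on binary cross-entropy (squared error available),
    default architecture two hidden layers of 15 units, learning rate
    0.001, batch size 64, 100 epochs;

``wo_ann_fit``
    a teaching-learning population search over flattened weight vectors:
    each generation every member moves toward the best member ("teacher")
    minus TF times the population mean (TF drawn from {1, 2}), then random
    member pairs exchange information (the worse moves toward the better,
    the better moves away), the best-ever vector replaces the current
    worst, and exact duplicates are mutated by resetting a quarter of
    their coordinates to the population mid-range.  Fitness is the
    training-set loss of the assembled network.  Default architecture has
    hidden layers of 50 and 15 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class MLPParams:
    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "MLPParams":
        return MLPParams(
            layer_sizes=list(self.layer_sizes),
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 64
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    loss: str = "bce"  # or "squared"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("bce", "squared"):
            raise ValueError(f"unknown loss {self.loss!r}")


def init_params(layer_sizes: list[int], rng: np.random.Generator) -> MLPParams:
    """Uniform [-0.5, 0.5] scaled by 1/sqrt(fan-in)."""
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes, layer_sizes[1:]):
        scale = 1.0 / math.sqrt(fan_in)
        weights.append(rng.uniform(-0.5, 0.5, size=(fan_in, fan_out)) * scale)
        biases.append(rng.uniform(-0.5, 0.5, size=fan_out) * scale)
    return MLPParams(layer_sizes=list(layer_sizes), weights=weights, biases=biases)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def ann_predict(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """Forward pass for a batch; returns P(class = 1) per row."""
    A = np.atleast_2d(np.asarray(X, dtype=float))
    if A.shape[1] != params.layer_sizes[0]:
        raise ValueError(
            f"expected {params.layer_sizes[0]} input features, got {A.shape[1]}"
        )
    n_layers = len(params.weights)
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        Z = A @ W + b
        A = _sigmoid(Z) if i == n_layers - 1 else np.maximum(Z, 0.0)
    return A[:, 0]


def ann_forward(params: MLPParams, x) -> float:
    """Forward pass for a single feature vector."""
    return float(ann_predict(params, np.asarray(x, dtype=float)[None, :])[0])


def bce_loss(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def squared_loss(probs: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((probs - y) ** 2))


def training_loss(params: MLPParams, X: np.ndarray, y: np.ndarray, loss: str = "bce") -> float:
    probs = ann_predict(params, X)
    return bce_loss(probs, y) if loss == "bce" else squared_loss(probs, y)


def _forward_cached(params: MLPParams, X: np.ndarray):
    acts = [X]
    n_layers = len(params.weights)
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        Z = acts[-1] @ W + b
        acts.append(_sigmoid(Z) if i == n_layers - 1 else np.maximum(Z, 0.0))
    return acts


def _backward(params: MLPParams, acts, y: np.ndarray, loss: str):
    n = len(y)
    probs = acts[-1][:, 0]
    if loss == "bce":
        delta = (probs - y)[:, None] / n  # d BCE / d z_out through the sigmoid
    else:
        p = probs
        delta = (2.0 * (p - y) * p * (1.0 - p))[:, None] / n
    grads_w, grads_b = [], []
    for i in range(len(params.weights) - 1, -1, -1):
        grads_w.append(acts[i].T @ delta)
        grads_b.append(delta.sum(axis=0))
        if i > 0:
            delta = (delta @ params.weights[i].T) * (acts[i] > 0)
    return grads_w[::-1], grads_b[::-1]


def ann_fit(
    X: np.ndarray,
    y: np.ndarray,
    hidden: tuple[int, ...] = (15, 15),
    cfg: TrainConfig | None = None,
) -> MLPParams:
    """Train by mini-batch Adam on the configured loss; deterministic per seed."""
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    layer_sizes = [X.shape[1], *hidden, 1]
    rng = np.random.default_rng(cfg.seed)
    params = init_params(layer_sizes, rng)

    m_w = [np.zeros_like(w) for w in params.weights]
    v_w = [np.zeros_like(w) for w in params.weights]
    m_b = [np.zeros_like(b) for b in params.biases]
    v_b = [np.zeros_like(b) for b in params.biases]
    step = 0
    n = len(y)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            acts = _forward_cached(params, X[batch])
            gw, gb = _backward(params, acts, y[batch], cfg.loss)
            step += 1
            bc1 = 1.0 - cfg.adam_beta1**step
            bc2 = 1.0 - cfg.adam_beta2**step
            for i in range(len(params.weights)):
                for g, m, v, target in (
                    (gw[i], m_w, v_w, params.weights),
                    (gb[i], m_b, v_b, params.biases),
                ):
                    m[i] = cfg.adam_beta1 * m[i] + (1 - cfg.adam_beta1) * g
                    v[i] = cfg.adam_beta2 * v[i] + (1 - cfg.adam_beta2) * g**2
                    target[i] -= (
                        cfg.learning_rate * (m[i] / bc1)
                        / (np.sqrt(v[i] / bc2) + cfg.adam_eps)
                    )
    final = training_loss(params, X, y, cfg.loss)
    if not math.isfinite(final):
        raise FloatingPointError("training diverged to a non-finite loss")
    return params


# ---------------------------------------------------------------------------
# population (teaching-learning) weight optimisation


@dataclass
class WeightOptConfig:
    pop_size: int = 20
    generations: int = 50
    loss: str = "bce"
    plateau_patience: int = 20
    plateau_tol: float = 1e-8
    #: optional Adam warm-start: epochs of gradient descent seeding one member
    warm_start_epochs: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 4:
            raise ValueError("population needs at least 4 members")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def flatten_params(params: MLPParams) -> np.ndarray:
    return np.concatenate(
        [w.ravel() for w in params.weights] + [b.ravel() for b in params.biases]
    )


def unflatten_params(vec: np.ndarray, layer_sizes: list[int]) -> MLPParams:
    weights, biases = [], []
    pos = 0
    for fan_in, fan_out in zip(layer_sizes, layer_sizes[1:]):
        weights.append(vec[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out))
        pos += fan_in * fan_out
    for _, fan_out in zip(layer_sizes, layer_sizes[1:]):
        biases.append(vec[pos : pos + fan_out].copy())
        pos += fan_out
    return MLPParams(layer_sizes=list(layer_sizes), weights=weights, biases=biases)


def teaching_factor(rng: np.random.Generator) -> int:
    """TF = round(1 + u(2 - 1)), u ~ U[0, 1]; takes only the values 1 and 2."""
    return int(round(1.0 + rng.uniform() * (2.0 - 1.0)))


def wo_ann_fit(
    X: np.ndarray,
    y: np.ndarray,
    hidden: tuple[int, ...] = (50, 15),
    cfg: WeightOptConfig | None = None,
) -> tuple[MLPParams, list[float]]:
    """Population-optimise network weights; returns (params, elite history).

    Elite fitness is non-increasing by construction: the best-ever weight
    vector is preserved and reinjected over the current worst each
    generation.
    """
    cfg = cfg or WeightOptConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    layer_sizes = [X.shape[1], *hidden, 1]
    rng = np.random.default_rng(cfg.seed)

    def fitness(vec: np.ndarray) -> float:
        return training_loss(unflatten_params(vec, layer_sizes), X, y, cfg.loss)

    pop = np.stack(
        [flatten_params(init_params(layer_sizes, rng)) for _ in range(cfg.pop_size)]
    )
    if cfg.warm_start_epochs > 0:
        warm = ann_fit(
            X, y, hidden=hidden,
            cfg=TrainConfig(epochs=cfg.warm_start_epochs, seed=cfg.seed),
        )
        pop[0] = flatten_params(warm)
    fits = np.array([fitness(v) for v in pop])

    elite = pop[int(np.argmin(fits))].copy()
    elite_fit = float(fits.min())
    history = [elite_fit]
    stale = 0

    n = cfg.pop_size
    for _ in range(cfg.generations):
        mean = pop.mean(axis=0)
        teacher = pop[int(np.argmin(fits))]

        # teacher phase with greedy replacement
        for i in range(n):
            tf = teaching_factor(rng)
            cand = pop[i] + rng.uniform() * (teacher - tf * mean)
            f = fitness(cand)
            if f < fits[i]:
                pop[i], fits[i] = cand, f

        # learner phase: random pairs, worse learns from better,
        # better moves away from worse; greedy acceptance
        for _ in range(n):
            i, j = rng.choice(n, size=2, replace=False)
            direction = pop[i] - pop[j] if fits[i] < fits[j] else pop[j] - pop[i]
            cand = pop[i] + rng.uniform() * direction
            f = fitness(cand)
            if f < fits[i]:
                pop[i], fits[i] = cand, f

        # elite preservation: best-ever replaces the current worst
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < elite_fit - cfg.plateau_tol:
            stale = 0
        else:
            stale += 1
        if fits[gen_best] < elite_fit:
            elite, elite_fit = pop[gen_best].copy(), float(fits[gen_best])
        worst = int(np.argmax(fits))
        pop[worst], fits[worst] = elite.copy(), elite_fit

        # duplicate mutation: reset a quarter of coordinates to the
        # population mid-range of that coordinate
        lo, hi = pop.min(axis=0), pop.max(axis=0)
        length = pop.shape[1]
        k = max(1, int(round(length / 4)))
        for i in range(1, n):
            if any(np.array_equal(pop[i], pop[j]) for j in range(i)):
                coords = rng.choice(length, size=k, replace=False)
                pop[i, coords] = (lo[coords] + hi[coords]) / 2.0
                fits[i] = fitness(pop[i])

        history.append(elite_fit)
        if cfg.plateau_patience and stale >= cfg.plateau_patience:
            break

    return unflatten_params(elite, layer_sizes), history
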