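"""Metaheuristic hyperparameter tuning of the screening classifiers.

A classifier configuration is encoded as a point in a box-bounded
continuous search space; the bat algorithm or the modified bat algorithm
minimises the inner-validation error of the decoded configuration.  Four
dimension kinds are supported:

* ``integer`` — decoded by rounding (e.g. the number of neighbours k);
* ``real`` — passed through (e.g. a per-feature distance weight);
* ``log-real`` — decoded as 10**x (e.g. a learning rate);
* ``mask-bit`` — decoded by a strict > 0.5 threshold (feature selection).

Fitness is 1 minus the accuracy on a stratified holdout carved from the
training split (a quarter by default); the untouched test split enters
only once, after tuning, when the best configuration is refit on the full
training split and evaluated.  For the k-nearest-neighbour classifier the
default space learns continuous per-feature distance weights rather than
hard mask bits — the error surface is far friendlier to a swarm search,
and a weight of zero recovers feature removal as a special case.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bat import BAConfig, run_ba
from .classifiers import make_classifier
from .data import split_train_test
from .mba import MBAConfig, run_mba
from .metrics import ConfusionMatrix, confusion, metric_report, roc_auc


@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    kind: str  # integer | real | log-real | mask-bit

    def __post_init__(self):
        if self.lower >= self.upper:
            raise ValueError(f"dimension {self.name!r}: lower must be < upper")
        if self.kind not in ("integer", "real", "log-real", "mask-bit"):
            raise ValueError(f"dimension {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class SearchSpace:
    """Box-bounded search dimensions, optionally tied to feature columns.

    ``weight:<g>`` and ``mask:<g>`` dimension names address feature columns;
    ``<g>`` is either a column index or a key of ``feature_groups``, a
    mapping from a group name to the column indices it covers (e.g. all ten
    questionnaire items as one group).  Group dimensions let the optimiser
    steer whole blocks of columns with a single coordinate, which keeps the
    space low-dimensional.
    """

    dims: list[Dimension]
    n_features: int | None = None
    feature_groups: dict[str, list[int]] | None = None

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dims]

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dims])

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dims])

    def column_indices(self, token: str) -> list[int]:
        if self.feature_groups and token in self.feature_groups:
            return list(self.feature_groups[token])
        return [int(token)]


def default_search_space(
    kind: str,
    n_features: int,
    feature_groups: dict[str, list[int]] | None = None,
) -> SearchSpace:
    """The stock space per classifier family.

    knn: k in [1, 25] plus one distance weight per feature (or per feature
    group when ``feature_groups`` is given).
    dt: max_depth in [1, 20], min_samples_leaf in [1, 10].
    ann: two hidden sizes in [4, 64], learning rate 10**[-4, -1].
    wo_ann: hidden sizes in [4, 64] and [2, 16] plus feature (group) mask
    bits.
    """
    tokens = list(feature_groups) if feature_groups else [str(j) for j in range(n_features)]
    if kind == "knn":
        # log-scaled weights: relative feature importances span decades,
        # and a log box gives the sparse corners usable volume
        dims = [Dimension("k", 1, 25, "integer")]
        dims += [Dimension(f"weight:{t}", -3.0, 0.0, "log-real") for t in tokens]
    elif kind == "dt":
        dims = [
            Dimension("max_depth", 1, 20, "integer"),
            Dimension("min_samples_leaf", 1, 10, "integer"),
        ]
    elif kind == "ann":
        dims = [
            Dimension("hidden1", 4, 64, "integer"),
            Dimension("hidden2", 4, 64, "integer"),
            Dimension("learning_rate", -4.0, -1.0, "log-real"),
        ]
    elif kind == "wo_ann":
        dims = [
            Dimension("hidden1", 4, 64, "integer"),
            Dimension("hidden2", 2, 16, "integer"),
        ]
        dims += [Dimension(f"mask:{t}", 0.0, 1.0, "mask-bit") for t in tokens]
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return SearchSpace(dims, n_features=n_features, feature_groups=feature_groups)


def decode_candidate(position: np.ndarray, space: SearchSpace) -> dict:
    """Decode a position into {'params', 'mask', 'weights'}.

    Out-of-box coordinates are clipped with a warning.  Mask bits use a
    strict > 0.5 threshold; integer dimensions round half away from zero.
    """
    position = np.asarray(position, dtype=float)
    lo, hi = space.lower, space.upper
    if (position < lo).any() or (position > hi).any():
        warnings.warn("position outside the search box; clipping", UserWarning,
                      stacklevel=2)
        position = np.clip(position, lo, hi)
    params: dict = {}
    mask_bits: list[tuple[list[int], bool]] = []
    weight_vals: list[tuple[list[int], float]] = []
    for value, dim in zip(position, space.dims):
        if dim.name.startswith("mask:"):
            mask_bits.append((space.column_indices(dim.name[5:]), value > 0.5))
        elif dim.name.startswith("weight:"):
            w = float(10.0**value) if dim.kind == "log-real" else float(value)
            weight_vals.append((space.column_indices(dim.name[7:]), w))
        elif dim.kind == "integer":
            params[dim.name] = int(np.floor(value + 0.5))
        elif dim.kind == "log-real":
            params[dim.name] = float(10.0**value)
        else:
            params[dim.name] = float(value)
    out = {"params": params, "mask": None, "weights": None}
    if mask_bits:
        size = space.n_features or (max(j for idx, _ in mask_bits for j in idx) + 1)
        mask = np.zeros(size, dtype=bool)
        for idx, bit in mask_bits:
            mask[idx] = bit
        out["mask"] = mask
    if weight_vals:
        size = space.n_features or (max(j for idx, _ in weight_vals for j in idx) + 1)
        w = np.zeros(size)
        for idx, v in weight_vals:
            w[idx] = v
        out["weights"] = w
    return out


@dataclass
class TuneSettings:
    """Optimiser and training budgets for tuning and for the final refit."""

    pop_size: int = 15
    iterations: int = 40
    inner_fraction: float = 0.25
    # reduced training budgets while searching; full budgets for the refit
    ann_epochs_tuning: int = 30
    ann_epochs_refit: int = 100
    wo_pop_tuning: int = 14
    wo_generations_tuning: int = 25
    wo_pop_refit: int = 24
    wo_generations_refit: int = 200


@dataclass
class TuningResult:
    classifier_kind: str
    optimizer: str
    best_config: dict
    best_fitness: float
    history: list[float]
    test_metrics: dict
    test_confusion: ConfusionMatrix
    test_auc: float
    model: object
    seed: int


def _config_key(kind: str, decoded: dict) -> str:
    mask = decoded["mask"]
    weights = decoded["weights"]
    return repr((
        kind,
        sorted(decoded["params"].items()),
        None if mask is None else mask.tolist(),
        None if weights is None else [round(w, 12) for w in weights],
    ))


def _derived_seed(root_seed: int, key: str) -> int:
    return (root_seed * 1000003 + zlib.crc32(key.encode())) % (2**31 - 1)


def _build(kind: str, decoded: dict, seed: int, settings: TuneSettings, refit: bool):
    params = dict(decoded["params"])
    if kind == "ann":
        hidden = (params.pop("hidden1", 15), params.pop("hidden2", 15))
        epochs = settings.ann_epochs_refit if refit else settings.ann_epochs_tuning
        return make_classifier(kind, hidden=hidden, epochs=epochs, seed=seed, **params)
    if kind == "wo_ann":
        hidden = (params.pop("hidden1", 50), params.pop("hidden2", 15))
        if refit:
            pop, gens = settings.wo_pop_refit, settings.wo_generations_refit
        else:
            pop, gens = settings.wo_pop_tuning, settings.wo_generations_tuning
        return make_classifier(
            kind, hidden=hidden, pop_size=pop, generations=gens, seed=seed, **params
        )
    return make_classifier(kind, **params)


def _apply_columns(X: np.ndarray, decoded: dict) -> np.ndarray | None:
    """Mask/weight the feature columns; None flags a degenerate candidate."""
    mask = decoded["mask"]
    weights = decoded["weights"]
    if mask is not None:
        if not mask.any():
            return None
        X = X[:, mask]
    if weights is not None:
        if not (weights > 0).any():
            return None
        X = X * np.sqrt(weights)[None, :]
    return X


def candidate_fitness(
    kind: str,
    decoded: dict,
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int,
    settings: TuneSettings | None = None,
) -> float:
    """1 - accuracy of the decoded configuration on an inner holdout."""
    settings = settings or TuneSettings()
    Xc = _apply_columns(X_train, decoded)
    if Xc is None:
        warnings.warn("candidate selects no features; worst fitness assigned",
                      UserWarning, stacklevel=2)
        return 1.0
    split = split_train_test(len(y_train), settings.inner_fraction, y_train, seed)
    fit_idx, val_idx = split.train_idx, split.test_idx
    key = _config_key(kind, decoded)
    clf = _build(kind, decoded, _derived_seed(seed, key), settings, refit=False)
    if kind == "knn":
        clf.k = min(clf.k, len(fit_idx))
    clf.fit(Xc[fit_idx], y_train[fit_idx])
    acc = float(np.mean(clf.predict(Xc[val_idx]) == y_train[val_idx]))
    return 1.0 - acc


def tune(
    classifier_kind: str,
    optimizer: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    space: SearchSpace | None = None,
    settings: TuneSettings | None = None,
    seed: int = 0,
) -> TuningResult:
    """Optimise a classifier configuration, refit it, and score the test split.

    The optimiser ("ba" or "mba") sees only the training split; identical
    seeds give identical results end to end.  Repeated evaluations of the
    same decoded configuration are cached.
    """
    settings = settings or TuneSettings()
    space = space or default_search_space(classifier_kind, X_train.shape[1])
    if settings.iterations < 1:
        raise ValueError("budget must allow at least one iteration")

    cache: dict[str, float] = {}

    def objective(position: np.ndarray) -> float:
        decoded = decode_candidate(position, space)
        key = _config_key(classifier_kind, decoded)
        if key not in cache:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cache[key] = candidate_fitness(
                    classifier_kind, decoded, X_train, y_train, seed, settings
                )
        return cache[key]

    kwargs = dict(
        dim=len(space.dims),
        lower=space.lower,
        upper=space.upper,
        pop_size=settings.pop_size,
        t_max=settings.iterations,
        seed=seed,
    )
    if optimizer == "mba":
        swarm, history = run_mba(objective, MBAConfig(**kwargs))
    elif optimizer == "ba":
        swarm, history = run_ba(objective, BAConfig(**kwargs))
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    decoded = decode_candidate(swarm.best_position, space)
    key = _config_key(classifier_kind, decoded)
    model = _build(classifier_kind, decoded, _derived_seed(seed, key),
                   settings, refit=True)
    Xtr = _apply_columns(X_train, decoded)
    Xte = _apply_columns(X_test, decoded)
    if Xtr is None:  # degenerate best candidate: fall back to all features
        Xtr, Xte = X_train, X_test
    if classifier_kind == "knn":
        model.k = min(model.k, len(y_train))
    model.fit(Xtr, y_train)
    y_pred = model.predict(Xte)
    cm = confusion(y_test, y_pred)
    try:
        auc_value = roc_auc(y_test, model.scores(Xte))
    except ValueError:
        auc_value = float("nan")
    return TuningResult(
        classifier_kind=classifier_kind,
        optimizer=optimizer,
        best_config=decoded,
        best_fitness=float(swarm.best_fitness),
        history=list(history.best_fitness_per_iteration),
        test_metrics=metric_report(cm),
        test_confusion=cm,
        test_auc=auc_value,
        model=model,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# k-fold evaluation


def run_crossval(
    classifier_kind: str,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    k: int = 10,
) -> pd.DataFrame:
    """Stratified k-fold metric table (one row per fold plus a mean row)."""
    from .data import fold_split, kfold_indices

    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if (counts < k).any():
        raise ValueError(f"each class needs at least {k} rows for {k}-fold")
    split = kfold_indices(len(y), k, y, seed)
    rows = []
    for fold in range(k):
        tr, te = fold_split(split, fold)
        clf = make_classifier(classifier_kind, **params)
        if classifier_kind == "knn":
            clf.k = min(clf.k, len(tr))
        clf.fit(X[tr], y[tr])
        cm = confusion(y[te], clf.predict(X[te]))
        rep = metric_report(cm)
        rows.append({
            "fold": fold + 1,
            "accuracy": rep["accuracy"],
            "precision": rep["precision"],
            "recall": rep["recall"],
            "f1": rep["f1"],
        })
    table = pd.DataFrame(rows)
    mean = table.drop(columns="fold").mean()
    mean["fold"] = "mean"
    return pd.concat([table, mean.to_frame().T], ignore_index=True)


# ---------------------------------------------------------------------------
# BA vs MBA benchmark comparison


def compare_optimizers(
    objective_names: list[str],
    dim: int = 10,
    pop_size: int = 30,
    t_max: int = 300,
    n_seeds: int = 20,
    seed0: int = 0,
) -> pd.DataFrame:
    """Paired-seed comparison of BA and MBA final best fitness.

    Returns one row per (objective, seed) with both algorithms' final best
    fitness; both runs share the seed so the comparison is paired.
    """
    from .synth import benchmark_objective

    rows = []
    for name in objective_names:
        obj = benchmark_objective(name, dim)
        for s in range(seed0, seed0 + n_seeds):
            common = dict(dim=dim, lower=obj.lower, upper=obj.upper,
                          pop_size=pop_size, t_max=t_max, seed=s)
            ba_swarm, _ = run_ba(obj, BAConfig(**common))
            mba_swarm, _ = run_mba(obj, MBAConfig(**common))
            rows.append({
                "objective": name,
                "seed": s,
                "ba_best": ba_swarm.best_fitness,
                "mba_best": mba_swarm.best_fitness,
            })
    return pd.DataFrame(rows)
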