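"""End-to-end screening experiments: preprocess, split, tune, report.

Binds the stages together in the screening workflow order — data selection,
dataset evaluation, pre-processing (label encoding + scaling fitted on the
training partition), splitting, optimiser-tuned classification, and
prediction on the untouched test split.  This is the layer the command-line
interface and the example scripts call.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    CLASS_COLUMN,
    ITEM_COLUMNS,
    SCORE_COLUMN,
    Dataset,
    encode_labels,
    load_csv,
    minmax_scale,
    split_train_test,
)
from .evaluate import evaluate_dataset
from .synth import GeneratorConfig, generate_dataset
from .tuning import TuneSettings, default_search_space, run_crossval, tune


def feature_groups(columns: list[str]) -> dict[str, list[int]]:
    """The questionnaire's natural column blocks, by position.

    ``items`` — the ten binary item scores; ``score`` — the screening
    score; ``demographics`` — everything else.  Used to build compact
    group-wise search spaces for the tuner.
    """
    groups: dict[str, list[int]] = {"items": [], "score": [], "demographics": []}
    for j, col in enumerate(columns):
        if col in ITEM_COLUMNS:
            groups["items"].append(j)
        elif col == SCORE_COLUMN:
            groups["score"].append(j)
        else:
            groups["demographics"].append(j)
    return {k: v for k, v in groups.items() if v}


@dataclass
class PreparedData:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    columns: list[str]
    groups: dict[str, list[int]]


def prepare_matrices(
    dataset: Dataset,
    test_fraction: float = 0.2,
    seed: int = 0,
    scaling: str = "minmax",
) -> PreparedData:
    """Encode, split and scale a dataset (scaler fitted on train rows only)."""
    enc = encode_labels(dataset)
    split = split_train_test(dataset.n_records, test_fraction, enc.labels, seed)
    with warnings.catch_warnings():
        # test rows may legitimately fall outside the fitted range
        warnings.simplefilter("ignore", UserWarning)
        scaled = minmax_scale(enc, split.train_idx, mode=scaling)
    X, y = scaled.features, scaled.labels
    return PreparedData(
        X_train=X[split.train_idx],
        y_train=y[split.train_idx],
        X_test=X[split.test_idx],
        y_test=y[split.test_idx],
        columns=list(scaled.columns),
        groups=feature_groups(list(scaled.columns)),
    )


def _load_or_generate(config: dict) -> Dataset:
    if "data_path" in config:
        return load_csv(config["data_path"])
    gen = config.get("generator", {})
    return generate_dataset(GeneratorConfig(**gen))


_KNOWN_KEYS = {
    "data_path", "generator", "classifier", "optimizer", "seed",
    "test_fraction", "scaling", "budget", "pop_size", "use_groups",
    "crossval_folds",
}


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown experiment config keys: {sorted(unknown)}")
    if "data_path" not in config and "generator" not in config:
        raise ValueError("config needs either data_path or generator")
    return config


def run_experiment(config: dict, out_dir: str | Path) -> dict:
    """Run one tuned-classifier experiment and write a results directory.

    Writes metrics.csv, confusion.json, history.csv, evaluation.csv,
    run.log and a provenance copy of the resolved configuration.  Returns
    the metrics as a dict.  Deterministic per (config, seed).
    """
    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        log_lines.append(f"[{stage}] {message}")

    seed = int(config.get("seed", 0))
    optimizers = config.get("optimizer", "mba")
    if isinstance(optimizers, str):
        optimizers = [optimizers]
    kind = config.get("classifier", "knn")

    dataset = _load_or_generate(config)
    log("data", f"{dataset.n_records} records, {dataset.n_attributes} attributes")

    report = evaluate_dataset(dataset)
    report.to_csv(out_dir / "evaluation.csv", index=False)
    log("evaluate", f"{int(report['significant'].sum())} of {len(report)} "
        "attributes significant at 0.05")

    prepared = prepare_matrices(
        dataset,
        test_fraction=float(config.get("test_fraction", 0.2)),
        seed=seed,
        scaling=config.get("scaling", "minmax"),
    )
    log("preprocess", f"{len(prepared.y_train)} train / {len(prepared.y_test)} test rows")

    settings = TuneSettings()
    if "budget" in config:
        settings.iterations = int(config["budget"])
    if "pop_size" in config:
        settings.pop_size = int(config["pop_size"])
    groups = prepared.groups if config.get("use_groups", True) else None
    space = default_search_space(kind, prepared.X_train.shape[1], groups)

    metric_rows, history_rows, confusions = [], [], {}
    for optimizer in optimizers:
        result = tune(
            kind, optimizer,
            prepared.X_train, prepared.y_train,
            prepared.X_test, prepared.y_test,
            space=space, settings=settings, seed=seed,
        )
        m = result.test_metrics
        metric_rows.append({
            "model": f"{optimizer}_{kind}",
            "accuracy": m["accuracy"],
            "precision": m["precision"],
            "recall": m["recall"],
            "f1": m["f1"],
            "auc": result.test_auc,
            "inner_fitness": result.best_fitness,
        })
        cm = result.test_confusion
        confusions[f"{optimizer}_{kind}"] = {
            "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
        }
        for it, best in enumerate(result.history, start=1):
            history_rows.append({
                "model": f"{optimizer}_{kind}", "iteration": it, "best_fitness": best,
            })
        log("tune", f"{optimizer}+{kind}: inner fitness {result.best_fitness:.4f}, "
            f"test accuracy {m['accuracy']:.4f}")

    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(out_dir / "metrics.csv", index=False, float_format="%.10g")
    pd.DataFrame(history_rows).to_csv(out_dir / "history.csv", index=False,
                                      float_format="%.10g")
    (out_dir / "confusion.json").write_text(json.dumps(confusions, indent=2))
    provenance = {"config": config, "seed": seed, "version": _version()}
    (out_dir / "config.json").write_text(json.dumps(provenance, indent=2, default=str))
    log("predict", "results written")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return {"metrics": metric_rows, "confusions": confusions}


def run_crossval_experiment(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Stratified k-fold table for a fixed-configuration classifier."""
    validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = _load_or_generate(config)
    prepared = prepare_matrices(
        dataset,
        test_fraction=float(config.get("test_fraction", 0.2)),
        seed=int(config.get("seed", 0)),
    )
    X = np.vstack([prepared.X_train, prepared.X_test])
    y = np.concatenate([prepared.y_train, prepared.y_test])
    table = run_crossval(
        config.get("classifier", "knn"), {}, X, y,
        seed=int(config.get("seed", 0)),
        k=int(config.get("crossval_folds", 10)),
    )
    table.to_csv(out_dir / "crossval.csv", index=False, float_format="%.10g")
    return table


def _version() -> str:
    from . import __version__

    return __version__
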