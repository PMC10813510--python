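"""Synthetic Q-CHAT-10 style data and benchmark objectives.

The generator emulates the questionnaire schema end to end: ten binary
item scores, demographics, a screening score equal to the item sum and a
binary class.  Two labelling modes:

``threshold``
    class = 1 iff the item sum reaches ``score_threshold`` (default 4,
    the established Q-CHAT-10 screening convention), optionally followed
    by symmetric label flips at rate ``label_noise``.  With zero noise the
    class is a deterministic function of the items — the same leakage
    structure the real screening data has by construction, which is what
    lets a tuned classifier reach perfect held-out accuracy.

``probabilistic``
    the class is drawn first at a configured prevalence and the items are
    drawn with class-conditional probabilities; with equal probabilities
    per class every item is independent of the label, which makes this
    mode the null model for chi-squared calibration tests.

Demographics are sampled independently of the class by default (an
optional dependence knob exists for power studies).  Standard benchmark
objectives (sphere, Rastrigin, Ackley, Rosenbrock) are provided for the
optimiser test harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CLASS_COLUMN, DEFAULT_SCHEMA, ITEM_COLUMNS, Dataset

_DEFAULT_DEMOGRAPHICS: dict[str, list[str]] = {
    "gender": ["f", "m"],
    "ethnicity": ["asian", "black", "hispanic", "latino", "middle-eastern",
                  "south-asian", "white-european", "others"],
    "respondent": ["parent", "self", "guardian", "medical-staff", "doctor"],
    "country": ["india", "jordan", "uk", "usa", "others"],
}


@dataclass
class GeneratorConfig:
    n: int = 300
    seed: int = 0
    mode: str = "threshold"  # or "probabilistic"
    score_threshold: int = 4
    item_prob: float = 0.4
    label_noise: float = 0.0
    # probabilistic mode
    prevalence: float = 0.5
    item_probs_pos: np.ndarray | list[float] | None = None
    item_probs_neg: np.ndarray | list[float] | None = None
    # demographics
    demographics: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_DEMOGRAPHICS.items()}
    )
    #: probability that gender is resampled conditional on class (power knob)
    demographic_dependence: float = 0.0
    age_range: tuple[int, int] = (1, 18)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mode not in ("threshold", "probabilistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 1 <= self.score_threshold <= 10:
            raise ValueError("score_threshold must lie in [1, 10]")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must lie in [0, 0.5]")
        for p in (self.item_prob, self.prevalence):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _age_group(age: int) -> int:
    if age <= 3:
        return 0  # toddler
    if age <= 12:
        return 1  # child
    if age <= 17:
        return 2  # adolescent
    return 3  # adult


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Draw a synthetic screening dataset; bit-identical per (config, seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n

    if config.mode == "threshold":
        items = (rng.uniform(size=(n, 10)) < config.item_prob).astype(int)
        score = items.sum(axis=1)
        labels = (score >= config.score_threshold).astype(int)
        if config.label_noise > 0:
            flips = rng.uniform(size=n) < config.label_noise
            labels = np.where(flips, 1 - labels, labels)
    else:
        labels = (rng.uniform(size=n) < config.prevalence).astype(int)
        p_pos = np.asarray(
            config.item_probs_pos
            if config.item_probs_pos is not None
            else np.full(10, config.item_prob)
        )
        p_neg = np.asarray(
            config.item_probs_neg
            if config.item_probs_neg is not None
            else np.full(10, config.item_prob)
        )
        if not ((0 <= p_pos).all() and (p_pos <= 1).all()
                and (0 <= p_neg).all() and (p_neg <= 1).all()):
            raise ValueError("item probabilities must lie in [0, 1]")
        probs = np.where(labels[:, None] == 1, p_pos[None, :], p_neg[None, :])
        items = (rng.uniform(size=(n, 10)) < probs).astype(int)
        score = items.sum(axis=1)

    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    frame = pd.DataFrame(items, columns=ITEM_COLUMNS)
    frame["age"] = age
    for col, cats in config.demographics.items():
        frame[col] = rng.choice(cats, size=n)
    if config.demographic_dependence > 0:
        # resample gender toward the class label to induce dependence
        forced = rng.uniform(size=n) < config.demographic_dependence
        cats = config.demographics["gender"]
        frame.loc[forced, "gender"] = [cats[l % len(cats)] for l in labels[forced]]
    frame["jaundice"] = rng.integers(0, 2, size=n)
    frame["family_pdd"] = rng.integers(0, 2, size=n)
    frame["used_app_before"] = rng.integers(0, 2, size=n)
    frame["age_group"] = [_age_group(a) for a in age]
    frame["score"] = score
    frame[CLASS_COLUMN] = labels
    frame = frame[list(DEFAULT_SCHEMA)]
    return Dataset(frame=frame, schema=dict(DEFAULT_SCHEMA))


# ---------------------------------------------------------------------------
# benchmark objectives for the optimisers


@dataclass
class BenchmarkObjective:
    name: str
    dim: int
    func: callable
    lower: float
    upper: float
    optimum_position: np.ndarray
    optimum_value: float

    def __call__(self, x) -> float:
        return self.func(np.asarray(x, dtype=float))


def _sphere(x):
    return float(np.sum(x**2))


def _rastrigin(x):
    return float(10.0 * len(x) + np.sum(x**2 - 10.0 * np.cos(2.0 * math.pi * x)))


def _ackley(x):
    d = len(x)
    return float(
        -20.0 * math.exp(-0.2 * math.sqrt(np.sum(x**2) / d))
        - math.exp(np.sum(np.cos(2.0 * math.pi * x)) / d)
        + 20.0
        + math.e
    )


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


_BENCHMARKS = {
    "sphere": (_sphere, -5.12, 5.12, 0.0),
    "rastrigin": (_rastrigin, -5.12, 5.12, 0.0),
    "ackley": (_ackley, -32.768, 32.768, 0.0),
    "rosenbrock": (_rosenbrock, -5.0, 10.0, 1.0),
}


def benchmark_objective(name: str, dim: int) -> BenchmarkObjective:
    """Standard test function by name with its box and known optimum."""
    try:
        func, lo, hi, opt_coord = _BENCHMARKS[name]
    except KeyError:
        raise ValueError(
            f"unknown objective {name!r}; supported: {sorted(_BENCHMARKS)}"
        ) from None
    pos = np.full(dim, opt_coord)
    return BenchmarkObjective(
        name=name,
        dim=dim,
        func=func,
        lower=lo,
        upper=hi,
        optimum_position=pos,
        optimum_value=func(pos),
    )
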