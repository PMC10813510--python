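"""Classic bat algorithm (BA).

A swarm of candidate solutions ("bats") flies through a box-bounded search
space.  Each iteration a bat draws an emission frequency

    freq = freq_min + (freq_max - freq_min) * beta,    beta ~ U[0, 1]

adds the frequency-scaled attraction toward the global best to its
velocity, and steps to a new position.  With probability (1 - r_k) it
instead exploits around the best-so-far position, perturbed by the swarm's
average loudness.  An improving candidate is accepted with probability
proportional to the bat's loudness; on acceptance the loudness decays
geometrically (factor alpha) and the pulse rate rises toward its ceiling
r0 as r0 * (1 - exp(-gamma * t)).

Defaults follow the screening study's stated configuration: freq range
[0, 2], alpha = gamma = 0.9, initial loudness 2, pulse-rate ceiling 1.
Minimisation convention throughout; negate an objective to maximise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class BAConfig:
    """Bat algorithm parameters.

    The source study also quotes "parameter of K is 5" without attaching it
    to any update rule; it plays no role here.
    """

    dim: int
    lower: np.ndarray | float = 0.0
    upper: np.ndarray | float = 1.0
    pop_size: int = 30
    freq_min: float = 0.0
    freq_max: float = 2.0
    alpha: float = 0.9
    gamma: float = 0.9
    lud0: float = 2.0
    r0: float = 1.0
    t_max: int = 100
    seed: int = 0

    def __post_init__(self):
        self.lower = np.broadcast_to(np.asarray(self.lower, float), (self.dim,)).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, float), (self.dim,)).copy()
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.freq_min > self.freq_max:
            raise ValueError("freq_min must not exceed freq_max")
        if not np.all(self.lower < self.upper):
            raise ValueError("bounds must satisfy lower < upper elementwise")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


@dataclass
class BatPopulation:
    positions: np.ndarray
    velocities: np.ndarray
    loudness: np.ndarray
    pulse_rates: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    iteration: int = 0


@dataclass
class RunHistory:
    best_fitness_per_iteration: list[float] = field(default_factory=list)
    evaluations: int = 0


# -- elementary update rules -------------------------------------------------


def draw_frequency(config: BAConfig, beta: float) -> float:
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    return config.freq_min + (config.freq_max - config.freq_min) * beta


def ba_velocity(sp_prev, pos_prev, pos_best, freq: float) -> np.ndarray:
    sp_prev, pos_prev, pos_best = map(np.asarray, (sp_prev, pos_prev, pos_best))
    if not sp_prev.shape == pos_prev.shape == pos_best.shape:
        raise ValueError("velocity/position vectors must share one dimension")
    return sp_prev + (pos_prev - pos_best) * freq


def advance_position(pos_prev, sp_new, lower, upper) -> np.ndarray:
    return np.clip(np.asarray(pos_prev) + np.asarray(sp_new), lower, upper)


def local_search(pos_best, avg_loudness: float, epsilon, lower, upper) -> np.ndarray:
    if avg_loudness < 0:
        raise ValueError("loudness cannot be negative")
    return np.clip(np.asarray(pos_best) + np.asarray(epsilon) * avg_loudness, lower, upper)


def decay_loudness(lud: float, alpha: float) -> float:
    if lud < 0:
        raise ValueError("loudness cannot be negative")
    return alpha * lud


def raise_pulse_rate(r0: float, gamma: float, t: int) -> float:
    if t < 0:
        raise ValueError("t must be nonnegative")
    return r0 * (1.0 - math.exp(-gamma * t))


# -- main loop ---------------------------------------------------------------


def _evaluate(objective, x: np.ndarray) -> float:
    f = float(objective(x))
    if not math.isfinite(f):
        raise ValueError(f"objective returned a non-finite value at {x}")
    return f


def init_population(objective, config: BAConfig, rng: np.random.Generator) -> BatPopulation:
    pos = rng.uniform(config.lower, config.upper, size=(config.pop_size, config.dim))
    fit = np.array([_evaluate(objective, p) for p in pos])
    best = int(np.argmin(fit))
    return BatPopulation(
        positions=pos,
        velocities=np.zeros_like(pos),
        loudness=np.full(config.pop_size, config.lud0, float),
        pulse_rates=np.zeros(config.pop_size),
        fitness=fit,
        best_position=pos[best].copy(),
        best_fitness=float(fit[best]),
    )


def run_ba(objective, config: BAConfig) -> tuple[BatPopulation, RunHistory]:
    """Minimise ``objective`` over the configured box. Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    swarm = init_population(objective, config, rng)
    history = RunHistory(evaluations=config.pop_size)
    accept_count = np.zeros(config.pop_size, dtype=int)

    for t in range(1, config.t_max + 1):
        avg_lud = float(swarm.loudness.mean())
        for k in range(config.pop_size):
            freq = draw_frequency(config, rng.uniform())
            swarm.velocities[k] = ba_velocity(
                swarm.velocities[k], swarm.positions[k], swarm.best_position, freq
            )
            cand = advance_position(
                swarm.positions[k], swarm.velocities[k], config.lower, config.upper
            )
            if rng.uniform() > swarm.pulse_rates[k]:
                eps = rng.uniform(-1.0, 1.0, config.dim)
                cand = local_search(
                    swarm.best_position, avg_lud, eps, config.lower, config.upper
                )
            f = _evaluate(objective, cand)
            history.evaluations += 1
            if f <= swarm.fitness[k] and rng.uniform() < swarm.loudness[k]:
                swarm.positions[k] = cand
                swarm.fitness[k] = f
                accept_count[k] += 1
                swarm.loudness[k] = decay_loudness(swarm.loudness[k], config.alpha)
                swarm.pulse_rates[k] = raise_pulse_rate(
                    config.r0, config.gamma, accept_count[k]
                )
            if f < swarm.best_fitness:
                swarm.best_fitness = f
                swarm.best_position = cand.copy()
        swarm.iteration = t
        history.best_fitness_per_iteration.append(swarm.best_fitness)
    return swarm, history


def run_summary(config: BAConfig, swarm: BatPopulation, history: RunHistory) -> dict:
    """JSON-serialisable record of a finished optimisation run."""
    return {
        "algorithm": "ba",
        "seed": config.seed,
        "dim": config.dim,
        "pop_size": config.pop_size,
        "t_max": config.t_max,
        "best_fitness": swarm.best_fitness,
        "best_position": [float(v) for v in swarm.best_position],
        "evaluations": history.evaluations,
        "history": [float(v) for v in history.best_fitness_per_iteration],
    }
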