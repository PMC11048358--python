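"""Particle swarm search over per-dimension profile weights.

Each particle's position is a weight vector w in [0,1]^D; the weighted
profile (column-wise product) feeds a logistic-regression meta-classifier
and the particle's fitness is that classifier's stratified k-fold
cross-validated accuracy.  The canonical update is used::

    v <- w_inertia * v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x <- x + v

with r1, r2 fresh uniforms per particle-dimension, velocities clamped to
±vmax (0.2 of the unit range, to stop bound-bouncing) and positions clipped
to the [0,1] box (absorbing walls).  Defaults mirror the published search:
60 particles, 100 iterations, inertia 0.8, c1 = c2 = 0.6, 10-fold fitness.

The CV partition inside the fitness is drawn once per search, so fitness is
a deterministic function of w and the gbest history is genuinely
non-decreasing rather than drifting with resampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .stacking import ProfileColumn, RnaProfile


@dataclass(frozen=True)
class PsoConfig:
    """Swarm settings; the defaults are the full-size published search."""

    n_particles: int = 60
    n_iterations: int = 100
    inertia: float = 0.8
    c1: float = 0.6
    c2: float = 0.6
    vmax: float = 0.2
    seed: int = 0
    fitness_folds: int = 10

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("need at least one particle and one iteration")
        if self.fitness_folds < 2:
            raise ValueError("fitness_folds must be >= 2")


#: Reduced search for continuous-integration-scale runs.
FAST_PSO = PsoConfig(n_particles=10, n_iterations=20, fitness_folds=5)


@dataclass
class PsoState:
    x: np.ndarray  # n_particles x D positions
    v: np.ndarray  # velocities
    pbest_x: np.ndarray
    pbest_f: np.ndarray
    gbest_x: np.ndarray
    gbest_f: float
    t: int
    rng: np.random.Generator


@dataclass
class WeightVector:
    """The searched per-dimension weights plus their fitness."""

    w: np.ndarray
    fitness: float
    columns: list[ProfileColumn] = field(default_factory=list)


FitnessFn = Callable[[np.ndarray], float]


def init_swarm(config: PsoConfig, dim: int, fitness_fn: FitnessFn) -> PsoState:
    """Uniform positions in [0,1]^D, velocities in ±vmax; evaluates everyone."""
    if dim < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(config.seed)
    x = rng.uniform(0.0, 1.0, size=(config.n_particles, dim))
    v = rng.uniform(-config.vmax, config.vmax, size=(config.n_particles, dim))
    f = np.array([fitness_fn(xi) for xi in x])
    best = int(np.argmax(f))
    return PsoState(
        x=x, v=v, pbest_x=x.copy(), pbest_f=f.copy(),
        gbest_x=x[best].copy(), gbest_f=float(f[best]), t=0, rng=rng,
    )


def step(state: PsoState, fitness_fn: FitnessFn, config: PsoConfig) -> PsoState:
    """One synchronous swarm update; mutates and returns ``state``."""
    n, dim = state.x.shape
    r1 = state.rng.uniform(size=(n, dim))
    r2 = state.rng.uniform(size=(n, dim))
    state.v = (
        config.inertia * state.v
        + config.c1 * r1 * (state.pbest_x - state.x)
        + config.c2 * r2 * (state.gbest_x - state.x)
    )
    np.clip(state.v, -config.vmax, config.vmax, out=state.v)
    state.x = np.clip(state.x + state.v, 0.0, 1.0)
    for i in range(n):
        try:
            f = fitness_fn(state.x[i])
        except Exception as exc:  # surface which particle broke the fitness
            raise RuntimeError(f"fitness evaluation failed for particle {i}") from exc
        if f > state.pbest_f[i]:
            state.pbest_f[i] = f
            state.pbest_x[i] = state.x[i].copy()
            if f > state.gbest_f:
                state.gbest_f = float(f)
                state.gbest_x = state.x[i].copy()
    state.t += 1
    return state


def cv_accuracy_fitness(
    profile_values: np.ndarray,
    labels,
    n_folds: int = 10,
    seed: int = 0,
    meta_params: dict | None = None,
) -> FitnessFn:
    """Fitness factory: pooled stratified CV accuracy of LR on (profile ⊙ w).

    The fold partition is fixed here, once, so every particle at every
    iteration is scored on the same surface.
    """
    X = np.asarray(profile_values, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("fitness needs both classes present")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    params = meta_params or {}

    def fitness(w: np.ndarray) -> float:
        Xw = X * w
        correct = 0
        for train_idx, test_idx in splits:
            clf = LogisticRegression(**params)
            clf.fit(Xw[train_idx], y[train_idx])
            correct += int((clf.predict(Xw[test_idx]) == y[test_idx]).sum())
        return correct / len(y)

    return fitness


def optimize_weights(
    profile: RnaProfile, labels, config: PsoConfig, meta_params: dict | None = None
) -> tuple[WeightVector, list[float]]:
    """Run the swarm; return the global best and its per-iteration history.

    The history has one entry per iteration (gbest fitness after that
    update) and is non-decreasing by construction.
    """
    fitness_fn = cv_accuracy_fitness(
        profile.values, labels, n_folds=config.fitness_folds,
        seed=config.seed, meta_params=meta_params,
    )
    state = init_swarm(config, profile.n_dims, fitness_fn)
    history: list[float] = []
    for _ in range(config.n_iterations):
        state = step(state, fitness_fn, config)
        history.append(state.gbest_f)
    wv = WeightVector(w=state.gbest_x.copy(), fitness=state.gbest_f, columns=list(profile.columns))
    return wv, history


def write_history(history: list[float], path: str) -> None:
    """Fitness-curve log: two-column TSV (iteration, gbest_accuracy)."""
    with open(path, "w") as fh:
        fh.write("iteration\tgbest_accuracy\n")
        for i, f in enumerate(history, start=1):
            fh.write(f"{i}\t{f:.6f}\n")
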