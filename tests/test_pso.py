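"""Particle swarm mechanics: update rule, bounds, monotone gbest, determinism."""

import numpy as np
import pytest

from pseusite import FAST_PSO, PsoConfig, optimize_weights
from pseusite.pso import cv_accuracy_fitness, init_swarm, step, write_history
from pseusite.stacking import ProfileColumn, RnaProfile
from pseusite import EncodingSpec


def _sphere(w):
    return -float(np.sum((w - 0.7) ** 2))


def test_init_swarm_shapes_bounds_and_gbest():
    cfg = PsoConfig(n_particles=60, n_iterations=100, seed=1)
    state = init_swarm(cfg, 30, _sphere)
    assert state.x.shape == state.v.shape == (60, 30)
    assert ((state.x >= 0) & (state.x <= 1)).all()
    assert (np.abs(state.v) <= cfg.vmax).all()
    fits = [_sphere(xi) for xi in state.x]
    assert state.gbest_f == pytest.approx(max(fits))
    assert np.array_equal(state.pbest_x, state.x)


def test_init_swarm_deterministic():
    cfg = PsoConfig(n_particles=8, seed=42)
    a, b = init_swarm(cfg, 5, _sphere), init_swarm(cfg, 5, _sphere)
    assert np.array_equal(a.x, b.x) and np.array_equal(a.v, b.v)


def test_hand_computed_position_update():
    """One particle, c1=c2=0, w=1, v=0.1, x=0.5: x moves to exactly 0.6."""
    cfg = PsoConfig(n_particles=1, n_iterations=1, inertia=1.0, c1=0.0, c2=0.0, seed=0)
    state = init_swarm(cfg, 1, _sphere)
    state.x[:] = 0.5
    state.v[:] = 0.1
    state.pbest_x[:] = 0.5
    state.gbest_x[:] = 0.5
    state = step(state, _sphere, cfg)
    assert state.x[0, 0] == pytest.approx(0.6)
    assert state.t == 1


def test_fixed_point_when_converged():
    cfg = PsoConfig(n_particles=3, seed=0)
    state = init_swarm(cfg, 4, _sphere)
    state.x[:] = 0.7
    state.v[:] = 0.0
    state.pbest_x[:] = 0.7
    state.gbest_x[:] = 0.7
    state.pbest_f[:] = _sphere(state.x[0])
    state.gbest_f = _sphere(state.x[0])
    before = state.x.copy()
    state = step(state, _sphere, cfg)
    assert np.array_equal(state.x, before)  # zero velocity, no attraction


def test_velocity_decays_geometrically_without_attraction():
    cfg = PsoConfig(n_particles=1, inertia=0.5, c1=0.0, c2=0.0, vmax=1.0, seed=0)
    state = init_swarm(cfg, 1, _sphere)
    state.x[:] = 0.5
    state.v[:] = 0.08
    state.pbest_x[:] = state.x
    state.gbest_x[:] = state.x
    for i in range(1, 5):
        state = step(state, _sphere, cfg)
        assert state.v[0, 0] == pytest.approx(0.08 * 0.5**i)


def test_gbest_monotone_and_positions_bounded():
    cfg = PsoConfig(n_particles=12, n_iterations=30, seed=5)
    state = init_swarm(cfg, 6, _sphere)
    prev = state.gbest_f
    for _ in range(30):
        state = step(state, _sphere, cfg)
        assert state.gbest_f >= prev
        assert ((state.x >= 0) & (state.x <= 1)).all()
        assert (np.abs(state.v) <= cfg.vmax + 1e-12).all()
        prev = state.gbest_f


def _toy_profile(n=120, n_noise=4, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    informative = np.clip(y * 0.8 + 0.1 + rng.normal(scale=0.05, size=n), 0, 1)
    cols = [informative] + [rng.uniform(size=n) for _ in range(n_noise)]
    families = ("ADA", "GBDT", "XGB", "RF", "ET")
    meta = [
        ProfileColumn(EncodingSpec("kmer", 1 + (i // 5) % 3), families[i % 5])
        for i in range(n_noise + 1)
    ]
    return RnaProfile(np.column_stack(cols), meta, "out_of_fold"), y


def test_unit_weights_reproduce_unweighted_fitness():
    profile, y = _toy_profile()
    fn = cv_accuracy_fitness(profile.values, y, n_folds=5, seed=0)
    assert fn(np.ones(profile.n_dims)) == pytest.approx(fn(np.ones(profile.n_dims)))
    # weighting by ones is the identity on the profile
    assert np.array_equal(profile.values * np.ones(profile.n_dims), profile.values)


def test_optimize_weights_recovers_informative_column():
    profile, y = _toy_profile(n=300, n_noise=29, seed=1)
    cfg = PsoConfig(n_particles=10, n_iterations=15, fitness_folds=5, seed=2)
    wv, history = optimize_weights(profile, y, cfg)
    assert len(history) == 15
    assert all(b >= a for a, b in zip(history, history[1:]))
    assert wv.fitness >= 0.95
    assert ((wv.w >= 0) & (wv.w <= 1)).all()
    # the informative column's weight ranks in the top quartile
    assert np.argsort(-wv.w).tolist().index(0) < len(wv.w) // 4


def test_optimize_weights_deterministic():
    profile, y = _toy_profile(n=80, n_noise=3)
    cfg = PsoConfig(n_particles=6, n_iterations=5, fitness_folds=4, seed=9)
    (w1, h1), (w2, h2) = (optimize_weights(profile, y, cfg) for _ in range(2))
    assert np.array_equal(w1.w, w2.w) and h1 == h2


def test_degenerate_labels_rejected():
    profile, y = _toy_profile(n=40, n_noise=2)
    with pytest.raises(ValueError, match="both classes"):
        optimize_weights(profile, np.ones_like(y), FAST_PSO)


def test_history_tsv(tmp_path):
    path = tmp_path / "history.tsv"
    write_history([0.5, 0.6, 0.6], str(path))
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "iteration\tgbest_accuracy"
    assert lines[1].startswith("1\t0.5")
    assert len(lines) == 4
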