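"""Shared fixtures: tiny synthetic datasets and reduced-size model specs.

Everything is generated programmatically and seeded; base-learner sizes are
kept tiny so unit tests run in seconds while exercising the same code paths
as the full architecture.
"""

import pytest

from pseusite import BaseModelSpec, default_specs, generate, registry

#: Tiny ensembles for unit tests (structure identical to the real families).
TINY_PARAMS = {
    "ADA": {"n_estimators": 10},
    "GBDT": {"n_estimators": 10, "max_depth": 2},
    "XGB": {"n_estimators": 10, "max_bin": 32},
    "RF": {"n_estimators": 10},
    "ET": {"n_estimators": 10},
}


def tiny_registry(seed: int = 0) -> list[BaseModelSpec]:
    return registry(seed=seed, params=TINY_PARAMS)


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly enriched human-like windows: near-centre A/U vs C/G contrast."""
    return generate(default_specs(n_pos=60, n_neg=60, seed=7)["human-like"])


@pytest.fixture(scope="session")
def small_dataset():
    """40 windows for fold-level oracles (4 folds of 10)."""
    return generate(default_specs(n_pos=20, n_neg=20, seed=5)["human-like"])


def pytest_configure(config):
    # derandomised hypothesis runs: property tests are reproducible in CI
    from hypothesis import settings

    settings.register_profile("deterministic", derandomize=True, deadline=None)
    settings.load_profile("deterministic")
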