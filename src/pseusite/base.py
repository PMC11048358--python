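"""Registry of the five tree-ensemble base learner families.

The stacking layer draws on adaptive boosting (ADA), gradient-boosted
decision trees (GBDT), extreme gradient boosting (XGB), random forest (RF)
and extra trees (ET) — each applied to each of the six encodings, for 30
base classifiers in the default architecture.  Every family exposes
nonnegative per-feature importances (consumed by the threshold-sweep
selection) and positive-class probabilities (the RNA-profile entries).

Hyperparameters are the libraries' widely used defaults (100 estimators);
no tuning is attempted, and every knob is overridable through the config so
a fitted bundle records exactly what was run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from xgboost import XGBClassifier

FAMILIES = ("ADA", "GBDT", "XGB", "RF", "ET")

#: Library defaults, pinned here so a config snapshot is self-describing.
DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "ADA": {"n_estimators": 100},
    "GBDT": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
    "XGB": {"n_estimators": 100, "tree_method": "hist", "eval_metric": "logloss"},
    "RF": {"n_estimators": 100},
    "ET": {"n_estimators": 100},
}


@dataclass(frozen=True)
class BaseModelSpec:
    """An unfitted base learner: family, hyperparameters, seed."""

    family: str
    params: tuple[tuple[str, Any], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")

    @classmethod
    def create(cls, family: str, params: Mapping[str, Any] | None = None, seed: int = 0):
        merged = dict(DEFAULT_PARAMS.get(family, {}))
        merged.update(params or {})
        return cls(family, tuple(sorted(merged.items())), seed)

    @property
    def param_dict(self) -> dict[str, Any]:
        return dict(self.params)

    def build(self):
        """Instantiate the underlying estimator (single-threaded, seeded)."""
        p = self.param_dict
        if self.family == "ADA":
            return AdaBoostClassifier(random_state=self.seed, **p)
        if self.family == "GBDT":
            return GradientBoostingClassifier(random_state=self.seed, **p)
        if self.family == "XGB":
            return XGBClassifier(random_state=self.seed, n_jobs=1, verbosity=0, **p)
        if self.family == "RF":
            return RandomForestClassifier(random_state=self.seed, n_jobs=1, **p)
        return ExtraTreesClassifier(random_state=self.seed, n_jobs=1, **p)


def registry(
    seed: int = 0, params: Mapping[str, Mapping[str, Any]] | None = None
) -> list[BaseModelSpec]:
    """The five family specs in fixed [ADA, GBDT, XGB, RF, ET] order.

    ``params`` holds optional per-family overrides merged onto the defaults.
    Deterministic: two calls with the same arguments give identical specs.
    """
    params = params or {}
    return [BaseModelSpec.create(f, params.get(f), seed=seed) for f in FAMILIES]


def _values(X) -> np.ndarray:
    return X.values if hasattr(X, "values") else np.asarray(X, dtype=np.float64)


@dataclass
class FittedBaseModel:
    """A fitted base learner plus the bookkeeping stacking needs."""

    spec: BaseModelSpec
    estimator: Any
    n_features: int

    @property
    def importances(self) -> np.ndarray:
        imp = np.asarray(self.estimator.feature_importances_, dtype=np.float64)
        return np.clip(imp, 0.0, None)

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability per row, in [0, 1]."""
        arr = _values(X)
        if arr.shape[1] != self.n_features:
            raise ValueError(
                f"feature count mismatch: model trained on {self.n_features}, got {arr.shape[1]}"
            )
        proba = self.estimator.predict_proba(arr)
        pos = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return np.clip(proba[:, pos], 0.0, 1.0)


def fit(spec: BaseModelSpec, X, y) -> FittedBaseModel:
    """Fit one base learner.  Requires both classes present; seeded, reproducible."""
    arr = _values(X)
    y = np.asarray(y, dtype=int)
    if arr.shape[0] != y.shape[0]:
        raise ValueError(f"X has {arr.shape[0]} rows but y has {y.shape[0]} labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training labels contain a single class {classes.tolist()}")
    est = spec.build()
    est.fit(arr, y)
    return FittedBaseModel(spec=spec, estimator=est, n_features=arr.shape[1])
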