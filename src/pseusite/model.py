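"""End-to-end assembly: train, predict, save and load the ensemble.

Training runs encoders → per-pair threshold-sweep feature selection →
out-of-fold stacking → (optionally) the particle swarm over profile weights
→ a logistic meta-classifier on the weighted profile.  Masks are selected
once on the full training data before stacking; the meta-classifier inside
the PSO fitness and the final meta-classifier share identical settings, so
the searched weights are optimal for the surface that is actually deployed.

A fitted bundle keeps the fold models (scoring new sequences averages the
k fold predictions per column), the masks, the weight vector and the meta
state, plus a config snapshot — enough to reproduce or audit the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import __version__
from .config import PipelineConfig, derive_seed
from .encoders import encode
from .io import SequenceDataset
from .pso import optimize_weights
from .selection import FeatureMask, threshold_sweep
from .stacking import FoldModels, ProfileColumn, RnaProfile, out_of_fold_profile, test_profile


@dataclass
class PipelineStages:
    """Intermediate artifacts shared by the stack / PSO finalisation modes."""

    config: PipelineConfig
    masks: dict[str, FeatureMask]
    profile: RnaProfile
    fold_models: FoldModels
    y: np.ndarray


@dataclass
class EnsembleModel:
    """Frozen predictor: fold models + masks + weights + meta-classifier."""

    config: PipelineConfig
    fold_models: FoldModels
    weights: np.ndarray
    weight_fitness: float | None
    meta: LogisticRegression
    fitness_history: list[float] = field(default_factory=list)

    @property
    def window_length(self) -> int:
        return self.fold_models.window_length

    @property
    def columns(self) -> list[ProfileColumn]:
        return self.fold_models.columns()


def fit_stages(train: SequenceDataset, config: PipelineConfig) -> PipelineStages:
    """Feature selection + out-of-fold stacking on the training data."""
    if not train.labeled:
        raise ValueError("training requires a labeled dataset")
    y = train.y
    if np.unique(y).size < 2:
        raise ValueError("training requires both classes present")
    specs = config.base_specs()
    masks: dict[str, FeatureMask] = {}
    try:
        for enc in config.encodings:
            X = encode(train, enc)
            for spec in specs:
                name = ProfileColumn(enc, spec.family).name
                masks[name] = threshold_sweep(
                    spec, X, y,
                    n_folds=config.sweep_folds,
                    seed=derive_seed(config.seed, f"sweep:{name}"),
                    max_thresholds=config.sweep_max_thresholds,
                )
    except Exception as exc:
        raise RuntimeError(f"feature-selection stage failed: {exc}") from exc
    try:
        profile, fold_models = out_of_fold_profile(
            train, config.encodings, specs, masks,
            n_folds=config.stacking_folds,
            seed=derive_seed(config.seed, "stacking"),
        )
    except Exception as exc:
        raise RuntimeError(f"stacking stage failed: {exc}") from exc
    return PipelineStages(config=config, masks=masks, profile=profile,
                          fold_models=fold_models, y=y)


def finalize(
    stages: PipelineStages,
    config: PipelineConfig,
    use_pso: bool | None = None,
    weights: np.ndarray | None = None,
) -> EnsembleModel:
    """Fit weights (swarm, unit, or caller-supplied) and the meta-classifier.

    Passing ``weights`` skips the swarm and fits the meta-classifier on the
    profile scaled by those fixed weights.
    """
    if use_pso is None:
        use_pso = config.use_pso
    dim = stages.profile.n_dims
    if weights is not None:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (dim,):
            raise ValueError(f"weights must have shape ({dim},)")
        fitness, history = None, []
    elif use_pso:
        try:
            wv, history = optimize_weights(
                stages.profile, stages.y, config.pso, meta_params=config.meta_params
            )
        except Exception as exc:
            raise RuntimeError(f"weight-optimisation stage failed: {exc}") from exc
        weights, fitness = wv.w, wv.fitness
    else:
        weights, fitness, history = np.ones(dim), None, []
    meta = LogisticRegression(random_state=derive_seed(config.seed, "meta"), **config.meta_params)
    meta.fit(stages.profile.values * weights, stages.y)
    return EnsembleModel(
        config=config, fold_models=stages.fold_models, weights=weights,
        weight_fitness=fitness, meta=meta, fitness_history=history,
    )


def fit_predictor(train: SequenceDataset, config: PipelineConfig) -> EnsembleModel:
    """The full training pipeline; reproducible from config + seed."""
    return finalize(fit_stages(train, config), config)


def predict(model: EnsembleModel, sequences: SequenceDataset) -> pd.DataFrame:
    """Score sequences: columns id, probability, label (threshold 0.5)."""
    if len(sequences) == 0:
        return pd.DataFrame(columns=["id", "probability", "label"])
    if sequences.window_length != model.window_length:
        raise ValueError(
            f"window length mismatch: model expects {model.window_length} nt, "
            f"got {sequences.window_length} nt (ids {sequences.ids[:5]} ...)"
        )
    profile = test_profile(sequences, model.fold_models)
    proba = model.meta.predict_proba(profile.values * model.weights)
    pos = int(np.flatnonzero(model.meta.classes_ == 1)[0])
    p = np.clip(proba[:, pos], 0.0, 1.0)
    return pd.DataFrame(
        {"id": sequences.ids, "probability": p, "label": (p >= 0.5).astype(int)}
    )


# -- persistence ------------------------------------------------------------

_MANIFEST = "manifest.json"
_ARTIFACTS = "artifacts.joblib"


def save(model: EnsembleModel, path: str | Path) -> None:
    """Persist a bundle directory: JSON manifest + joblib artifacts."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "pseusite-bundle/1",
        "package_version": __version__,
        "window_length": model.window_length,
        "columns": [c.name for c in model.columns],
        "weights": model.weights.tolist(),
        "weight_fitness": model.weight_fitness,
        "fitness_history": model.fitness_history,
        "config": model.config.to_dict(),
    }
    (path / _MANIFEST).write_text(json.dumps(manifest, indent=2))
    joblib.dump(
        {"fold_models": model.fold_models, "meta": model.meta, "weights": model.weights},
        path / _ARTIFACTS,
    )


def load(path: str | Path) -> EnsembleModel:
    path = Path(path)
    manifest = json.loads((path / _MANIFEST).read_text())
    if manifest.get("format") != "pseusite-bundle/1":
        raise ValueError(f"{path}: not a pseusite model bundle")
    art = joblib.load(path / _ARTIFACTS)
    return EnsembleModel(
        config=PipelineConfig.from_dict(manifest["config"]),
        fold_models=art["fold_models"],
        weights=np.asarray(art["weights"], dtype=np.float64),
        weight_fitness=manifest.get("weight_fitness"),
        meta=art["meta"],
        fitness_history=list(manifest.get("fitness_history", [])),
    )
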