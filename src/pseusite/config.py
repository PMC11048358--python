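"""Pipeline configuration: every knob of the architecture in one snapshot.

The default configuration reproduces the published architecture — six
encodings × five tree-ensemble families (a 30-dim profile), 10-fold
stacking, a 60-particle × 100-iteration swarm with 10-fold fitness, and a
plain logistic meta-classifier.  ``PipelineConfig.fast()`` is the reduced
continuous-integration profile (smaller ensembles, 10 × 20 swarm, 5-fold
fitness) for desk-scale runs; it changes sizes only, never the structure.

All stage seeds are derived deterministically from the single top-level
seed, so a config plus its seed reproduces a training run bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Any

from .base import FAMILIES, BaseModelSpec, registry
from .encoders import EncodingSpec, default_encodings
from .pso import FAST_PSO, PsoConfig

#: Reduced base-learner sizes for the fast profile.
FAST_BASE_PARAMS: dict[str, dict[str, Any]] = {
    "ADA": {"n_estimators": 20},
    "GBDT": {"n_estimators": 20, "max_depth": 2, "max_features": "sqrt"},
    "XGB": {"n_estimators": 30, "max_bin": 64},
    "RF": {"n_estimators": 30},
    "ET": {"n_estimators": 30},
}


def derive_seed(seed: int, tag: str) -> int:
    """Stable per-stage sub-seed in [0, 2^31) from the top-level seed."""
    return (seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


@dataclass
class PipelineConfig:
    encodings: list[EncodingSpec] = field(default_factory=default_encodings)
    families: tuple[str, ...] = FAMILIES
    base_params: dict[str, dict[str, Any]] = field(default_factory=dict)
    sweep_folds: int = 5
    sweep_max_thresholds: int = 200
    stacking_folds: int = 10
    pso: PsoConfig = field(default_factory=PsoConfig)
    use_pso: bool = True
    meta_params: dict[str, Any] = field(default_factory=lambda: {"max_iter": 1000})
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "PipelineConfig":
        return cls(seed=seed).reseed(seed)

    @classmethod
    def fast(cls, seed: int = 0) -> "PipelineConfig":
        """CI-scale profile: same 30-column architecture, smaller ensembles."""
        cfg = cls(
            base_params={k: dict(v) for k, v in FAST_BASE_PARAMS.items()},
            sweep_folds=3,
            sweep_max_thresholds=6,
            stacking_folds=5,
            pso=FAST_PSO,
            seed=seed,
        )
        return cfg.reseed(seed)

    def reseed(self, seed: int) -> "PipelineConfig":
        """Set the top-level seed and rederive the swarm's sub-seed."""
        self.seed = seed
        self.pso = replace(self.pso, seed=derive_seed(seed, "pso"))
        return self

    def base_specs(self, seed_tag: str = "base") -> list[BaseModelSpec]:
        specs = registry(seed=derive_seed(self.seed, seed_tag), params=self.base_params)
        return [s for s in specs if s.family in self.families]

    @property
    def n_profile_dims(self) -> int:
        return len(self.encodings) * len(self.families)

    # -- (de)serialisation for manifests and YAML configs -------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "encodings": [e.name for e in self.encodings],
            "families": list(self.families),
            "base_params": self.base_params,
            "sweep_folds": self.sweep_folds,
            "sweep_max_thresholds": self.sweep_max_thresholds,
            "stacking_folds": self.stacking_folds,
            "pso": {
                "n_particles": self.pso.n_particles,
                "n_iterations": self.pso.n_iterations,
                "inertia": self.pso.inertia,
                "c1": self.pso.c1,
                "c2": self.pso.c2,
                "vmax": self.pso.vmax,
                "seed": self.pso.seed,
                "fitness_folds": self.pso.fitness_folds,
            },
            "use_pso": self.use_pso,
            "meta_params": self.meta_params,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        cfg = cls(
            encodings=[EncodingSpec.parse(n) for n in d.get("encodings", [])]
            or default_encodings(),
            families=tuple(d.get("families", FAMILIES)),
            base_params=d.get("base_params", {}),
            sweep_folds=d.get("sweep_folds", 5),
            sweep_max_thresholds=d.get("sweep_max_thresholds", 200),
            stacking_folds=d.get("stacking_folds", 10),
            pso=PsoConfig(**d["pso"]) if "pso" in d else PsoConfig(),
            use_pso=d.get("use_pso", True),
            meta_params=d.get("meta_params", {"max_iter": 1000}),
            seed=d.get("seed", 0),
        )
        return cfg
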