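"""Stacked generalisation: the out-of-fold "RNA profile".

Each sequence is re-represented by the positive-class probabilities the
base classifiers assign to it — one column per (encoding, family) pair, 30
columns in the default six-encodings × five-families architecture.  On
training data every entry is *out-of-fold*: the training rows are split
into stratified folds and the entry for row i comes from the model fitted
on the folds that do not contain i, so the meta-classifier never sees a
base prediction contaminated by its own row.  On held-out data each column
is the average of the k fold-models' probabilities.

Feature masks from the threshold sweep are applied per column before
fitting; the fitted fold models are retained, because scoring new
sequences uses exactly the fold-average route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .base import BaseModelSpec, FittedBaseModel, fit
from .encoders import EncodingSpec, encode
from .evaluation import ConfusionCounts, compute_metrics
from .io import SequenceDataset
from .selection import FeatureMask


@dataclass(frozen=True)
class ProfileColumn:
    """Metadata for one profile dimension: which encoding fed which family."""

    encoding: EncodingSpec
    family: str

    @property
    def name(self) -> str:
        return f"{self.encoding.name}:{self.family}"


@dataclass
class RnaProfile:
    """n_sequences × D matrix of base-classifier probabilities."""

    values: np.ndarray
    columns: list[ProfileColumn]
    provenance: str  # "out_of_fold" | "averaged_test"

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column metadata does not match matrix width")

    @property
    def n_dims(self) -> int:
        return len(self.columns)

    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


@dataclass
class FoldModels:
    """Everything needed to score new sequences: per-column fold models + masks."""

    encodings: list[EncodingSpec]
    specs: list[BaseModelSpec]
    masks: dict[str, FeatureMask]  # keyed by ProfileColumn.name
    models: dict[str, list[FittedBaseModel]] = field(default_factory=dict)
    fold_test_indices: list[np.ndarray] = field(default_factory=list)
    window_length: int = 0
    n_folds: int = 0
    seed: int = 0

    def columns(self) -> list[ProfileColumn]:
        return [ProfileColumn(enc, spec.family) for enc in self.encodings for spec in self.specs]


def _masked(values: np.ndarray, mask: FeatureMask | None) -> np.ndarray:
    return values if mask is None else values[:, mask.keep]


def out_of_fold_profile(
    dataset: SequenceDataset,
    encodings: list[EncodingSpec],
    specs: list[BaseModelSpec],
    masks: dict[str, FeatureMask] | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[RnaProfile, FoldModels]:
    """Build the training profile from stratified out-of-fold predictions.

    ``masks`` maps column names (``"<encoding>:<family>"``) to feature
    masks; missing or None entries mean "use all features".
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = dataset.y
    if len(dataset) < n_folds:
        raise ValueError(f"{len(dataset)} rows cannot be split into {n_folds} folds")
    masks = masks or {}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    for fold_i, (train_idx, _) in enumerate(splits):
        if np.unique(y[train_idx]).size < 2:
            raise ValueError(f"fold {fold_i}: a class is absent from the training part")

    features = {enc.name: encode(dataset, enc).values for enc in encodings}
    fm = FoldModels(
        encodings=list(encodings),
        specs=list(specs),
        masks={},
        fold_test_indices=[test for _, test in splits],
        window_length=dataset.window_length,
        n_folds=n_folds,
        seed=seed,
    )
    cols = []
    for enc in encodings:
        for spec in specs:
            name = ProfileColumn(enc, spec.family).name
            mask = masks.get(name)
            X = _masked(features[enc.name], mask)
            col = np.empty(len(y), dtype=np.float64)
            fold_fits = []
            for train_idx, test_idx in splits:
                m = fit(spec, X[train_idx], y[train_idx])
                col[test_idx] = m.predict_proba(X[test_idx])
                fold_fits.append(m)
            fm.models[name] = fold_fits
            if mask is not None:
                fm.masks[name] = mask
            cols.append(col)
    profile = RnaProfile(np.column_stack(cols), fm.columns(), provenance="out_of_fold")
    return profile, fm


def test_profile(test: SequenceDataset, fold_models: FoldModels) -> RnaProfile:
    """Profile for held-out sequences: per column, mean over the k fold models."""
    if test.window_length != fold_models.window_length:
        raise ValueError(
            f"window length mismatch: model expects {fold_models.window_length} nt, "
            f"input is {test.window_length} nt"
        )
    features = {enc.name: encode(test, enc).values for enc in fold_models.encodings}
    cols = []
    for enc in fold_models.encodings:
        for spec in fold_models.specs:
            name = ProfileColumn(enc, spec.family).name
            X = _masked(features[enc.name], fold_models.masks.get(name))
            preds = np.stack([m.predict_proba(X) for m in fold_models.models[name]])
            cols.append(preds.mean(axis=0))
    return RnaProfile(np.column_stack(cols), fold_models.columns(), provenance="averaged_test")


def profile_column_mcc(profile: RnaProfile, labels, threshold: float = 0.5) -> np.ndarray:
    """Per-dimension MCC of the thresholded profile against the labels.

    Shows how unevenly the base classifiers perform across encodings — the
    heterogeneity that makes stacking them worthwhile.
    """
    y = np.asarray(labels, dtype=int)
    out = np.empty(profile.n_dims)
    for j in range(profile.n_dims):
        pred = (profile.values[:, j] >= threshold).astype(int)
        out[j] = compute_metrics(ConfusionCounts.from_labels(y, pred)).mcc
    return out
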