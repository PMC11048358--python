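"""Two-step importance-threshold feature selection.

Step 1: pretrain the base learner on the full feature matrix and read off
its per-feature importances.  Step 2: sort the distinct importance values
ascending and try each as a keep-threshold (feature kept iff importance ≥
threshold — masks are therefore nested as the threshold grows); score each
candidate mask by stratified cross-validated accuracy of a freshly fitted
model of the same family, and keep the best.  Ties break toward the larger
threshold, i.e. the smaller feature set.

The comparison is inclusive so the largest threshold always retains the
argmax feature(s): the returned mask is never empty, even when every
importance is zero (then the single threshold 0 keeps all features).
Because a k=3 one-hot matrix can have over a thousand distinct importances,
the candidate list is subsampled at evenly spaced quantiles beyond a
configurable cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .base import BaseModelSpec, _values, fit


@dataclass
class FeatureMask:
    """Result of the threshold sweep for one (encoding, family) pair."""

    keep: np.ndarray  # boolean over features
    threshold: float
    score: float  # CV accuracy at that threshold
    n_candidates: int  # thresholds actually evaluated

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if not self.keep.any():
            raise ValueError("a feature mask must keep at least one feature")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def rank_importances(spec: BaseModelSpec, X, y) -> np.ndarray:
    """Pretrain ``spec`` on (X, y) and return its nonnegative importances."""
    return fit(spec, X, y).importances


def candidate_thresholds(importances: np.ndarray, max_thresholds: int) -> np.ndarray:
    """Distinct importances ascending, quantile-subsampled beyond the cap.

    The smallest and largest distinct values are always retained, so the
    all-features and fewest-features masks are always candidates.
    """
    distinct = np.unique(np.asarray(importances, dtype=np.float64))
    if distinct.size <= max_thresholds:
        return distinct
    idx = np.unique(np.round(np.linspace(0, distinct.size - 1, max_thresholds)).astype(int))
    return distinct[idx]


def threshold_sweep(
    spec: BaseModelSpec,
    X,
    y,
    n_folds: int = 5,
    seed: int = 0,
    max_thresholds: int = 200,
    importances: np.ndarray | None = None,
) -> FeatureMask:
    """Sweep importance thresholds; return the best-scoring mask.

    ``importances`` may be passed to reuse a pretrained ranking; otherwise
    step 1 is run here with the same spec.
    """
    arr = _values(X)
    y = np.asarray(y, dtype=int)
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    if arr.shape[0] < n_folds:
        raise ValueError(f"{arr.shape[0]} rows cannot be split into {n_folds} folds")
    if importances is None:
        importances = rank_importances(spec, arr, y)
    importances = np.asarray(importances, dtype=np.float64)
    if importances.shape[0] != arr.shape[1]:
        raise ValueError("importances length does not match feature count")

    thresholds = candidate_thresholds(importances, max_thresholds)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    best: FeatureMask | None = None
    for t in thresholds:
        keep = importances >= t
        if not keep.any():  # cannot happen for t <= max(importances); guard anyway
            continue
        score = float(cross_val_score(spec.build(), arr[:, keep], y, cv=cv, scoring="accuracy").mean())
        # ascending sweep + ">=" prefers the larger threshold (fewer features) on ties
        if best is None or score >= best.score:
            best = FeatureMask(keep=keep, threshold=float(t), score=score, n_candidates=thresholds.size)
    assert best is not None
    return best


def mask_table(mask: FeatureMask, importances: np.ndarray, feature_names: list[str]):
    """Per-feature TSV-ready table: name, importance, kept."""
    import pandas as pd

    return pd.DataFrame(
        {"feature": feature_names, "importance": importances, "kept": mask.keep}
    )
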