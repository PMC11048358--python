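"""Evaluation: ACC / SN / SP / MCC, the outer cross-validation harness, and
profile diagnostics.

The four metrics are the field's standard quartet for site predictors::

    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

Whenever a denominator is zero the metric is defined as 0 — balanced
benchmarks never hit this, but degenerate synthetic folds can.

``cross_validate`` is the honest protocol: outer stratified folds, and the
*entire* pipeline (feature selection, stacking, PSO) refitted on each outer
training part, so nothing leaks from the held-out part.  Metrics are pooled
over all held-out predictions by default; per-fold sets are also returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        if t.shape != p.shape:
            raise ValueError("y_true and y_pred lengths differ")
        return cls(
            tp=int(((t == 1) & (p == 1)).sum()),
            fp=int(((t == 0) & (p == 1)).sum()),
            tn=int(((t == 0) & (p == 0)).sum()),
            fn=int(((t == 1) & (p == 0)).sum()),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sn: float
    sp: float
    mcc: float
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "SN": self.sn, "SP": self.sp, "MCC": self.mcc}


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """ACC, SN, SP and MCC from confusion counts (zero denominators -> 0)."""
    if counts.total < 1:
        raise ValueError("need at least one evaluated example")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    den = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    return MetricSet(
        acc=_ratio(tp + tn, counts.total),
        sn=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        mcc=mcc,
        counts=counts,
    )


def profile_correlation(profile) -> np.ndarray:
    """Pearson correlation between profile columns (diversity diagnostic).

    Constant columns get correlation 0 against everything else; the
    diagonal is 1 by convention.  Returns a symmetric D×D matrix in [-1, 1].
    """
    values = profile.values if hasattr(profile, "values") else np.asarray(profile, float)
    if values.shape[0] < 2:
        raise ValueError("need at least two rows to correlate")
    sd = values.std(axis=0)
    keep = sd > 0
    corr = np.zeros((values.shape[1], values.shape[1]))
    if keep.any():
        sub = np.corrcoef(values[:, keep], rowvar=False)
        corr[np.ix_(keep, keep)] = np.atleast_2d(sub)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


@dataclass
class CvResult:
    pooled: MetricSet
    per_fold: list[MetricSet]


def cross_validate(
    dataset,
    config,
    n_folds: int = 10,
    seed: int | None = None,
    modes: tuple[str, ...] = ("stack", "pso"),
    pso_refit: bool = True,
) -> dict[str, CvResult]:
    """Outer stratified CV of the full pipeline.

    For each outer fold the base stages (encodings, feature selection,
    out-of-fold stacking) are fitted once on the training part; each
    requested mode then finalises its own meta-classifier — ``stack`` with
    unit weights, ``pso`` with swarm-optimised weights — and scores the
    held-out part.  With identical seeds the stages are identical between
    modes, so sharing them changes nothing but runtime.

    ``pso_refit=False`` is the cheaper, *optimistic* variant: the swarm
    runs once on the whole dataset and the resulting weights are reused in
    every outer fold.  Its weights have seen the held-out rows' profile,
    so its numbers can be biased upward; the honest default refits the
    swarm per fold.
    """
    from . import model as model_mod  # local import to avoid a cycle
    from .pso import optimize_weights

    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if seed is None:
        seed = config.seed
    y = dataset.y
    fixed_weights = None
    if "pso" in modes and not pso_refit:
        full_stages = model_mod.fit_stages(dataset, config)
        wv, _ = optimize_weights(
            full_stages.profile, y, config.pso, meta_params=config.meta_params
        )
        fixed_weights = wv.w
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    counts: dict[str, list[ConfusionCounts]] = {m: [] for m in modes}
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train_ds = dataset.subset(train_idx)
        test_ds = dataset.subset(test_idx)
        stages = model_mod.fit_stages(train_ds, config)
        for mode in modes:
            if mode == "pso" and fixed_weights is not None:
                bundle = model_mod.finalize(stages, config, weights=fixed_weights)
            else:
                bundle = model_mod.finalize(stages, config, use_pso=(mode == "pso"))
            preds = model_mod.predict(bundle, test_ds)
            counts[mode].append(
                ConfusionCounts.from_labels(y[test_idx], preds["label"].to_numpy())
            )
    out: dict[str, CvResult] = {}
    for mode in modes:
        pooled = counts[mode][0]
        for c in counts[mode][1:]:
            pooled = pooled + c
        out[mode] = CvResult(
            pooled=compute_metrics(pooled),
            per_fold=[compute_metrics(c) for c in counts[mode]],
        )
    return out


def report_text(results: dict[str, CvResult]) -> str:
    """Human-readable two-row comparison (unweighted stack vs PSO-weighted)."""
    lines = [f"{'mode':<12}{'ACC':>8}{'MCC':>8}{'SN':>8}{'SP':>8}"]
    for mode, res in results.items():
        m = res.pooled
        lines.append(f"{mode:<12}{m.acc:>8.3f}{m.mcc:>8.3f}{m.sn:>8.3f}{m.sp:>8.3f}")
    return "\n".join(lines)
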