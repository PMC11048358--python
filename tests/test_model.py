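"""End-to-end assembly: training, prediction, determinism, persistence."""

import numpy as np
import pytest

from pseusite import EncodingSpec, PipelineConfig, PsoConfig, fit_predictor, load, predict, save
from pseusite.model import finalize, fit_stages
from tests.conftest import TINY_PARAMS


def _tiny_config(seed=0, use_pso=True):
    """Reduced architecture (2 encodings x 5 families) for fast end-to-end runs."""
    cfg = PipelineConfig(
        encodings=[EncodingSpec("onehot", 1), EncodingSpec("kmer", 2)],
        base_params={k: dict(v) for k, v in TINY_PARAMS.items()},
        sweep_folds=3,
        sweep_max_thresholds=4,
        stacking_folds=4,
        pso=PsoConfig(n_particles=6, n_iterations=5, fitness_folds=3),
        use_pso=use_pso,
        seed=seed,
    )
    return cfg.reseed(seed)


@pytest.fixture(scope="module")
def fitted(separable_dataset):
    return fit_predictor(separable_dataset, _tiny_config(seed=1))


def test_fit_predictor_learns_separable_data(fitted, separable_dataset):
    preds = predict(fitted, separable_dataset)
    assert list(preds.columns) == ["id", "probability", "label"]
    assert len(preds) == len(separable_dataset)
    assert ((preds["probability"] >= 0) & (preds["probability"] <= 1)).all()
    acc = (preds["label"].to_numpy() == separable_dataset.y).mean()
    assert acc > 0.9
    assert fitted.weights.shape == (10,)
    assert len(fitted.fitness_history) == 5


def test_pipeline_composition_equals_manual_stages(fitted, separable_dataset):
    """fit_predictor is exactly fit_stages + finalize on the same seeds."""
    cfg = _tiny_config(seed=1)
    manual = finalize(fit_stages(separable_dataset, cfg), cfg)
    assert np.array_equal(manual.weights, fitted.weights)
    assert np.array_equal(manual.meta.coef_, fitted.meta.coef_)
    p1 = predict(manual, separable_dataset)["probability"].to_numpy()
    p2 = predict(fitted, separable_dataset)["probability"].to_numpy()
    assert np.array_equal(p1, p2)


def test_refit_is_deterministic(separable_dataset, fitted):
    again = fit_predictor(separable_dataset, _tiny_config(seed=1))
    assert np.array_equal(again.weights, fitted.weights)
    assert np.array_equal(again.meta.coef_, fitted.meta.coef_)
    assert again.fitness_history == fitted.fitness_history


def test_duplicated_input_scores_identically(fitted, separable_dataset):
    doubled = separable_dataset.subset([0, 0, 1])
    preds = predict(fitted, doubled)
    assert preds["probability"].iloc[0] == preds["probability"].iloc[1]


def test_save_load_round_trip(tmp_path, fitted, separable_dataset):
    save(fitted, tmp_path / "bundle")
    assert (tmp_path / "bundle" / "manifest.json").exists()
    back = load(tmp_path / "bundle")
    assert np.array_equal(back.weights, fitted.weights)
    p1 = predict(fitted, separable_dataset)["probability"].to_numpy()
    p2 = predict(back, separable_dataset)["probability"].to_numpy()
    assert np.array_equal(p1, p2)


def test_window_length_mismatch_names_ids(fitted):
    from pseusite.simulate import default_specs, generate

    yeast = generate(default_specs(n_pos=3, n_neg=3, seed=0)["yeast-like"])
    with pytest.raises(ValueError, match="window length mismatch"):
        predict(fitted, yeast)


def test_unlabeled_training_rejected(separable_dataset):
    from pseusite import RnaSequenceRecord, SequenceDataset

    unlabeled = SequenceDataset(
        [RnaSequenceRecord(r.id, r.sequence) for r in separable_dataset.records]
    )
    with pytest.raises(ValueError, match="label"):
        fit_stages(unlabeled, _tiny_config())


def test_stack_mode_skips_swarm(separable_dataset):
    bundle = fit_predictor(separable_dataset, _tiny_config(seed=2, use_pso=False))
    assert np.array_equal(bundle.weights, np.ones(10))
    assert bundle.weight_fitness is None and bundle.fitness_history == []


def test_fixed_weights_cv_mode_is_supported(separable_dataset):
    """The optimistic variant (swarm run once, weights reused per outer fold)
    produces valid pooled metrics and conserves the confusion counts."""
    from pseusite import cross_validate

    cfg = _tiny_config(seed=4)
    res = cross_validate(separable_dataset, cfg, n_folds=3, pso_refit=False)
    pooled = res["pso"].pooled
    assert 0.0 <= pooled.acc <= 1.0
    assert sum(m.counts.total for m in res["pso"].per_fold) == len(separable_dataset)
    assert pooled.counts.total == len(separable_dataset)
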