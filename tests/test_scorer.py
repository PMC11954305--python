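"""Synthesizability scorer: features, splits, training, evaluation, I/O."""

import math

import numpy as np
import pytest

from insynth.chem import DESCRIPTOR_NAMES
from insynth.fixtures import gen_planted_dataset
from insynth.planner import SearchConfig
from insynth.scorer import (
    DEFAULT_PARAMS,
    HyperparameterSpace,
    LabeledDataset,
    ScoreModel,
    evaluate,
    feature_names,
    featurize,
    label_by_planning,
    predict_synthesizability,
    stratified_holdout,
    train_final,
    tune_hyperparameters,
)


@pytest.fixture(scope="module")
def small_dataset():
    records, noisy, _ = gen_planted_dataset(0, 500, 0.0)
    return LabeledDataset(records=records[:200], labels=noisy[:200])


def test_featurize_shape_and_dtype(small_dataset):
    X = featurize(small_dataset.records[:10])
    assert X.shape == (10, 2048 + len(DESCRIPTOR_NAMES))
    assert X.dtype == np.float32
    assert len(feature_names()) == X.shape[1]


def test_stratified_holdout_preserves_balance(small_dataset):
    train, test = stratified_holdout(small_dataset, test_fraction=0.2, seed=0)
    assert len(train) + len(test) == len(small_dataset)
    full_rate = small_dataset.labels.mean()
    assert abs(test.labels.mean() - full_rate) <= 1.5 / len(test)


def test_stratified_holdout_single_class_error(small_dataset):
    ones = LabeledDataset(
        records=small_dataset.records[:20], labels=np.ones(20, dtype=int)
    )
    with pytest.raises(ValueError, match="stratify"):
        stratified_holdout(ones)


def test_retrain_same_seed_identical_predictions(small_dataset):
    m1 = train_final(small_dataset, DEFAULT_PARAMS, seed=3)
    m2 = train_final(small_dataset, DEFAULT_PARAMS, seed=3)
    p1 = m1.predict_proba_records(small_dataset.records[:50])
    p2 = m2.predict_proba_records(small_dataset.records[:50])
    assert np.array_equal(p1, p2)


def test_evaluate_matches_hand_computed_confusion(small_dataset):
    train, test = stratified_holdout(small_dataset, test_fraction=0.2, seed=0)
    model = train_final(train, DEFAULT_PARAMS, seed=0)
    metrics = evaluate(model, test)
    c = metrics["confusion"]
    tp, tn, fp, fn = c["tp"], c["tn"], c["fp"], c["fn"]
    assert tp + tn + fp + fn == metrics["n"] == len(test)
    # recompute every reported metric from the confusion matrix
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 2 * precision * recall / (precision + recall)
    assert metrics["f1"] == pytest.approx(f1)
    assert metrics["accuracy"] == pytest.approx((tp + tn) / metrics["n"])
    mcc = (tp * tn - fp * fn) / math.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    assert metrics["mcc"] == pytest.approx(mcc)


def test_mcc_zero_marginal_convention(small_dataset):
    model = train_final(small_dataset, DEFAULT_PARAMS, seed=0)
    pos_idx = [i for i, y in enumerate(small_dataset.labels) if y == 1][:20]
    one_class = small_dataset.subset(pos_idx)
    metrics = evaluate(model, one_class)
    assert metrics["mcc"] == 0.0


def test_duplicate_inputs_identical_probabilities(small_dataset):
    model = train_final(small_dataset, DEFAULT_PARAMS, seed=0)
    rec = small_dataset.records[0]
    proba = model.predict_proba_records([rec, rec, rec])
    assert proba[0] == proba[1] == proba[2]
    single = model.predict_proba_records([rec])
    assert single[0] == proba[0]


def test_model_save_load_roundtrip(small_dataset, tmp_path):
    model = train_final(small_dataset, DEFAULT_PARAMS, seed=0)
    out = str(tmp_path / "model")
    model.save(out)
    back = ScoreModel.load(out)
    p1 = predict_synthesizability(model, small_dataset.records[:30])
    p2 = predict_synthesizability(back, small_dataset.records[:30])
    assert np.array_equal(p1, p2)
    assert back.fp_params == model.fp_params
    assert back.params == pytest.approx(model.params)


def test_hyperparameter_space_bounds():
    space = HyperparameterSpace()
    rng = np.random.default_rng(0)
    for _ in range(50):
        p = space.sample(rng)
        assert 0.05 <= p["learning_rate"] <= 0.4
        assert 1 <= p["max_depth"] <= 50
        assert 0 <= p["gamma"] <= 10
        assert 5 <= p["n_estimators"] <= 250


def test_tuner_is_seeded_and_logged(small_dataset):
    best1, log1 = tune_hyperparameters(small_dataset, n_rounds=3, seed=5)
    best2, log2 = tune_hyperparameters(small_dataset, n_rounds=3, seed=5)
    assert best1 == best2
    assert len(log1) == 3
    assert log1.equals(log2)
    with pytest.raises(ValueError):
        tune_hyperparameters(small_dataset, n_rounds=0)


def test_label_by_planning_agrees_with_certified_truth(
    universe, solvable_set, unsolvable_set
):
    templates, stock, _ = universe
    molecules = [s.record for s in solvable_set[:5]] + [
        u.record for u in unsolvable_set[:3]
    ]
    config = SearchConfig(iteration_limit=300, max_depth=4, seed=0)
    dataset = label_by_planning(molecules, stock, templates, config)
    assert dataset.labels.tolist() == [1] * 5 + [0] * 3
    assert dataset.search_config_digest == config.digest()


def test_training_exemplar_scores_above_half(small_dataset):
    model = train_final(small_dataset, DEFAULT_PARAMS, seed=0)
    pos = [r for r, y in zip(small_dataset.records, small_dataset.labels) if y == 1]
    proba = model.predict_proba_records(pos[:10])
    assert (proba > 0.5).all()
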