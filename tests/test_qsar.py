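"""Multiclass QSAR: feature filtering, metrics, CV, the model suite."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from cyp17space.errors import (
    ConfigurationError,
    DegenerateFeaturesError,
    DegenerateLabelError,
)
from cyp17space.qsar import (
    ConfusionMatrix,
    ModelConfig,
    accuracy,
    collapse_binary,
    cross_validate,
    evaluate_dataset,
    feature_select,
    micro_recall,
    multiclass_mcc,
    run_model_suite,
    train_model,
)


def _random_cm(rng, k=4, high=40):
    return ConfusionMatrix(tuple(f"c{i}" for i in range(k)),
                           rng.integers(0, high, size=(k, k)))


# ---------- feature selection ----------

def test_feature_select_drops_constant_and_duplicate_columns():
    rng = np.random.default_rng(0)
    base = rng.integers(0, 2, size=(200, 1)).astype(float)
    X = np.hstack([base, np.ones((200, 1)), base.copy(), rng.integers(0, 2, (200, 1))])
    mask = feature_select(X)
    assert mask.tolist() == [True, False, False, True]


def test_feature_select_keeps_independent_binary_columns():
    rng = np.random.default_rng(1)
    X = rng.integers(0, 2, size=(1000, 2)).astype(float)
    assert feature_select(X).all()  # variance ~0.25, |r| ~0


def test_feature_select_row_order_invariant_and_degenerate():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(50, 10))
    mask = feature_select(X)
    assert np.array_equal(mask, feature_select(X[rng.permutation(50)]))
    with pytest.raises(DegenerateFeaturesError):
        feature_select(np.ones((10, 3)))


# ---------- metrics ----------

def test_accuracy_and_recall_examples():
    cm = ConfusionMatrix(("a", "b"), np.array([[3, 1], [2, 4]]))
    assert accuracy(cm) == pytest.approx(0.7)
    perfect = ConfusionMatrix(("a", "b"), np.diag([5, 7]))
    assert accuracy(perfect) == 1.0 and micro_recall(perfect) == 1.0
    with pytest.raises(ValueError):
        accuracy(ConfusionMatrix(("a",), np.zeros((1, 1))))


def test_accuracy_equals_micro_recall_for_random_matrices():
    """The multiclass accuracy/micro-recall identity, checked exhaustively."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        k = int(rng.integers(2, 6))
        cm = _random_cm(rng, k)
        if cm.total == 0:
            continue
        assert accuracy(cm) == pytest.approx(micro_recall(cm), abs=1e-12)


def test_multiclass_mcc_matches_binary_formula():
    """On k=2 the R_k statistic reduces to the classical binary MCC."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        cm = _random_cm(rng, 2)
        tn, fp = cm.counts[1, 1], cm.counts[1, 0]
        tp, fn = cm.counts[0, 0], cm.counts[0, 1]
        den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        classical = 0.0 if den == 0 else (tp * tn - fp * fn) / den
        assert multiclass_mcc(cm) == pytest.approx(classical, abs=1e-10)


def test_multiclass_mcc_range_and_extremes():
    rng = np.random.default_rng(8)
    for _ in range(200):
        cm = _random_cm(rng, int(rng.integers(2, 5)))
        v = multiclass_mcc(cm)
        assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12
        off_diag = cm.counts.sum() - np.trace(cm.counts)
        if v == pytest.approx(1.0) and cm.total > 0:
            assert off_diag == 0
    perfect = ConfusionMatrix(("a", "b", "c"), np.diag([3, 4, 5]))
    assert multiclass_mcc(perfect) == pytest.approx(1.0)
    # all predictions in one class: zero denominator -> 0 by convention
    degenerate = ConfusionMatrix(("a", "b"), np.array([[3, 0], [5, 0]]))
    assert multiclass_mcc(degenerate) == 0.0
    # agreement with sklearn's implementation on prediction vectors
    rng2 = np.random.default_rng(9)
    y_true = rng2.integers(0, 4, 300)
    y_pred = rng2.integers(0, 4, 300)
    cm = ConfusionMatrix.from_predictions(
        [str(v) for v in y_true], [str(v) for v in y_pred], [str(i) for i in range(4)]
    )
    assert multiclass_mcc(cm) == pytest.approx(matthews_corrcoef(y_true, y_pred))


def test_collapse_binary_blocks_and_chance_accuracy():
    labels = ("potent", "active", "intermediate", "inactive")
    perfect = ConfusionMatrix(labels, np.diag([5, 5, 5, 5]))
    cm2, stats = collapse_binary(perfect)
    assert stats["q2"] == 1.0
    assert stats["q2_rnd"] == pytest.approx(0.5)  # balanced marginals
    assert stats["delta_q2"] == pytest.approx(0.5)
    assert cm2.counts.tolist() == [[10, 0], [0, 10]]
    mixed = ConfusionMatrix(labels, np.array(
        [[3, 1, 1, 0], [2, 2, 0, 1], [0, 1, 4, 1], [1, 0, 2, 3]]))
    cm2, stats = collapse_binary(mixed)
    # block sums: positive = potent+active rows/cols
    assert cm2.counts[0, 0] == 3 + 1 + 2 + 2
    assert stats["q2"] == accuracy(cm2)
    with pytest.raises(ConfigurationError):
        collapse_binary(perfect, positive=labels)


# ---------- training and CV ----------

def test_tree_memorizes_separable_toy_data():
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 5, dtype=float)
    y = np.array(["a", "a", "b", "b"] * 5)
    model = train_model(ModelConfig("DT"), X, y)
    assert (model.predict(X) == y).all()


def test_training_determinism_and_degenerate_labels():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 5))
    y = np.array(["a", "b", "c"] * 20)
    m1 = train_model(ModelConfig("ET", seed=11), X, y)
    m2 = train_model(ModelConfig("ET", seed=11), X, y)
    assert (m1.predict(X) == m2.predict(X)).all()
    with pytest.raises(DegenerateLabelError):
        train_model(ModelConfig("DT"), X, np.array(["a"] * 60))
    with pytest.raises(ConfigurationError):
        train_model(ModelConfig("KNN"), X[:3], y[:3])
    with pytest.raises(ConfigurationError):
        ModelConfig("NOT_AN_ALGO")


def test_cv_pools_each_sample_once():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(50, 4))
    X[:25] += 10.0  # cleanly separable
    y = np.array(["hi"] * 25 + ["lo"] * 25)
    res = cross_validate(ModelConfig("DT", cv_folds=5), X, y)
    assert res["confusion"].total == 50  # every sample predicted exactly once
    assert res["accuracy"] == pytest.approx(1.0)
    assert res["n_folds"] == 5


def test_cv_majority_dummy_on_balanced_four_classes():
    """A feature-blind model scores ~1/4 pooled accuracy on balanced labels."""
    rng = np.random.default_rng(5)
    X = np.zeros((120, 3))
    X[:, 0] = rng.normal(size=120) * 1e-9
    y = np.array(["a", "b", "c", "d"] * 30)
    res = cross_validate(ModelConfig("KNN", cv_folds=4), X + rng.normal(size=(120, 3)), y)
    assert abs(res["accuracy"] - 0.25) < 0.15


def test_cv_fold_reduction_warning(caplog):
    rng = np.random.default_rng(6)
    X = rng.normal(size=(12, 3))
    y = np.array(["a"] * 8 + ["b"] * 4)
    res = cross_validate(ModelConfig("DT", cv_folds=10), X, y)
    assert res["n_folds"] == 4


# ---------- suite ----------

def test_suite_on_separable_synthetic_group(fixture_dataset):
    records, _ = fixture_dataset
    from cyp17space.scaffolds import scaffold_table

    biggest = scaffold_table(records)[0]
    reports, skipped = run_model_suite(
        records, [ModelConfig("ET")], scaffold_groups={"g0": biggest.member_ids}
    )
    assert not skipped
    rep = reports[0]
    assert rep.test_accuracy >= 0.8
    assert rep.is_best
    # feature mask fitted on train is applied unchanged to test
    assert rep.feature_mask.dtype == bool and rep.feature_mask.any()
    # the identity holds on every reported matrix
    for section in (rep.training, rep.cv, rep.test):
        assert section["accuracy"] == pytest.approx(section["micro_recall"])


def test_suite_skips_small_and_single_class_groups(fixture_dataset):
    records, truth = fixture_dataset
    small_ids = [r.compound_id for r in records[:6]]
    reports, skipped = run_model_suite(
        records, [ModelConfig("DT")], scaffold_groups={"tiny": small_ids}
    )
    assert reports == []
    assert skipped[0]["reason"] == "too_few_compounds"
    with pytest.raises(ConfigurationError):
        run_model_suite(records, [ModelConfig("DT")], scaffold_groups={"bad": ["nope"]})


def test_suite_deterministic_ranking(fixture_dataset):
    records, _ = fixture_dataset
    from cyp17space.scaffolds import scaffold_table

    biggest = scaffold_table(records)[0]
    configs = [ModelConfig("DT"), ModelConfig("ET")]
    r1, _ = run_model_suite(records, configs, scaffold_groups={"g": biggest.member_ids})
    r2, _ = run_model_suite(records, configs, scaffold_groups={"g": biggest.member_ids})
    assert [(r.config.algorithm, r.test_accuracy) for r in r1] == [
        (r.config.algorithm, r.test_accuracy) for r in r2
    ]
    accs = [r.test_accuracy for r in r1]
    assert accs == sorted(accs, reverse=True)
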