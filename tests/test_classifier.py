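"""Neural-network classifier: model matrix, training, CV and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antmorph import (
    NNConfig,
    NNModel,
    build_model_matrix,
    classification_metrics,
    confusion_matrix,
    cross_validate,
    stratified_kfold,
    train_nn,
)
from antmorph.classifier import ColumnScaler
from antmorph.errors import StratificationError
from conftest import make_table


def _toy_blobs(n_per=25, gap=8.0, seed=0, k=2, p=5):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(i * gap, 1.0, (n_per, p)) for i in range(k)])
    y = np.repeat([f"c{i}" for i in range(k)], n_per)
    return X, y


# -- model matrix -----------------------------------------------------


def test_model_matrix_shape_and_interactions(study_table):
    X, y, names = build_model_matrix(study_table)
    assert X.shape == (81, 43)
    assert len(names) == 43
    infected = study_table.data["infected"].to_numpy()
    # uninfected rows: all interaction columns zero
    assert np.all(X[~infected, 22:] == 0.0)
    # infected rows: interaction columns equal raw trait columns
    np.testing.assert_array_equal(X[infected, 22:], X[infected, :21])
    assert set(y) == set(study_table.species_levels)


def test_scaler_fits_on_given_rows_only():
    X = np.array([[0.0], [2.0], [100.0]])
    sc = ColumnScaler().fit(X[:2])
    np.testing.assert_allclose(sc.mean, [1.0])
    z = sc.transform(X)
    np.testing.assert_allclose(z[:2].mean(), 0.0, atol=1e-12)


# -- training ---------------------------------------------------------


def test_training_is_deterministic_given_seed():
    X, y = _toy_blobs()
    Z = ColumnScaler().fit(X).transform(X)
    cfg = NNConfig(epochs=300, seed=9)
    m1, m2 = train_nn(Z, y, cfg), train_nn(Z, y, cfg)
    for W1, W2 in zip(m1.weights, m2.weights):
        np.testing.assert_array_equal(W1, W2)
    m3 = train_nn(Z, y, NNConfig(epochs=300, seed=10))
    assert any(not np.array_equal(a, b)
               for a, b in zip(m1.weights, m3.weights))


def test_loss_non_increasing_at_small_learning_rate():
    X, y = _toy_blobs()
    Z = ColumnScaler().fit(X).transform(X)
    m = train_nn(Z, y, NNConfig(learning_rate=0.01, epochs=500, seed=1))
    diffs = np.diff(m.loss_history)
    assert np.all(diffs <= 1e-10)


def test_separable_blobs_reach_perfect_training_accuracy():
    X, y = _toy_blobs()
    Z = ColumnScaler().fit(X).transform(X)
    m = train_nn(Z, y, NNConfig(seed=1))
    pred = m.predict(Z)
    assert (pred == y.astype(object)).mean() == 1.0


def test_zero_epochs_gives_near_uniform_probabilities():
    X, y = _toy_blobs(k=3)
    Z = ColumnScaler().fit(X).transform(X)
    m = train_nn(Z, y, NNConfig(epochs=0, seed=4))
    proba = m.predict_proba(Z)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(proba > 0.05) and np.all(proba < 0.8)


def test_probabilities_sum_to_one_and_tie_breaks_to_first_class():
    X, y = _toy_blobs(k=3)
    m = train_nn(ColumnScaler().fit(X).transform(X), y,
                 NNConfig(epochs=5, seed=0))
    proba = m.predict_proba(X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
    # exact tie: zero out the output layer -> equal logits
    m.weights[-1][:] = 0.0
    m.biases[-1][:] = 0.0
    assert set(m.predict(X)) == {"c0"}


def test_dimension_mismatch_raises():
    X, y = _toy_blobs()
    m = train_nn(X, y, NNConfig(epochs=1, seed=0))
    with pytest.raises(ValueError, match="columns"):
        m.predict(X[:, :3])


def test_model_json_round_trip_preserves_predictions():
    X, y = _toy_blobs()
    m = train_nn(X, y, NNConfig(epochs=50, seed=2))
    back = NNModel.from_json(m.to_json())
    np.testing.assert_array_equal(m.predict_proba(X),
                                  back.predict_proba(X))


# -- stratified folds -------------------------------------------------


def test_exactly_divisible_classes_give_one_per_fold():
    labels = np.repeat(["a", "b", "c"], 10)
    folds = stratified_kfold(labels, k=10, seed=0)
    for f in range(10):
        sel = labels[folds == f]
        assert sorted(sel) == ["a", "b", "c"]


def test_small_class_pigeonholes_across_folds():
    labels = np.array(["big"] * 30 + ["small"] * 6)
    folds = stratified_kfold(labels, k=10, seed=1)
    counts = np.bincount(folds[labels == "small"], minlength=10)
    assert sorted(counts) == [0, 0, 0, 0, 1, 1, 1, 1, 1, 1]


def test_study_like_class_counts_spread_within_one(study_table):
    y = study_table.data["species"].to_numpy()
    folds = stratified_kfold(y, k=10, seed=3)
    # folds partition the rows
    assert len(np.unique(folds)) == 10
    assert np.bincount(folds).sum() == 81
    for cls, lo, hi in (("T_nylanderi", 3, 4), ("T_sordidulus", 2, 3),
                        ("T_unifasciatus", 1, 2)):
        counts = np.bincount(folds[y == cls], minlength=10)
        assert counts.min() >= lo and counts.max() <= hi


def test_fold_assignment_deterministic_and_class_min_size_enforced():
    labels = np.repeat(["a", "b"], 15)
    f1 = stratified_kfold(labels, k=5, seed=7)
    f2 = stratified_kfold(labels, k=5, seed=7)
    np.testing.assert_array_equal(f1, f2)
    with pytest.raises(StratificationError):
        stratified_kfold(np.array(["a"] * 10 + ["b"]), k=5, seed=0)


# -- metrics ----------------------------------------------------------


def test_perfect_and_uniform_confusion_metrics():
    perfect = classification_metrics(np.diag([5, 5, 5]))
    assert all(abs(v - 1.0) < 1e-12 for v in perfect.values())
    uniform = classification_metrics(np.array([[1, 1], [1, 1]]))
    assert uniform["mcc"] == 0.0
    assert uniform["accuracy"] == 0.5


def _binary_mcc(tp, fn, fp, tn):
    den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    return 0.0 if den == 0 else (tp * tn - fp * fn) / den


def test_worked_binary_example_matches_closed_form():
    mat = np.array([[3, 1], [2, 4]])
    got = classification_metrics(mat)["mcc"]
    np.testing.assert_allclose(got, _binary_mcc(3, 1, 2, 4), rtol=1e-12)


@settings(max_examples=200, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=50), min_size=4,
                max_size=4))
def test_multiclass_mcc_reduces_to_binary_formula(cells):
    tp, fn, fp, tn = cells
    if tp + fn + fp + tn == 0:
        return
    mat = np.array([[tp, fn], [fp, tn]])
    got = classification_metrics(mat)["mcc"]
    np.testing.assert_allclose(got, _binary_mcc(tp, fn, fp, tn), atol=1e-12)


def test_multiclass_mcc_matches_sklearn_oracle():
    from sklearn.metrics import matthews_corrcoef

    rng = np.random.default_rng(5)
    for _ in range(20):
        y_true = rng.integers(0, 4, 60)
        y_pred = rng.integers(0, 4, 60)
        mat = confusion_matrix(y_true, y_pred, ["0", "1", "2", "3"])
        np.testing.assert_allclose(
            classification_metrics(mat)["mcc"],
            matthews_corrcoef(y_true, y_pred),
            atol=1e-12,
        )


def test_micro_averaging_collapses_precision_to_accuracy():
    rng = np.random.default_rng(0)
    mat = rng.integers(0, 10, (3, 3))
    m = classification_metrics(mat, averaging="micro")
    np.testing.assert_allclose(m["precision"], m["accuracy"], atol=1e-12)
    np.testing.assert_allclose(m["sensitivity"], m["accuracy"], atol=1e-12)


# -- cross-validation -------------------------------------------------


def test_cv_folds_partition_and_confusions_sum_to_fold_sizes(study_table):
    cfg = NNConfig(epochs=50)
    report = cross_validate(study_table, k=10, config=cfg, seed=2)
    sizes = [int(c.sum()) for c in report.confusions]
    assert sum(sizes) == 81
    assert max(sizes) - min(sizes) <= 1
    # averaged row is the arithmetic mean of fold rows
    np.testing.assert_allclose(
        report.metrics.loc["averaged"],
        report.metrics.drop(index="averaged").mean(axis=0),
    )


def test_scaling_refit_per_fold_without_test_rows(study_table,
                                                  monkeypatch):
    """Leakage guard: each fold's scaler must be fitted on exactly the
    training rows (n_total - fold size), never on held-out rows."""
    fitted_sizes = []
    orig = ColumnScaler.fit

    def spy(self, X):
        fitted_sizes.append(len(X))
        return orig(self, X)

    monkeypatch.setattr(ColumnScaler, "fit", spy)
    report = cross_validate(study_table, k=10, config=NNConfig(epochs=2),
                            seed=0)
    test_sizes = [int(c.sum()) for c in report.confusions]
    assert fitted_sizes == [81 - s for s in test_sizes]


def test_permutation_null_accuracy_near_chance(study_table):
    """With species labels randomly permuted the classifier cannot beat
    chance (1/3) on held-out folds."""
    rng = np.random.default_rng(11)
    accs, sens = [], []
    for rep in range(3):
        df = study_table.data.copy()
        df["species"] = rng.permutation(df["species"].to_numpy())
        from antmorph import SpecimenTable

        shuffled = SpecimenTable.from_dataframe(df)
        rep_ = cross_validate(shuffled, k=5, config=NNConfig(epochs=400),
                              seed=rep)
        accs.append(rep_.averaged["accuracy"])
        sens.append(rep_.averaged["sensitivity"])
    assert 0.15 < np.mean(accs) < 0.55
    assert 0.15 < np.mean(sens) < 0.55


def test_train_test_duplication_gives_perfect_accuracy():
    """Sanity check on the scoring path: predicting the training rows of
    a separable problem back yields accuracy 1."""
    t = make_table({"a": (10, 10), "b": (10, 10)}, seed=2,
                   species_gap=200.0, noise=3.0)
    X, y, _ = build_model_matrix(t)
    Z = ColumnScaler().fit(X).transform(X)
    m = train_nn(Z, y, NNConfig(seed=0))
    mat = confusion_matrix(y, m.predict(Z), sorted(set(y)))
    assert classification_metrics(mat)["accuracy"] == 1.0
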