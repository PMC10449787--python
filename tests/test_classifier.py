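"""Forest training, the 70:30 split, RFE, vote-fraction prediction,
proximity outliers, and model persistence."""

import numpy as np
import pandas as pd
import pytest

from arcvir.classifier import (
    CatalogMismatchError,
    load_model,
    predict,
    proximity_matrix,
    proximity_outliers,
    rfe_select,
    save_model,
    split_train_test,
    train_forest,
    vote_fractions,
)
from arcvir.features import FeatureTable


def _labeled_table(n, n_features=6, seed=0, informative=True, labels=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    if labels is None:
        labels = np.array(["archaeal_virus", "phage"])[np.arange(n) % 2]
    if informative:
        X[:, 0] += np.where(labels == "archaeal_virus", 3.0, -3.0)
    ids = [f"s{i:04d}" for i in range(n)]
    return FeatureTable(
        data=pd.DataFrame(X, index=ids, columns=[f"f{j}" for j in range(n_features)]),
        labels=pd.Series(labels, index=ids),
    )


# ------------------------------------------------------------------- split


def test_split_sizes_follow_rounding_rule():
    labels = np.array(["archaeal_virus"] * 428 + ["phage"] * 429)
    t = _labeled_table(857, seed=1, labels=labels)
    tr, te = split_train_test(t, seed=0)
    assert (tr.n, te.n) == (600, 257)  # round(0.7 * 857) = 600
    assert set(tr.data.index).isdisjoint(te.data.index)
    assert set(tr.data.index) | set(te.data.index) == set(t.data.index)


def test_split_small_balanced_keeps_both_classes():
    t = _labeled_table(10, seed=2)
    tr, te = split_train_test(t, seed=5)
    assert (tr.n, te.n) == (7, 3)
    assert set(tr.labels) == set(te.labels) == {"archaeal_virus", "phage"}


def test_split_deterministic_given_seed():
    t = _labeled_table(40, seed=3)
    a = split_train_test(t, seed=9)[0].data.index
    b = split_train_test(t, seed=9)[0].data.index
    assert list(a) == list(b)


def test_split_is_stratified():
    labels = np.array(["archaeal_virus"] * 30 + ["phage"] * 70)
    t = _labeled_table(100, seed=4, labels=labels)
    tr, _ = split_train_test(t, seed=0)
    assert tr.labels.value_counts()["archaeal_virus"] == 21  # 0.7 * 30


def test_split_rejects_tiny_class():
    labels = np.array(["archaeal_virus"] * 3 + ["phage"] * 17)
    t = _labeled_table(20, seed=5, labels=labels)
    with pytest.raises(ValueError, match="fewer than 5"):
        split_train_test(t)


# ------------------------------------------------------------------- forest


def test_training_rejects_single_class():
    t = _labeled_table(20, labels=np.array(["phage"] * 20))
    with pytest.raises(ValueError, match="single class"):
        train_forest(t, n_trees=10)


def test_gini_importances_sum_to_one(trained):
    model, _, _ = trained
    assert model.gini_importances.sum() == pytest.approx(1.0, abs=1e-9)


def test_separable_synthetic_data_learned_well(trained):
    from arcvir.pipeline import confusion_from_predictions
    from arcvir.benchmark import compute_metrics

    model, _, te = trained
    preds = predict(model, te, threshold=0.5)
    rep = compute_metrics(confusion_from_predictions(preds, te.labels.to_dict()))
    assert rep.f1 >= 0.95


def test_identical_seeds_give_identical_predictions():
    t = _labeled_table(60, seed=6)
    tr, te = split_train_test(t, seed=1)
    p1 = predict(train_forest(tr, n_trees=50, seed=7), te)
    p2 = predict(train_forest(tr, n_trees=50, seed=7), te)
    assert p1 == p2


# ---------------------------------------------------------------- prediction


def test_probability_is_tree_vote_fraction():
    """p_archaeal equals a manual per-tree vote count on a 5-tree forest."""
    t = _labeled_table(40, seed=8)
    model = train_forest(t, n_trees=5, seed=3, oob=False)
    X = t.data.to_numpy()
    manual = np.zeros(len(X))
    pos = list(model.forest.classes_).index("archaeal_virus")
    for est in model.forest.estimators_:
        manual += est.predict(X).astype(int) == pos
    manual /= 5
    got = vote_fractions(model, X)
    assert np.allclose(got, manual)
    assert set(np.round(got * 5)) <= {0, 1, 2, 3, 4, 5}  # multiples of 1/5


def test_class_complement_probabilities_sum_to_one(trained):
    model, _, te = trained
    p = vote_fractions(model, te.data[model.feature_names].to_numpy())
    assert np.all((0 <= p) & (p <= 1))  # phage fraction is 1 - p by construction


def test_threshold_zero_calls_everything_archaeal(trained):
    model, _, te = trained
    preds = predict(model, te, threshold=0.0)
    assert all(p.predicted_class == "archaeal_virus" for p in preds)


def test_threshold_monotonicity(trained):
    model, _, te = trained
    pos_08 = {p.contig_id for p in predict(model, te, 0.8) if p.predicted_class == "archaeal_virus"}
    pos_05 = {p.contig_id for p in predict(model, te, 0.5) if p.predicted_class == "archaeal_virus"}
    assert pos_08 <= pos_05


def test_predict_rejects_missing_feature(trained):
    model, _, te = trained
    crippled = FeatureTable(te.data.drop(columns=["ocav_hit_count"]), te.labels, te.catalog_version)
    with pytest.raises(ValueError, match="ocav_hit_count"):
        predict(model, crippled)


def test_predict_warns_on_extra_columns(trained):
    model, _, te = trained
    extra = te.data.copy()
    extra["bonus"] = 1.0
    with pytest.warns(UserWarning, match="bonus"):
        predict(model, FeatureTable(extra, te.labels, te.catalog_version))


def test_predict_refuses_catalog_mismatch(trained):
    model, _, te = trained
    other = FeatureTable(te.data.copy(), te.labels, catalog_version="other-catalog-v9")
    with pytest.raises(CatalogMismatchError):
        predict(model, other)


# ---------------------------------------------------------------------- RFE


def test_rfe_trace_shape_and_floor():
    t = _labeled_table(120, n_features=10, seed=9)
    trace = rfe_select(t, folds=5, min_features=5, seed=1, n_trees=30)
    assert len(trace.steps) == 6  # 10 -> 5, one drop per step
    assert all(len(s.features) >= 5 for s in trace.steps)
    assert all(0.0 <= s.mean_f1 <= 1.0 for s in trace.steps)
    assert len(trace.steps[-1].features) == 5 and trace.steps[-1].dropped_next is None


def test_rfe_keeps_planted_predictive_feature():
    t = _labeled_table(120, n_features=10, seed=10)  # f0 is perfectly separating
    trace = rfe_select(t, seed=2, n_trees=30)
    assert "f0" in trace.selected_features


def test_rfe_selection_never_materially_hurts():
    t = _labeled_table(150, n_features=8, seed=12)
    trace = rfe_select(t, seed=3, n_trees=40)
    assert trace.steps[trace.selected_index].mean_f1 >= trace.steps[0].mean_f1 - 0.02


# ----------------------------------------------------------------- proximity


def test_proximity_symmetric_unit_diagonal(trained):
    model, tr, _ = trained
    sub = tr.subset_rows(list(tr.data.index[:12]))
    prox = proximity_matrix(model, sub)
    assert np.allclose(prox, prox.T)
    assert np.allclose(np.diag(prox), 1.0)
    assert prox.min() >= 0 and prox.max() <= 1


def test_duplicated_row_has_unit_proximity(trained):
    model, tr, _ = trained
    ids = list(tr.data.index[:6])
    sub = tr.subset_rows(ids + [ids[0]])
    # duplicate index labels: use positional matrix instead
    data = tr.data.loc[ids + [ids[0]]].reset_index(drop=True)
    table = FeatureTable(data.set_axis([f"r{i}" for i in range(len(data))]), None, tr.catalog_version)
    prox = proximity_matrix(model, table)
    assert prox[0, -1] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_mislabeled_planted_row_is_flagged(seed):
    t = _labeled_table(30, seed=seed)
    labels = t.labels.copy()
    victim = labels.index[0]
    labels[victim] = "phage" if labels[victim] == "archaeal_virus" else "archaeal_virus"
    flipped = FeatureTable(t.data, labels, t.catalog_version)
    model = train_forest(t, n_trees=100, seed=seed)  # forest sees true structure
    report = proximity_outliers(model, flipped)
    assert victim in report.outliers


def test_proximity_needs_three_rows(trained):
    model, tr, _ = trained
    with pytest.raises(ValueError, match="3 rows"):
        proximity_outliers(model, tr.subset_rows(list(tr.data.index[:2])))


# --------------------------------------------------------------- persistence


def test_save_load_roundtrip_predictions(tmp_path, trained):
    model, _, te = trained
    path = tmp_path / "model.joblib"
    save_model(model, path)
    back = load_model(path)
    assert predict(back, te) == predict(model, te)
    assert back.seed == model.seed and back.n_trees == model.n_trees


def test_load_refuses_foreign_catalog(tmp_path, trained):
    model, _, _ = trained
    path = tmp_path / "model.joblib"
    save_model(model, path)
    with pytest.raises(CatalogMismatchError):
        load_model(path, require_catalog="someone-elses-catalog")
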