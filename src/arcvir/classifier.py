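"""Random-forest training, RFE by Gini importance, prediction, proximity.

The classifier is a scikit-learn random forest over the per-contig feature
table.  A contig's archaeal-virus probability is the fraction of trees whose
terminal leaf votes for the archaeal class (not the forest's averaged leaf
distribution), matching the vote-proportion reading of forest probabilities.
Training uses a stratified 70:30 split; recursive feature elimination drops
the lowest-mean-Gini feature per step down to a floor of five features, with
five-fold cross-validated F1 recorded at every step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .features import FeatureTable, LABELS

POSITIVE_LABEL = "archaeal_virus"
NEGATIVE_LABEL = "phage"
DEFAULT_N_TREES = 1000
DEFAULT_THRESHOLD = 0.80

_MODEL_FORMAT = "arcvir-model-1"


class CatalogMismatchError(ValueError):
    """Model and feature table were built under different feature catalogs."""


@dataclass
class RfeStep:
    features: tuple[str, ...]
    mean_f1: float
    fold_f1: tuple[float, ...]
    dropped_next: str | None  # feature removed to form the next step


@dataclass
class RfeTrace:
    steps: list[RfeStep]
    selected_index: int

    @property
    def selected_features(self) -> tuple[str, ...]:
        return self.steps[self.selected_index].features

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": [len(s.features) for s in self.steps],
                "mean_f1": [s.mean_f1 for s in self.steps],
                "dropped_next": [s.dropped_next for s in self.steps],
                "selected": [i == self.selected_index for i in range(len(self.steps))],
            }
        )


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    feature_names: list[str]
    catalog_version: str
    seed: int
    n_trees: int
    gini_importances: pd.Series = field(default_factory=pd.Series)
    split_record: dict = field(default_factory=dict)  # {"train": [...], "test": [...]}
    training_summary: dict = field(default_factory=dict)
    rfe_trace: RfeTrace | None = None


@dataclass(frozen=True)
class Prediction:
    contig_id: str
    p_archaeal: float
    predicted_class: str
    threshold_used: float


def split_train_test(
    table: FeatureTable, ratio: float = 0.7, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified split; train size = round(ratio * n); disjoint and exhaustive.

    Per-class quotas use the largest-remainder method so the total matches
    the rounded target exactly while staying as proportional as possible.
    """
    if table.labels is None:
        raise ValueError("split requires a labeled table")
    labels = table.labels
    counts = labels.value_counts()
    small = counts[counts < 5]
    if not small.empty:
        raise ValueError(
            f"classes with fewer than 5 members cannot be stratified for five-fold CV: {dict(small)}"
        )
    n_train = int(round(ratio * table.n))
    rng = np.random.default_rng(seed)
    quotas = {cls: ratio * cnt for cls, cnt in counts.items()}
    floors = {cls: int(np.floor(q)) for cls, q in quotas.items()}
    short = n_train - sum(floors.values())
    order = sorted(quotas, key=lambda c: (-(quotas[c] - floors[c]), str(c)))
    take = dict(floors)
    for cls in order[:short]:
        take[cls] += 1
    train_ids: list[str] = []
    for cls in sorted(counts.index):
        ids = list(labels.index[labels == cls])
        rng.shuffle(ids)
        k = min(take[cls], len(ids) - 1) if take[cls] >= len(ids) else take[cls]
        k = max(1, k)  # every class represented in both parts
        train_ids.extend(ids[:k])
    test_ids = [i for i in labels.index if i not in set(train_ids)]
    return table.subset_rows(train_ids), table.subset_rows(test_ids)


def _as_xy(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    if table.labels is None or table.labels.isna().any():
        raise ValueError("training requires labels for every row")
    return table.data.to_numpy(dtype=float), table.labels.to_numpy()


def _new_forest(n_trees: int, seed: int, oob: bool) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=oob, n_jobs=1, bootstrap=True
    )


def train_forest(
    train: FeatureTable, n_trees: int = DEFAULT_N_TREES, seed: int = 0, oob: bool = True
) -> TrainedModel:
    """Fit the forest on a labeled table; deterministic given the seed."""
    X, y = _as_xy(train)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(f"training data contains a single class {classes}; need both of {LABELS}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small forests: some rows never OOB
        forest = _new_forest(n_trees, seed, oob).fit(X, y)
    oob_score = float(getattr(forest, "oob_score_", np.nan)) if oob else None
    return TrainedModel(
        forest=forest,
        feature_names=train.feature_names,
        catalog_version=train.catalog_version,
        seed=seed,
        n_trees=n_trees,
        gini_importances=pd.Series(forest.feature_importances_, index=train.feature_names),
        training_summary={
            "class_counts": {c: int((y == c).sum()) for c in classes},
            "oob_score": oob_score,
            "n_rows": len(y),
        },
    )


def vote_fractions(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for the archaeal class, per row."""
    forest = model.forest
    pos = int(np.where(forest.classes_ == POSITIVE_LABEL)[0][0])
    votes = np.zeros(X.shape[0])
    for est in forest.estimators_:
        votes += est.predict(X).astype(int) == pos  # trees predict encoded class indices
    return votes / len(forest.estimators_)


def predict(
    model: TrainedModel, table: FeatureTable, threshold: float = DEFAULT_THRESHOLD
) -> list[Prediction]:
    """Per-contig archaeal-virus probability and thresholded class call.

    A contig is called archaeal when p_archaeal >= threshold (so at an exact
    tree-vote tie of 0.5 the archaeal call requires threshold <= 0.5).
    """
    if table.catalog_version != model.catalog_version:
        raise CatalogMismatchError(
            f"table catalog {table.catalog_version!r} != model catalog {model.catalog_version!r}"
        )
    missing = [f for f in model.feature_names if f not in table.data.columns]
    if missing:
        raise ValueError(f"feature table is missing model features: {missing}")
    extra = [c for c in table.data.columns if c not in model.feature_names]
    if extra:
        warnings.warn(f"ignoring extra feature columns: {extra}")
    X = table.data[model.feature_names].to_numpy(dtype=float)
    p = vote_fractions(model, X)
    return [
        Prediction(
            contig_id=cid,
            p_archaeal=float(pi),
            predicted_class=POSITIVE_LABEL if pi >= threshold else NEGATIVE_LABEL,
            threshold_used=threshold,
        )
        for cid, pi in zip(table.data.index, p)
    ]


def _cv_f1(table: FeatureTable, features: Sequence[str], folds: int, seed: int, n_trees: int) -> tuple[float, tuple[float, ...]]:
    X = table.data[list(features)].to_numpy(dtype=float)
    y = table.labels.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        f = _new_forest(n_trees, seed, oob=False).fit(X[tr], y[tr])
        scores.append(
            f1_score(y[te], f.predict(X[te]), pos_label=POSITIVE_LABEL, zero_division=0)
        )
    return float(np.mean(scores)), tuple(float(s) for s in scores)


def rfe_select(
    table: FeatureTable,
    folds: int = 5,
    min_features: int = 5,
    seed: int = 0,
    n_trees: int = 200,
) -> RfeTrace:
    """Recursive feature elimination by Gini importance.

    At each step the cross-validated F1 of the current feature set is
    recorded, a forest is refit on all rows, and the feature with the lowest
    Gini importance is dropped; never below ``min_features``.  The selected
    step maximises mean F1, ties resolved toward fewer features.
    """
    if table.labels is None:
        raise ValueError("RFE requires labels")
    features = list(table.feature_names)
    if len(features) < min_features:
        raise ValueError(f"need at least {min_features} features, got {len(features)}")
    X_full = table.data
    y = table.labels.to_numpy()
    steps: list[RfeStep] = []
    while True:
        mean_f1, fold_f1 = _cv_f1(table, features, folds, seed, n_trees)
        dropped = None
        if len(features) > min_features:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = _new_forest(n_trees, seed, oob=False).fit(
                    X_full[features].to_numpy(dtype=float), y
                )
            imp = pd.Series(f.feature_importances_, index=features)
            dropped = imp.sort_values(kind="stable").index[0]
        steps.append(RfeStep(tuple(features), mean_f1, fold_f1, dropped))
        if dropped is None:
            break
        features.remove(dropped)
    best = max(range(len(steps)), key=lambda i: (steps[i].mean_f1, -len(steps[i].features)))
    return RfeTrace(steps=steps, selected_index=best)


def proximity_matrix(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """prox(i, j) = fraction of trees in which rows i and j share a leaf."""
    X = table.data[model.feature_names].to_numpy(dtype=float)
    leaves = model.forest.apply(X)  # (n, n_trees)
    n = leaves.shape[0]
    prox = np.zeros((n, n))
    for t in range(leaves.shape[1]):
        col = leaves[:, t]
        prox += col[:, None] == col[None, :]
    return prox / leaves.shape[1]


@dataclass
class ProximityReport:
    matrix: np.ndarray
    linkage: np.ndarray
    cluster_of: pd.Series  # 2-cluster assignment per row id
    outliers: list[str]  # rows whose cluster majority label contradicts their own


def proximity_outliers(
    model: TrainedModel, table: FeatureTable, labels: Mapping[str, str] | None = None
) -> ProximityReport:
    """Flag rows whose proximity-based 2-cluster assignment contradicts their label.

    Average-linkage hierarchical clustering on 1 - proximity; each of the two
    clusters takes its majority label; a row disagreeing with its cluster's
    majority is an outlier (candidate mislabel / poorly covered sequence).
    """
    if labels is None:
        if table.labels is None:
            raise ValueError("proximity outlier detection needs labels")
        labels = table.labels.to_dict()
    ids = list(table.data.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 rows to cluster")
    prox = proximity_matrix(model, table)
    dist = 1.0 - prox
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=2, criterion="maxclust")
    cluster_of = pd.Series(assign, index=ids)
    outliers: list[str] = []
    for cl in sorted(set(assign)):
        members = [i for i, a in zip(ids, assign) if a == cl]
        lab = pd.Series([labels[m] for m in members])
        majority = lab.mode().iloc[0]
        outliers.extend(m for m in members if labels[m] != majority)
    return ProximityReport(matrix=prox, linkage=Z, cluster_of=cluster_of, outliers=sorted(outliers))


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the forest plus its feature catalog, seed, and RFE trace."""
    payload = {
        "format": _MODEL_FORMAT,
        "forest": model.forest,
        "feature_names": model.feature_names,
        "catalog_version": model.catalog_version,
        "seed": model.seed,
        "n_trees": model.n_trees,
        "gini_importances": model.gini_importances,
        "split_record": model.split_record,
        "training_summary": model.training_summary,
        "rfe_trace": model.rfe_trace,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path, require_catalog: str | None = None) -> TrainedModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a recognised model archive")
    if require_catalog is not None and payload["catalog_version"] != require_catalog:
        raise CatalogMismatchError(
            f"model catalog {payload['catalog_version']!r} != required {require_catalog!r}"
        )
    return TrainedModel(
        forest=payload["forest"],
        feature_names=payload["feature_names"],
        catalog_version=payload["catalog_version"],
        seed=payload["seed"],
        n_trees=payload["n_trees"],
        gini_importances=payload["gini_importances"],
        split_record=payload["split_record"],
        training_summary=payload["training_summary"],
        rfe_trace=payload["rfe_trace"],
    )
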