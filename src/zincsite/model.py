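"""Per-family Random-Forest training, hyper-parameter search and evaluation.

Protocol: the labelled dataset is split 20:80 test:train (stratified); all 48
hyper-parameter combinations (impurity gini/entropy x max depth 4/6/8/none x
10/100/1000 trees x sqrt/log2 features per split) are scored by mean F1 over
stratified 5-fold cross-validation of the training set; the best combination
(first in enumeration order on ties) is refit on the whole training set; and
the held-out test set yields recall, precision, F1 and Matthews Correlation
Coefficient.  Accuracy is deliberately never reported — the balanced 1:1
design makes it redundant and it misleads on any unbalanced variant.

One run seed governs the split, the folds, subsampling and the forests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterGrid, StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted, validate_data

from .datasets import LabeledDataset
from .families import FamilySignature
from .seqfeatures import sequence_feature_names
from .structfeatures import STRUCTURE_FEATURE_NAMES

MODEL_FORMAT = "zincsite-model"
MODEL_FORMAT_VERSION = "1"

#: The full hyper-parameter grid: 2 x 4 x 3 x 2 = 48 combinations.
DEFAULT_PARAM_GRID: dict[str, list] = {
    "criterion": ["gini", "entropy"],
    "max_depth": [4, 6, 8, None],
    "n_estimators": [10, 100, 1000],
    "max_features": ["sqrt", "log2"],
}


def expected_feature_names(family: FamilySignature, modality: str) -> list[str]:
    """The fixed feature schema for a family/modality pair."""
    if modality == "sequence":
        return sequence_feature_names(family)
    if modality == "structure":
        return list(STRUCTURE_FEATURE_NAMES)
    raise ValueError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# Metrics

@dataclass(frozen=True)
class EvalMetrics:
    """Confusion-matrix summary: recall, precision, F1 and MCC.

    ``degenerate`` flags any metric whose denominator was zero (reported
    as 0 by convention).
    """

    recall: float
    precision: float
    f1: float
    mcc: float
    tp: int
    tn: int
    fp: int
    fn: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "recall": self.recall, "precision": self.precision,
            "f1": self.f1, "mcc": self.mcc,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
        }


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> EvalMetrics:
    """Closed-form recall, precision, F1 and MCC from confusion counts.

    Zero denominators yield 0 for the affected metric, with the
    ``degenerate`` flag set.
    """
    for name, value in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("confusion counts sum to zero")
    degenerate = False

    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    else:
        mcc, degenerate = 0.0, True
    return EvalMetrics(
        recall=float(recall), precision=float(precision), f1=float(f1),
        mcc=float(mcc), tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
        degenerate=degenerate,
    )


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return compute_metrics(tp, tn, fp, fn)


# ---------------------------------------------------------------------------
# Core grid search (array level)

def _check_cv_feasible(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} rows; need >= {k} for {k}-fold CV"
        )


def _grid_search_arrays(
    X: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, list],
    k: int,
    seed: Optional[int],
) -> tuple[dict, pd.DataFrame]:
    """Mean-F1 k-fold scoring of every grid point; strict-argmax selection.

    Returns the chosen parameters and a table with one row per combination
    (in enumeration order) recording the per-fold and mean F1 scores.
    """
    _check_cv_feasible(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for _, test_idx in folds:
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("degenerate single-class CV fold")

    records = []
    best_params, best_score = None, -np.inf
    for params in ParameterGrid(dict(grid)):
        fold_scores = []
        for train_idx, test_idx in folds:
            forest = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
            forest.fit(X[train_idx], y[train_idx])
            pred = forest.predict(X[test_idx])
            fold_scores.append(metrics_from_predictions(y[test_idx], pred).f1)
        mean_f1 = float(np.mean(fold_scores))
        records.append({**params, "fold_f1": fold_scores, "mean_f1": mean_f1,
                        "n_folds": len(fold_scores)})
        if mean_f1 > best_score:  # strict: first best wins ties
            best_score, best_params = mean_f1, dict(params)
    return best_params, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Estimator

class ZincSiteClassifier(ClassifierMixin, BaseEstimator):
    """Random-Forest site classifier with built-in hyper-parameter search.

    ``fit`` runs the full protocol on already-featurized rows: stratified
    k-fold cross-validated grid search scored by F1, then a final refit of
    the winning forest on all rows.

    Parameters
    ----------
    family:
        Family name the model is for (metadata; e.g. ``"C2H2"``).
    modality:
        ``"sequence"`` or ``"structure"`` (metadata).
    param_grid:
        Mapping of RandomForest parameter lists; defaults to the 48-point
        grid in :data:`DEFAULT_PARAM_GRID`.
    cv:
        Number of stratified folds (default 5).
    random_state:
        Seed for folds and forests.

    Attributes
    ----------
    best_params_ : dict
        Winning hyper-parameter combination.
    cv_results_ : pandas.DataFrame
        One row per combination with per-fold and mean F1.
    estimator_ : RandomForestClassifier
        Final forest refit on all training rows.
    """

    def __init__(
        self,
        family: str = "C2H2",
        modality: str = "sequence",
        param_grid: Optional[Mapping[str, list]] = None,
        cv: int = 5,
        random_state: Optional[int] = None,
    ):
        self.family = family
        self.modality = modality
        self.param_grid = param_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        grid = self.param_grid if self.param_grid is not None else DEFAULT_PARAM_GRID
        self.classes_ = np.unique(y)
        self.best_params_, self.cv_results_ = _grid_search_arrays(
            X, y, grid, k=self.cv, seed=self.random_state
        )
        self.estimator_ = RandomForestClassifier(
            random_state=self.random_state, n_jobs=1, **self.best_params_
        ).fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.estimator_.predict_proba(X)


# ---------------------------------------------------------------------------
# Dataset-level protocol operations

def split_train_test(
    dataset: LabeledDataset,
    test_fraction: float = 0.2,
    seed: Optional[int] = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified, disjoint test:train split (default 20:80)."""
    if len(dataset) < 5:
        raise ValueError("dataset too small to split")
    indices = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        indices, test_size=test_fraction, stratify=dataset.y, random_state=seed
    )
    return dataset.subset(train_idx), dataset.subset(test_idx)


def grid_search(
    train: LabeledDataset,
    grid: Optional[Mapping[str, list]] = None,
    k: int = 5,
    seed: Optional[int] = None,
) -> tuple[dict, pd.DataFrame]:
    """Cross-validated grid search on a training dataset.

    Returns ``(best_params, cv_results)`` where ``cv_results`` has one row
    per explored combination, in fixed enumeration order.
    """
    grid = grid if grid is not None else DEFAULT_PARAM_GRID
    return _grid_search_arrays(
        train.X.to_numpy(dtype=float), train.y, grid, k=k, seed=seed
    )


@dataclass
class ModelBundle:
    """A trained per-family classifier plus everything needed to apply it."""

    family: str
    modality: str
    classifier: RandomForestClassifier
    hyper_parameters: dict
    feature_schema: list[str]
    provenance: dict = field(default_factory=dict)
    version: str = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        expected = expected_feature_names(FamilySignature.parse(self.family), self.modality)
        if list(self.feature_schema) != expected:
            raise ValueError(
                f"feature schema {self.feature_schema} does not match the "
                f"{self.family}/{self.modality} schema {expected}"
            )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(np.asarray(X, dtype=float))

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (binding) class, per row."""
        proba = self.classifier.predict_proba(np.asarray(X, dtype=float))
        pos_col = list(self.classifier.classes_).index(1)
        return proba[:, pos_col]

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format": MODEL_FORMAT,
            "version": self.version,
            "meta": {
                "family": self.family,
                "modality": self.modality,
                "hyper_parameters": self.hyper_parameters,
                "feature_schema": self.feature_schema,
                "provenance": self.provenance,
            },
            "classifier": self.classifier,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ModelBundle":
        payload = joblib.load(path)
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path} is not a zincsite model bundle")
        if payload.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"bundle version {payload.get('version')} unsupported "
                f"(expected {MODEL_FORMAT_VERSION})"
            )
        meta = payload["meta"]
        return cls(
            family=meta["family"],
            modality=meta["modality"],
            classifier=payload["classifier"],
            hyper_parameters=meta["hyper_parameters"],
            feature_schema=list(meta["feature_schema"]),
            provenance=meta.get("provenance", {}),
            version=payload["version"],
        )


def train_final(
    train: LabeledDataset,
    params: Mapping,
    seed: Optional[int] = None,
    provenance: Optional[dict] = None,
) -> ModelBundle:
    """Fit the chosen forest on the entire training set and bundle it."""
    schema = expected_feature_names(train.family, train.modality)
    if list(train.X.columns) != schema:
        raise ValueError(
            f"training columns {list(train.X.columns)} do not match schema {schema}"
        )
    forest = RandomForestClassifier(random_state=seed, n_jobs=1, **dict(params))
    forest.fit(train.X.to_numpy(dtype=float), train.y)
    prov = {
        "n_train": len(train),
        "n_positive": train.n_positive,
        "n_negative": train.n_negative,
        "seed": seed,
        "dataset_hash": joblib.hash((train.X.to_numpy().tobytes(), train.y.tobytes())),
    }
    if provenance:
        prov.update(provenance)
    return ModelBundle(
        family=train.family.canonical_name,
        modality=train.modality,
        classifier=forest,
        hyper_parameters=dict(params),
        feature_schema=schema,
        provenance=prov,
    )


def evaluate(bundle: ModelBundle, test: LabeledDataset) -> EvalMetrics:
    """Recall/precision/F1/MCC of a bundle on a held-out dataset."""
    if len(test) == 0:
        raise ValueError("empty test set")
    schema = expected_feature_names(test.family, test.modality)
    if list(test.X.columns) != schema or bundle.feature_schema != schema:
        raise ValueError("test set schema does not match the model bundle")
    pred = bundle.predict(test.X.to_numpy(dtype=float))
    return metrics_from_predictions(test.y, pred)


def train_pipeline(
    dataset: LabeledDataset,
    grid: Optional[Mapping[str, list]] = None,
    test_fraction: float = 0.2,
    k: int = 5,
    seed: Optional[int] = None,
) -> tuple[ModelBundle, EvalMetrics]:
    """Full protocol: split, grid-search, final refit, held-out evaluation."""
    train, test = split_train_test(dataset, test_fraction=test_fraction, seed=seed)
    best_params, cv_results = grid_search(train, grid=grid, k=k, seed=seed)
    bundle = train_final(
        train, best_params, seed=seed,
        provenance={"cv_mean_f1": float(cv_results["mean_f1"].max()),
                    "n_grid_points": int(len(cv_results))},
    )
    return bundle, evaluate(bundle, test)


def learning_curve(
    dataset: LabeledDataset,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    k: int = 5,
    seed: Optional[int] = None,
    params: Optional[Mapping] = None,
) -> list[tuple[int, float]]:
    """Mean cross-validated MCC at increasing stratified subsample sizes.

    ``params`` fixes the forest hyper-parameters across all points
    (default: 100 trees, gini, sqrt features, unlimited depth) so the curve
    isolates the effect of dataset size.
    """
    params = dict(params) if params is not None else {
        "n_estimators": 100, "criterion": "gini", "max_features": "sqrt",
        "max_depth": None,
    }
    X_all = dataset.X.to_numpy(dtype=float)
    y_all = dataset.y
    points = []
    for fraction in fractions:
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        if fraction < 1.0:
            idx, _ = train_test_split(
                np.arange(len(y_all)), train_size=fraction,
                stratify=y_all, random_state=seed,
            )
        else:
            idx = np.arange(len(y_all))
        X, y = X_all[idx], y_all[idx]
        _check_cv_feasible(y, k)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        mccs = []
        for train_idx, test_idx in skf.split(X, y):
            forest = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
            forest.fit(X[train_idx], y[train_idx])
            pred = forest.predict(X[test_idx])
            mccs.append(metrics_from_predictions(y[test_idx], pred).mcc)
        points.append((len(idx), float(np.mean(mccs))))
    return points
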