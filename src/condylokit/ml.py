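"""Multivariable resorption risk modelling.

The recipe: a stratified 70/30 split, SMOTE oversampling of the minority
(resorption) class on the training set only, feature selection by Boruta
(shadow-feature comparison against a random forest) or by a gradient
boosting total-gain threshold, and evaluation of random-forest and
gradient-boosted models with AUC, F1, accuracy, misclassification,
precision and recall on the untouched test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

__all__ = [
    "MLConfig",
    "ModelReport",
    "split_cohort",
    "smote",
    "boruta_select",
    "fit_and_evaluate",
    "rank_features",
    "run_risk_model",
]


@dataclass(frozen=True)
class MLConfig:
    split: float = 0.70
    smote_k: int = 5
    boruta_iterations: int = 20
    boruta_alpha: float = 0.05
    importance_threshold: float = 1.0  # gradient-boosting total gain
    n_estimators: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.split < 1.0:
            raise ValueError("split must be in (0, 1)")
        if self.boruta_iterations < 1:
            raise ValueError("boruta_iterations must be >= 1")


@dataclass
class ModelReport:
    model_kind: str
    auc: float | None
    f_score: float
    accuracy: float
    misclassification: float
    precision: float
    recall: float
    feature_importances: dict
    selected_features: list
    config: MLConfig = field(repr=False, default=MLConfig())


def split_cohort(features: pd.DataFrame, labels, config: MLConfig = MLConfig()):
    """Seeded stratified split into 70% training / 30% testing."""
    labels = np.asarray(labels).astype(int)
    if len(features) < 10:
        raise ValueError("need at least 10 records to split")
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    X_tr, X_te, y_tr, y_te = train_test_split(
        features,
        labels,
        train_size=config.split,
        stratify=labels,
        random_state=config.seed % (2**31),
    )
    if len(np.unique(y_tr)) < 2:
        raise ValueError("split left a class empty in the training set")
    return X_tr, X_te, y_tr, y_te


def smote(features: np.ndarray, labels: np.ndarray, config: MLConfig = MLConfig(), rng=None):
    """Synthetic minority oversampling to class parity.

    Each synthetic sample lies on the segment between a minority point and
    one of its k nearest minority neighbours: x + u (x_nn - x), u ~ U(0,1).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    rng = rng or np.random.default_rng(config.seed % (2**31))
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote expects a binary label")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return X.copy(), y.copy()
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise ValueError("minority class of size 1: no neighbour to interpolate toward")
    k = min(config.smote_k, len(Xm) - 1)
    tree = cKDTree(Xm)
    _, nn = tree.query(Xm, k=k + 1)  # first neighbour is the point itself
    nn = np.atleast_2d(nn)[:, 1:]
    base = rng.integers(0, len(Xm), size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    u = rng.random(n_needed)[:, None]
    neighbours = Xm[nn[base, pick]]
    synth = Xm[base] + u * (neighbours - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority)])
    return X_out, y_out


def boruta_select(
    features: pd.DataFrame | np.ndarray,
    labels,
    config: MLConfig = MLConfig(),
) -> dict:
    """All-relevant feature selection by shadow-feature comparison.

    Per iteration every feature gets a permuted shadow copy, a random
    forest is trained on the augmented matrix, and a feature scores a hit
    when its importance exceeds the maximum shadow importance. After the
    configured iterations a two-sided binomial test at ``boruta_alpha``
    splits features into confirmed / rejected / tentative.
    """
    X = pd.DataFrame(features)
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    if Xv.shape[1] < 2:
        raise ValueError("need at least 2 features")
    constant = [n for n, col in zip(names, Xv.T) if np.ptp(col) == 0]
    if constant:
        raise ValueError(f"degenerate constant features: {constant}")

    rng = np.random.default_rng(config.seed % (2**31))
    hits = np.zeros(Xv.shape[1], dtype=int)
    for it in range(config.boruta_iterations):
        shadow = np.column_stack([rng.permutation(col) for col in Xv.T])
        Xaug = np.hstack([Xv, shadow])
        forest = RandomForestClassifier(
            n_estimators=config.n_estimators,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(Xaug, y)
        imp = forest.feature_importances_
        real, sh = imp[: Xv.shape[1]], imp[Xv.shape[1]:]
        hits += (real > sh.max()).astype(int)

    confirmed, rejected, tentative = [], [], []
    n = config.boruta_iterations
    for name, h in zip(names, hits):
        p = binomtest(int(h), n, 0.5, alternative="two-sided").pvalue
        if p < config.boruta_alpha and h > n / 2:
            confirmed.append(name)
        elif p < config.boruta_alpha and h < n / 2:
            rejected.append(name)
        else:
            tentative.append(name)
    return {
        "confirmed": confirmed,
        "tentative": tentative,
        "rejected": rejected,
        "hits": dict(zip(names, hits.tolist())),
    }


def _make_model(model_kind: str, config: MLConfig, seed: int):
    if model_kind == "random_forest":
        return RandomForestClassifier(n_estimators=config.n_estimators, random_state=seed, n_jobs=1)
    if model_kind == "gradient_boosting":
        return XGBClassifier(
            n_estimators=config.n_estimators,
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
        )
    raise ValueError(f"unknown model kind {model_kind!r}")


def _importances(model, model_kind: str, names: list) -> dict:
    if model_kind == "random_forest":
        return dict(zip(names, model.feature_importances_.tolist()))
    score = model.get_booster().get_score(importance_type="total_gain")
    return {n: float(score.get(f"f{i}", 0.0)) for i, n in enumerate(names)}


def fit_and_evaluate(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    model_kind: str = "random_forest",
    config: MLConfig = MLConfig(),
    selected_features: list | None = None,
) -> ModelReport:
    """Train on the SMOTE-augmented training set, evaluate on the test set.

    The test set is never oversampled or used for selection. Probability
    threshold 0.5; AUC by the rank statistic; the F-score is the F1 of the
    resorption (positive) class. A single-class test set yields AUC None.
    """
    X_train = pd.DataFrame(X_train)
    X_test = pd.DataFrame(X_test)
    names = [str(c) for c in X_train.columns]
    if selected_features:
        names = [n for n in names if n in set(map(str, selected_features))]
        X_train = X_train[names]
        X_test = X_test[names]

    y_train = np.asarray(y_train).astype(int)
    y_test = np.asarray(y_test).astype(int)

    Xb, yb = smote(X_train.to_numpy(dtype=float), y_train, config)
    model = _make_model(model_kind, config, config.seed % (2**31))
    model.fit(Xb, yb)

    proba = model.predict_proba(X_test.to_numpy(dtype=float))[:, 1]
    pred = (proba >= 0.5).astype(int)
    auc = float(roc_auc_score(y_test, proba)) if len(np.unique(y_test)) == 2 else None
    acc = float(accuracy_score(y_test, pred))
    return ModelReport(
        model_kind=model_kind,
        auc=auc,
        f_score=float(f1_score(y_test, pred, zero_division=0)),
        accuracy=acc,
        misclassification=1.0 - acc,
        precision=float(precision_score(y_test, pred, zero_division=0)),
        recall=float(recall_score(y_test, pred, zero_division=0)),
        feature_importances=_importances(model, model_kind, names),
        selected_features=names,
        config=config,
    )


def rank_features(features: pd.DataFrame, labels, config: MLConfig = MLConfig()) -> list:
    """Features ordered by random-forest importance on SMOTE-balanced data."""
    X = pd.DataFrame(features)
    Xb, yb = smote(X.to_numpy(dtype=float), np.asarray(labels).astype(int), config)
    forest = RandomForestClassifier(
        n_estimators=config.n_estimators, random_state=config.seed % (2**31), n_jobs=1
    )
    forest.fit(Xb, yb)
    order = np.argsort(forest.feature_importances_)[::-1]
    return [str(X.columns[i]) for i in order]


def run_risk_model(
    features: pd.DataFrame,
    labels,
    model_kind: str = "random_forest",
    config: MLConfig = MLConfig(),
) -> ModelReport:
    """Full recipe: split, Boruta or gain-threshold selection, evaluation.

    Random forest selects the Boruta-confirmed (plus tentative) features;
    gradient boosting keeps features whose total gain in a preliminary fit
    reaches the importance threshold. Falls back to all features when the
    selection is empty.
    """
    X_tr, X_te, y_tr, y_te = split_cohort(pd.DataFrame(features), labels, config)

    if model_kind == "random_forest":
        decision = boruta_select(X_tr, y_tr, config)
        selected = decision["confirmed"] + decision["tentative"]
    else:
        prelim = fit_and_evaluate(X_tr, y_tr, X_te, y_te, "gradient_boosting", config)
        selected = [
            n for n, v in prelim.feature_importances.items() if v >= config.importance_threshold
        ]
    if not selected:
        selected = [str(c) for c in pd.DataFrame(features).columns]
    return fit_and_evaluate(X_tr, y_tr, X_te, y_te, model_kind, config, selected_features=selected)
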