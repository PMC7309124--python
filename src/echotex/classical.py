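"""Classical classifiers over the conventional texture features.

Four methods are compared, before and after relevant-feature selection:

* linear SVM (degree-1 polynomial kernel, min-max normalized inputs),
* multi-layer perceptron with an automatically searched hidden topology,
* random forest (100 trees),
* AdaBoost over entropy decision trees (100 boosting rounds).

The estimators themselves come from scikit-learn; this module pins the
hyperparameters, the MLP topology grid, the stratified 80/20 evaluation
protocol and the report layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import EvalReport, confusion_metrics, roc_auc
from .io_via import HCC

__all__ = ["ClassifierSpec", "TrainedModel", "make_spec", "fit", "predict_scores", "run_comparison", "CLASSIFIER_KINDS"]

CLASSIFIER_KINDS = ("svm_linear", "mlp", "random_forest", "adaboost_trees")


@dataclass
class ClassifierSpec:
    """Classifier kind plus its resolved hyperparameters and seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class TrainedModel:
    """A fitted estimator bound to the feature order used at fit time."""

    spec: ClassifierSpec
    estimator: object
    feature_names: list[str]
    classes: list


def mlp_hidden_grid(n_features: int, n_classes: int = 2) -> list[tuple[int, ...]]:
    """Hidden topologies searched for the MLP.

    {1, 2, 3 layers} x {a, a/2, a/3} nodes per layer, where
    ``a = (n_features + n_classes) // 2``.
    """
    a = (n_features + n_classes) // 2
    widths = sorted({max(1, a), max(1, a // 2), max(1, a // 3)}, reverse=True)
    return [tuple([wdt] * depth) for depth in (1, 2, 3) for wdt in widths]


def make_spec(kind: str, seed: int = 0, **overrides) -> ClassifierSpec:
    """Build a classifier spec with the pinned defaults of this study.

    svm_linear: degree-1 polynomial (i.e. linear) kernel, C = 1, min-max
    normalized inputs. random_forest: 100 trees. adaboost_trees: 100
    rounds over entropy trees. mlp: learning rate 0.2, momentum 0.8,
    500 epochs, topology grid searched at fit time.
    """
    defaults = {
        "svm_linear": {"C": 1.0, "degree": 1},
        "mlp": {"learning_rate": 0.2, "momentum": 0.8, "epochs": 500},
        "random_forest": {"n_estimators": 100},
        "adaboost_trees": {"n_estimators": 100, "ccp_alpha": 0.001, "min_samples_leaf": 2},
    }
    if kind not in defaults:
        raise ValueError(f"unknown classifier kind: {kind!r}")
    params = dict(defaults[kind])
    params.update(overrides)
    return ClassifierSpec(kind=kind, hyperparameters=params, seed=seed)


def _build_estimator(spec: ClassifierSpec, n_features: int):
    hp = spec.hyperparameters
    if spec.kind == "svm_linear":
        return Pipeline(
            [
                ("scale", MinMaxScaler()),
                (
                    "svm",
                    SVC(
                        kernel="poly",
                        degree=hp.get("degree", 1),
                        gamma=1.0,
                        coef0=0.0,
                        C=hp.get("C", 1.0),
                        probability=True,
                        random_state=spec.seed,
                    ),
                ),
            ]
        )
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=spec.seed
        )
    if spec.kind == "adaboost_trees":
        base = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=hp.get("min_samples_leaf", 2),
            ccp_alpha=hp.get("ccp_alpha", 0.001),
            random_state=spec.seed,
        )
        return AdaBoostClassifier(
            estimator=base,
            n_estimators=hp.get("n_estimators", 100),
            random_state=spec.seed,
        )
    if spec.kind == "mlp":
        # topology resolved in fit(); this builds one candidate
        hidden = hp.get("hidden_layer_sizes", (max(1, (n_features + 2) // 2),))
        return Pipeline(
            [
                ("scale", MinMaxScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=hidden,
                        solver="sgd",
                        learning_rate_init=hp.get("learning_rate", 0.2),
                        momentum=hp.get("momentum", 0.8),
                        max_iter=hp.get("epochs", 500),
                        random_state=spec.seed,
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown classifier kind: {spec.kind!r}")


def fit(spec: ClassifierSpec, X: pd.DataFrame, y: Sequence) -> TrainedModel:
    """Fit one classifier; deterministic given the spec's seed.

    The MLP fits every topology of the grid and keeps the one with the
    best accuracy on an internal 90/10 split of the training portion.
    """
    feature_names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite feature values")
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("single-class training data")

    if spec.kind == "mlp" and "hidden_layer_sizes" not in spec.hyperparameters:
        Xt, Xh, yt, yh = train_test_split(
            Xv, y, test_size=0.1, random_state=spec.seed, stratify=y
        )
        best = None
        import warnings as _warnings

        for hidden in mlp_hidden_grid(Xv.shape[1]):
            trial = ClassifierSpec(
                spec.kind, {**spec.hyperparameters, "hidden_layer_sizes": hidden}, spec.seed
            )
            est = _build_estimator(trial, Xv.shape[1])
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # convergence warnings on capped epochs
                est.fit(Xt, yt)
            acc = float(np.mean(est.predict(Xh) == yh))
            if best is None or acc > best[0]:
                best = (acc, hidden)
        spec = ClassifierSpec(
            spec.kind, {**spec.hyperparameters, "hidden_layer_sizes": best[1]}, spec.seed
        )

    est = _build_estimator(spec, Xv.shape[1])
    if spec.kind == "mlp":
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            est.fit(Xv, y)
    else:
        est.fit(Xv, y)
    classes = list(est.classes_ if hasattr(est, "classes_") else est[-1].classes_)
    return TrainedModel(spec=spec, estimator=est, feature_names=feature_names, classes=classes)


def predict_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Per-row class probabilities, columns ordered like ``model.classes``."""
    if list(X.columns) != model.feature_names:
        raise ValueError("feature columns do not match the fitted order")
    return model.estimator.predict_proba(X.to_numpy(dtype=float))


def _hcc_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    probs = predict_scores(model, X)
    col = model.classes.index(HCC) if HCC in model.classes else int(np.argmax(model.classes))
    return probs[:, col]


def evaluate_model(model: TrainedModel, X: pd.DataFrame, y: Sequence) -> EvalReport:
    """Confusion metrics + ROC/AUC of a fitted model on held-out rows."""
    scores = _hcc_scores(model, X)
    preds = np.where(scores > 0.5, HCC, "PAR")
    report = confusion_metrics(y, preds)
    report.roc, report.auc = roc_auc(y, scores)
    report.method = model.spec.kind
    return report


def run_comparison(
    features: pd.DataFrame,
    labels: Sequence,
    specs: Sequence[ClassifierSpec],
    selection: set[str] | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/evaluate every spec before and after feature selection.

    Stratified seeded ``(1 - test_fraction)/test_fraction`` split; returns
    one row per spec x {before, after} with accuracy, sensitivity,
    specificity and AUC (the after rows only when a selection is given).
    """
    y = np.asarray(labels)
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=test_fraction, random_state=seed, stratify=y
    )
    variants: list[tuple[str, pd.DataFrame]] = [("before", features)]
    if selection is not None:
        kept = [c for c in features.columns if c in selection]
        variants.append(("after", features.loc[:, kept]))

    rows = []
    for stage, table in variants:
        for spec in specs:
            model = fit(spec, table.iloc[idx_train], y[idx_train])
            report = evaluate_model(model, table.iloc[idx_test], y[idx_test])
            rows.append(
                {
                    "method": spec.kind,
                    "selection": stage,
                    "n_features": table.shape[1],
                    "accuracy": report.accuracy,
                    "sensitivity": report.sensitivity,
                    "specificity": report.specificity,
                    "auc": report.auc,
                }
            )
    return pd.DataFrame(rows)
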