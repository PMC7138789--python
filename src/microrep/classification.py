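"""Classifier grids, inner cross-validated selection, and test scoring.

Three classifier families are searched exhaustively:

* SVM — linear kernel × C ∈ {2⁻⁵, 2⁻³, …, 2⁵} plus RBF kernel × the same
  C × γ ∈ {2⁻¹³, 2⁻¹¹, …, 2³}: 60 combinations;
* RF — trees ∈ {100, 300, 500, 700, 900} × min leaf ∈ {1..5} ×
  {gini, entropy} × max_features ∈ {sqrt, log2}: 100 combinations;
* MLP — hidden layers ∈ {1, 2, 3} × epochs ∈ {30, 50, 100, 200, 300} ×
  first-layer units ∈ {10, 30, 50, 100} × dropout ∈ {0.1, 0.3}:
  120 combinations. Hidden widths halve after the first layer; a single
  sigmoid output unit gives the disease probability.

Selection is stratified 5-fold cross-validation on the (encoded)
training rows, scored by accuracy and averaged over folds; ties go to
the earlier grid entry. The chosen specification is refit on the whole
training set and scored on the test set by AUC, AUPRC, and accuracy.

RF grid search grows each forest incrementally through the tree-count
axis with scikit-learn's ``warm_start`` (trees are seeded sequentially
from ``random_state``, so the grown forest at each stop is identical to
a fresh fit of that size); this cuts grid cost ~2.8× with bit-equal
selections.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .classification_mlp import MLPClassifierNet, mlp_layer_schedule

__all__ = [
    "Algorithm",
    "ClassifierSpec",
    "CVSelection",
    "ClassificationError",
    "enumerate_classifier_grid",
    "mlp_layer_schedule",
    "cross_validate_select",
    "fit_and_score",
]

SVM_C_GRID = tuple(2.0**e for e in (-5, -3, -1, 1, 3, 5))
SVM_GAMMA_GRID = tuple(2.0**e for e in (-13, -11, -9, -7, -5, -3, -1, 1, 3))
RF_N_ESTIMATORS = (100, 300, 500, 700, 900)
RF_MIN_SAMPLES_LEAF = (1, 2, 3, 4, 5)
RF_CRITERIA = ("gini", "entropy")
RF_MAX_FEATURES = ("sqrt", "log2")
MLP_HIDDEN_LAYERS = (1, 2, 3)
MLP_EPOCHS = (30, 50, 100, 200, 300)
MLP_FIRST_UNITS = (10, 30, 50, 100)
MLP_DROPOUT = (0.1, 0.3)


class ClassificationError(ValueError):
    pass


class Algorithm(str, enum.Enum):
    SVM = "SVM"
    RF = "RF"
    MLP = "MLP"


@dataclass(frozen=True)
class ClassifierSpec:
    """One point of a classifier hyper-parameter grid."""

    algorithm: Algorithm
    hyper_parameters: tuple  # sorted (name, value) pairs

    def __post_init__(self):
        object.__setattr__(self, "algorithm", Algorithm(self.algorithm))
        hp = self.hyper_parameters
        if isinstance(hp, dict):
            hp = tuple(sorted(hp.items()))
        object.__setattr__(self, "hyper_parameters", tuple(hp))

    @property
    def params(self) -> dict:
        return dict(self.hyper_parameters)

    def to_text(self) -> str:
        inner = ";".join(f"{k}={v}" for k, v in self.hyper_parameters)
        return f"{self.algorithm.value}[{inner}]"


def enumerate_classifier_grid(algorithm) -> list[ClassifierSpec]:
    """The full grid for one algorithm: 60 SVM, 100 RF, 120 MLP specs."""
    algorithm = Algorithm(algorithm)
    grid: list[ClassifierSpec] = []
    if algorithm is Algorithm.SVM:
        for c in SVM_C_GRID:
            grid.append(ClassifierSpec(algorithm, {"kernel": "linear", "C": c}))
        for c in SVM_C_GRID:
            for gamma in SVM_GAMMA_GRID:
                grid.append(
                    ClassifierSpec(algorithm, {"kernel": "rbf", "C": c, "gamma": gamma})
                )
    elif algorithm is Algorithm.RF:
        for ne in RF_N_ESTIMATORS:
            for leaf in RF_MIN_SAMPLES_LEAF:
                for crit in RF_CRITERIA:
                    for mf in RF_MAX_FEATURES:
                        grid.append(
                            ClassifierSpec(
                                algorithm,
                                {
                                    "n_estimators": ne,
                                    "min_samples_leaf": leaf,
                                    "criterion": crit,
                                    "max_features": mf,
                                },
                            )
                        )
    else:
        for layers in MLP_HIDDEN_LAYERS:
            for epochs in MLP_EPOCHS:
                for units in MLP_FIRST_UNITS:
                    for rate in MLP_DROPOUT:
                        grid.append(
                            ClassifierSpec(
                                algorithm,
                                {
                                    "n_hidden_layers": layers,
                                    "epochs": epochs,
                                    "first_layer_units": units,
                                    "dropout": rate,
                                },
                            )
                        )
    return grid


@dataclass(frozen=True)
class CVSelection:
    """Outcome of grid selection by 5-fold cross-validated accuracy."""

    best_spec: ClassifierSpec
    mean_accuracy: float
    per_fold_accuracy: tuple
    grid_size: int


def _make_estimator(spec: ClassifierSpec, seed: int, n_features: int):
    p = spec.params
    if spec.algorithm is Algorithm.SVM:
        return SVC(random_state=seed, **p)
    if spec.algorithm is Algorithm.RF:
        return RandomForestClassifier(n_jobs=1, random_state=seed, **p)
    return MLPClassifierNet(
        n_features=n_features,
        first_layer_units=p["first_layer_units"],
        n_hidden_layers=p["n_hidden_layers"],
        dropout=p["dropout"],
        epochs=p["epochs"],
        seed=seed,
    )


def _check_cv_inputs(features, labels):
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != labels.shape[0]:
        raise ClassificationError("features and labels are not row-aligned")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 5:
        raise ClassificationError(
            f"need >= 5 samples per class for 5-fold CV, got counts {counts.tolist()}"
        )
    return features, labels


def cross_validate_select(
    features, labels, algorithm, seed: int, *, use_fast_rf: bool = True
) -> CVSelection:
    """Pick the grid spec maximizing mean 5-fold stratified CV accuracy.

    The fold partition is seeded and shared across the whole grid, so
    specs compete on identical folds. Ties are broken by grid order.
    """
    algorithm = Algorithm(algorithm)
    features, labels = _check_cv_inputs(features, labels)
    grid = enumerate_classifier_grid(algorithm)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    folds = list(skf.split(features, labels))

    if algorithm is Algorithm.RF and use_fast_rf:
        acc = _rf_grid_accuracies(features, labels, folds, grid, seed)
    else:
        acc = np.empty((len(grid), len(folds)))
        for i, spec in enumerate(grid):
            for j, (tr, te) in enumerate(folds):
                est = _make_estimator(spec, seed, features.shape[1])
                est.fit(features[tr], labels[tr])
                acc[i, j] = accuracy_score(labels[te], est.predict(features[te]))

    means = acc.mean(axis=1)
    best = int(np.argmax(means))  # argmax returns the first maximum: grid order
    return CVSelection(
        best_spec=grid[best],
        mean_accuracy=float(means[best]),
        per_fold_accuracy=tuple(float(a) for a in acc[best]),
        grid_size=len(grid),
    )


def _rf_grid_accuracies(features, labels, folds, grid, seed: int) -> np.ndarray:
    """RF grid accuracies via warm-start growth along the tree axis.

    For each (criterion, max_features, min_samples_leaf) combination and
    fold, one forest is grown through the n_estimators grid, scoring at
    every stop. scikit-learn derives each tree's seed sequentially from
    ``random_state``, so the forest at each stop is tree-identical to a
    fresh fit with that n_estimators.
    """
    index = {spec.hyper_parameters: i for i, spec in enumerate(grid)}
    acc = np.empty((len(grid), len(folds)))
    for crit in RF_CRITERIA:
        for mf in RF_MAX_FEATURES:
            for leaf in RF_MIN_SAMPLES_LEAF:
                for j, (tr, te) in enumerate(folds):
                    forest = RandomForestClassifier(
                        n_estimators=RF_N_ESTIMATORS[0],
                        criterion=crit,
                        max_features=mf,
                        min_samples_leaf=leaf,
                        warm_start=True,
                        n_jobs=1,
                        random_state=seed,
                    )
                    for ne in RF_N_ESTIMATORS:
                        forest.set_params(n_estimators=ne)
                        forest.fit(features[tr], labels[tr])
                        key = ClassifierSpec(
                            Algorithm.RF,
                            {
                                "n_estimators": ne,
                                "min_samples_leaf": leaf,
                                "criterion": crit,
                                "max_features": mf,
                            },
                        ).hyper_parameters
                        acc[index[key], j] = accuracy_score(
                            labels[te], forest.predict(features[te])
                        )
    return acc


def fit_and_score(
    train_features,
    train_labels,
    test_features,
    test_labels,
    spec: ClassifierSpec,
    seed: int,
):
    """Refit ``spec`` on all training rows and score the held-out test rows.

    Returns (auc, auprc, accuracy, scores) where ``scores`` are the
    continuous decision values: the signed margin for SVM, the
    positive-class probability for RF/MLP. Accuracy thresholds
    probabilities at 0.5 and margins at 0.
    """
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    train_labels = np.asarray(train_labels, dtype=int)
    test_labels = np.asarray(test_labels, dtype=int)
    if len(np.unique(test_labels)) < 2:
        raise ClassificationError("test labels contain a single class; AUC undefined")

    est = _make_estimator(spec, seed, train_features.shape[1])
    est.fit(train_features, train_labels)
    if spec.algorithm is Algorithm.SVM:
        scores = est.decision_function(test_features)
        predictions = (scores > 0).astype(int)
    else:
        scores = est.predict_proba(test_features)[:, 1]
        predictions = (scores > 0.5).astype(int)
    auc = float(roc_auc_score(test_labels, scores))
    auprc = float(average_precision_score(test_labels, scores))
    accuracy = float(accuracy_score(test_labels, predictions))
    return auc, auprc, accuracy, scores
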