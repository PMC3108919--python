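"""Comparison classifiers: polynomial-kernel SVMs, an MLP and a random forest.

These are thin adapters over scikit-learn estimators configured to mirror
the comparison study's settings: SMO-style SVMs with complexity 0.1,
tolerance 0.001 and polynomial kernels of degree 1, 2 or 3; a single
hidden-layer back-propagation perceptron with sigmoid activations, learning
rate 0.03, constant momentum 0.2, (attributes + classes)/2 hidden units and
500 epochs; and a 2500-tree random forest with one candidate attribute per
node — 2500 matching the GP inspection budget of 500 individuals times
5 generations.  Exact numerical equivalence with other toolkits is not
promised; options without a scikit-learn counterpart (kernel cache size,
round-off epsilon, a decaying momentum schedule) are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

METHODS = ("svm_poly1", "svm_poly2", "svm_poly3", "mlp", "random_forest")

_DEFAULTS = {
    "svm_poly1": {"C": 0.1, "degree": 1, "tol": 0.001},
    "svm_poly2": {"C": 0.1, "degree": 2, "tol": 0.001},
    "svm_poly3": {"C": 0.1, "degree": 3, "tol": 0.001},
    "mlp": {"learning_rate": 0.03, "momentum": 0.2, "epochs": 500},
    "random_forest": {"n_trees": 2500, "attributes_per_node": 1},
}


@dataclass
class ComparatorSpec:
    """A comparison method plus its hyperparameter table."""

    method: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        self.hyperparameters = {**_DEFAULTS[self.method], **self.hyperparameters}


def hidden_units(n_attributes: int, n_classes: int = 2) -> int:
    """Hidden-layer width rule: (number of attributes + number of classes) / 2."""
    return (n_attributes + n_classes) // 2


def train_comparator(spec: ComparatorSpec, X_train, y_train, seed: int = 0):
    """Fit the requested classifier; deterministic given *seed*.

    Raises on single-class training labels (no decision boundary exists).
    """
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    hp = spec.hyperparameters
    if spec.method.startswith("svm_poly"):
        # Weka-style homogeneous polynomial kernel (x . y)^d
        model = SVC(
            kernel="poly" if hp["degree"] > 1 else "linear",
            degree=hp["degree"],
            gamma=1.0,
            coef0=0.0,
            C=hp["C"],
            tol=hp["tol"],
            random_state=seed,
        )
    elif spec.method == "mlp":
        model = MLPClassifier(
            hidden_layer_sizes=(hidden_units(X_train.shape[1]),),
            activation="logistic",
            solver="sgd",
            learning_rate="constant",
            learning_rate_init=hp["learning_rate"],
            momentum=hp["momentum"],
            nesterovs_momentum=False,
            batch_size=1,  # per-instance (online) backprop updates
            max_iter=hp["epochs"],
            random_state=seed,
        )
    else:
        model = RandomForestClassifier(
            n_estimators=hp["n_trees"],
            max_features=hp["attributes_per_node"],
            random_state=seed,
            n_jobs=1,
        )
    with warnings.catch_warnings():
        # SGD often hits the epoch cap without meeting sklearn's tolerance;
        # a fixed epoch budget is the intended behaviour here
        warnings.simplefilter("ignore")
        model.fit(X_train, y_train)
    return model


def predict_comparator(model, X) -> np.ndarray:
    """Binary predictions; errors on a feature-count mismatch."""
    X = np.asarray(X)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"model trained on {model.n_features_in_} features, got {X.shape[1]}"
        )
    return np.asarray(model.predict(X), dtype=np.int8)
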