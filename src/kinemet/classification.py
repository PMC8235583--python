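"""Activity classification with one-against-all RBF-kernel SVMs.

Three binary support-vector machines (one per activity, RBF kernel) are
trained on standardised velocity features; a row is assigned the class
whose machine returns the largest signed decision value.  Exact ties are
broken by the fixed class order standing < walking < running, with a
logged warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "CLASS_ORDER",
    "INTENSITY",
    "ClassifierModel",
    "train_classifier",
    "classify",
    "classification_accuracy",
    "majority_vote",
]

logger = logging.getLogger(__name__)

#: Fixed class order: light, moderate, vigorous.
CLASS_ORDER: tuple[str, ...] = ("standing", "walking", "running")
INTENSITY: dict[str, str] = {"standing": "light", "walking": "moderate", "running": "vigorous"}


def _as_values(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    values = features.values if isinstance(features, FeatureMatrix) else np.atleast_2d(features)
    if not np.all(np.isfinite(values)):
        raise ValueError("features contain non-finite values")
    return np.asarray(values, dtype=float)


@dataclass
class ClassifierModel:
    """A trained one-vs-all activity classifier.

    Holds the standardisation statistics of the training features, one
    binary RBF machine per class in :data:`CLASS_ORDER`, and the
    hyperparameters used.
    """

    scaler: StandardScaler
    ovr: OneVsRestClassifier
    classes: tuple[str, ...]
    C: float
    gamma: float | str
    n_features: int

    def decision_values(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        """(n_rows, n_classes) signed decision values, columns in class order."""
        values = _as_values(features)
        if values.shape[1] != self.n_features:
            raise ValueError(
                f"classifier was trained on {self.n_features} features, got {values.shape[1]}"
            )
        scaled = self.scaler.transform(values)
        raw = self.ovr.decision_function(scaled)
        if raw.ndim == 1:  # two classes: one machine, signed towards classes_[1]
            raw = np.column_stack([-raw, raw])
        # reorder sklearn's sorted classes_ into the canonical class order
        order = [list(self.ovr.classes_).index(c) for c in self.classes]
        return raw[:, order]

    def predict(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        """Per-row activity labels: argmax of the decision values; exact
        ties resolve to the earlier class in :data:`CLASS_ORDER`."""
        dec = self.decision_values(features)
        best = dec.max(axis=1, keepdims=True)
        ties = (dec == best).sum(axis=1) > 1
        if np.any(ties):
            warnings.warn(
                f"{int(ties.sum())} exact decision-value tie(s) broken by class order",
                stacklevel=2,
            )
        return np.asarray(self.classes)[dec.argmax(axis=1)]

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Persist the model (joblib) next to a text manifest."""
        path = Path(path)
        joblib.dump(self, path)
        manifest = {
            "format": "kinemet.ClassifierModel.v1",
            "classes": list(self.classes),
            "C": self.C,
            "gamma": self.gamma,
            "n_features": self.n_features,
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
        }
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold a ClassifierModel")
        return model


def train_classifier(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
) -> ClassifierModel:
    """Fit the three one-vs-all RBF machines on standardised features.

    ``gamma="scale"`` is 1 / (n_features x feature variance), the usual RBF
    width default.  Training is deterministic for fixed data (the SMO
    solver draws no random numbers for these problem sizes; ``seed`` is
    accepted for interface symmetry).
    """
    values = _as_values(features)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must have equal length")
    present = [c for c in CLASS_ORDER if c in set(labels)]
    unknown = set(labels) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown activity label(s): {sorted(unknown)}")
    if len(present) < 2:
        raise ValueError("training needs at least 2 distinct activity classes")
    scaler = StandardScaler().fit(values)
    ovr = OneVsRestClassifier(SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed))
    ovr.fit(scaler.transform(values), labels)
    logger.info(
        "trained one-vs-all RBF SVM on %d rows, %d features, classes=%s",
        values.shape[0],
        values.shape[1],
        present,
    )
    return ClassifierModel(
        scaler=scaler,
        ovr=ovr,
        classes=tuple(present),
        C=C,
        gamma=gamma,
        n_features=values.shape[1],
    )


def classify(model: ClassifierModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-row activity labels (see :meth:`ClassifierModel.predict`)."""
    return model.predict(features)


def classification_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of rows whose predicted label matches the truth."""
    predicted, truth = np.asarray(predicted), np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("cannot compute accuracy of zero rows")
    return float(np.mean(predicted == truth))


def majority_vote(labels: np.ndarray) -> str:
    """Bout-level label: the most frequent per-row label (ties resolve to
    the earlier class in :data:`CLASS_ORDER`)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot vote over zero labels")
    uniq, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    winners = set(uniq[counts == best])
    for c in CLASS_ORDER:
        if c in winners:
            return c
    return str(uniq[counts.argmax()])
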