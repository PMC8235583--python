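"""MET regression models and activity-specific routing.

Three regressor families estimate per-frame energy expenditure (MET) from
velocity features:

* **LR** — ordinary least squares with intercept, the linear baseline;
* **MLP** — a feed-forward network with three logistic hidden layers
  (default 70 nodes each, the width a node sweep selects);
* **CNN** — a 1-D conv-net over the 18-wide velocity vector (two length-3
  convolution layers with ReLU, two max-pools, a 2 x 16-unit dense head).

A :class:`ModelRegistry` holds one general model per camera view and one
model per activity per view, plus a routing table that sends each
classified activity to its best (view, family) pair; the default routing —
CNN for standing (rear view), CNN for walking (side view), MLP for running
(rear view) — reflects the per-activity optima of the evaluation grid.
Predictions convert to kilocalories via 1 MET = 1 kcal / kg / h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from ._cnn import CNNRegressor
from .classification import CLASS_ORDER, ClassifierModel
from .features import FeatureMatrix

__all__ = [
    "EEModel",
    "ModelRegistry",
    "DEFAULT_ROUTING",
    "train_lr",
    "train_mlp",
    "train_cnn",
    "sweep_mlp_nodes",
    "predict_met",
    "hierarchical_predict",
    "met_to_kcal",
]

FAMILIES = ("lr", "mlp", "cnn")

#: activity -> (view, family): per-activity optima of the evaluation grid.
DEFAULT_ROUTING: dict[str, tuple[str, str]] = {
    "standing": ("rear", "cnn"),
    "walking": ("side", "cnn"),
    "running": ("rear", "mlp"),
}


def _as_values(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    values = features.values if isinstance(features, FeatureMatrix) else np.atleast_2d(features)
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("features contain non-finite values")
    return values


def _check_targets(values: np.ndarray, targets) -> np.ndarray:
    y = np.asarray(targets, dtype=float).ravel()
    if y.shape[0] != values.shape[0]:
        raise ValueError("features and MET targets must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("MET targets contain non-finite values")
    return y


@dataclass
class EEModel:
    """A trained MET regressor with its architecture descriptor.

    ``scaler`` holds training-feature standardisation statistics (``None``
    for the LR family, which is scale-equivariant); ``architecture`` is a
    plain-text descriptor of the fitted network.
    """

    family: str
    estimator: object
    scaler: StandardScaler | None
    input_dim: int
    architecture: str
    seed: int | None = None
    metadata: dict = field(default_factory=dict)
    #: zero-pad inputs up to this width before scaling (CNN on reduced inputs)
    pad_to: int | None = None

    def predict(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        values = _as_values(features)
        if values.shape[1] != self.input_dim:
            raise ValueError(
                f"{self.family} model expects {self.input_dim} features, got {values.shape[1]}"
            )
        if self.pad_to is not None and values.shape[1] < self.pad_to:
            values = np.pad(values, ((0, 0), (0, self.pad_to - values.shape[1])))
        if self.scaler is not None:
            values = self.scaler.transform(values)
        pred = np.asarray(self.estimator.predict(values), dtype=float).ravel()
        if not np.all(np.isfinite(pred)):
            raise RuntimeError("model produced non-finite MET predictions")
        return pred

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self, path)
        manifest = {
            "format": "kinemet.EEModel.v1",
            "family": self.family,
            "architecture": self.architecture,
            "input_dim": self.input_dim,
            "seed": self.seed,
            **{k: v for k, v in self.metadata.items() if isinstance(v, (str, int, float))},
        }
        path.with_suffix(path.suffix + ".manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EEModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold an EEModel")
        return model


class _Rescaled:
    """Wraps a regressor trained on standardised targets; maps its output
    back to MET units."""

    def __init__(self, net, mean, sd):
        self.net, self.mean, self.sd = net, mean, sd

    def predict(self, X):
        return self.net.predict(X) * self.sd + self.mean


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_lr(features: FeatureMatrix | np.ndarray, met_targets) -> EEModel:
    """Ordinary-least-squares MET regression with intercept.

    Deterministic; rank-deficient designs fall back to the minimum-norm
    pseudo-inverse solution (the LAPACK least-squares driver), which is
    recorded in the metadata rather than raised.
    """
    values = _as_values(features)
    y = _check_targets(values, met_targets)
    if values.shape[0] < values.shape[1] + 1:
        raise ValueError(
            f"OLS with intercept needs at least {values.shape[1] + 1} rows, got {values.shape[0]}"
        )
    est = LinearRegression().fit(values, y)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(values)), values]))
    return EEModel(
        family="lr",
        estimator=est,
        scaler=None,
        input_dim=values.shape[1],
        architecture=f"OLS({values.shape[1]} features + intercept)",
        metadata={"full_rank": bool(rank == values.shape[1] + 1)},
    )


def train_mlp(
    features: FeatureMatrix | np.ndarray,
    met_targets,
    n_nodes: int = 70,
    seed: int = 0,
    epochs: int = 200,
    learning_rate: float = 1e-3,
    early_stopping: bool = True,
) -> EEModel:
    """Three logistic hidden layers of ``n_nodes`` units, linear output.

    Adam optimisation on standardised features with an internal 10%
    validation split for early stopping; reproducible per seed.  Targets
    are standardised internally (logistic nets optimise poorly against
    raw multi-MET scales) and predictions mapped back to MET units.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be at least 1")
    values = _as_values(features)
    y = _check_targets(values, met_targets)
    scaler = StandardScaler().fit(values)
    y_mean, y_sd = float(y.mean()), float(y.std())
    y_sd = y_sd if y_sd > 0 else 1.0
    est = MLPRegressor(
        hidden_layer_sizes=(n_nodes,) * 3,
        activation="logistic",
        solver="adam",
        learning_rate_init=learning_rate,
        max_iter=epochs,
        early_stopping=early_stopping,
        validation_fraction=0.1,
        n_iter_no_change=20,
        random_state=seed,
    )
    est.fit(scaler.transform(values), (y - y_mean) / y_sd)
    return EEModel(
        family="mlp",
        estimator=_Rescaled(est, y_mean, y_sd),
        scaler=scaler,
        input_dim=values.shape[1],
        architecture=f"MLP({values.shape[1]}-{n_nodes}-{n_nodes}-{n_nodes}-1, logistic)",
        seed=seed,
        metadata={"n_nodes": n_nodes, "epochs": epochs, "n_iter": est.n_iter_},
    )


def train_cnn(
    features: FeatureMatrix | np.ndarray,
    met_targets,
    seed: int = 0,
    epochs: int = 200,
    filters: tuple[int, int] = (16, 32),
    dense_units: int = 16,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    pad_to_width: bool = False,
) -> EEModel:
    """1-D conv-net over the 18-wide velocity vector.

    The network requires the full 18 features; narrower (e.g. PCA-reduced)
    inputs are rejected unless ``pad_to_width=True`` explicitly requests
    zero-padding up to 18.  Targets are standardised internally for stable
    optimisation and predictions mapped back to MET units.
    """
    values = _as_values(features)
    native_dim = values.shape[1]
    if native_dim != 18:
        if not pad_to_width or native_dim > 18:
            raise ValueError(
                f"the convolutional model takes exactly 18 input features, got "
                f"{native_dim} (pass pad_to_width=True to zero-pad reduced inputs)"
            )
        values = np.pad(values, ((0, 0), (0, 18 - native_dim)))
    y = _check_targets(values, met_targets)
    scaler = StandardScaler().fit(values)
    y_mean, y_sd = float(y.mean()), float(y.std())
    y_sd = y_sd if y_sd > 0 else 1.0
    net = CNNRegressor(
        input_width=18,
        filters=filters,
        dense_units=dense_units,
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        seed=seed,
    )
    net.fit(scaler.transform(values), (y - y_mean) / y_sd)
    return EEModel(
        family="cnn",
        estimator=_Rescaled(net, y_mean, y_sd),
        scaler=scaler,
        input_dim=native_dim,
        pad_to=18 if native_dim != 18 else None,
        architecture=(
            f"CNN(18x1 -> conv3x{filters[0]} relu -> pool2 -> conv3x{filters[1]} relu "
            f"-> pool2 -> dense {dense_units}x2 relu -> 1)"
        ),
        seed=seed,
        metadata={"epochs": epochs, "n_iter": net.n_iter_},
    )


def sweep_mlp_nodes(
    features: FeatureMatrix | np.ndarray,
    met_targets,
    candidates: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90),
    seed: int = 0,
    epochs: int = 200,
    validation_fraction: float = 0.2,
) -> tuple[int, pd.DataFrame]:
    """Validation-MSE sweep over hidden-layer widths.

    Splits off a validation set, trains one MLP per candidate width, and
    returns the argmin width (ties resolve to the smaller width) together
    with the full width/MSE table for plotting.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list must be non-empty")
    values = _as_values(features)
    y = _check_targets(values, met_targets)
    Xtr, Xval, ytr, yval = train_test_split(
        values, y, test_size=validation_fraction, random_state=seed
    )
    rows = []
    for n_nodes in candidates:
        model = train_mlp(Xtr, ytr, n_nodes=n_nodes, seed=seed, epochs=epochs)
        mse = float(np.mean((model.predict(Xval) - yval) ** 2))
        rows.append({"n_nodes": n_nodes, "val_mse": mse})
    table = pd.DataFrame(rows)
    best_n = int(table.loc[table["val_mse"].idxmin(), "n_nodes"])
    return best_n, table


_TRAINERS = {"lr": train_lr, "mlp": train_mlp, "cnn": train_cnn}


def train_family(family: str, features, met_targets, **kwargs) -> EEModel:
    """Dispatch to :func:`train_lr` / :func:`train_mlp` / :func:`train_cnn`."""
    if family not in _TRAINERS:
        raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
    if family == "lr":
        kwargs.pop("seed", None)
    return _TRAINERS[family](features, met_targets, **kwargs)


def predict_met(model: EEModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Per-row MET estimate from a trained model."""
    return model.predict(features)


# ---------------------------------------------------------------------------
# registry and hierarchical routing
# ---------------------------------------------------------------------------


@dataclass
class ModelRegistry:
    """General and per-activity MET models indexed by camera view.

    ``general[view]`` is a model trained on all activities from that view;
    ``per_activity[(activity, view)]`` is trained on one activity only.
    ``routing`` sends each classified activity to the (view, family) whose
    per-activity model scores it.
    """

    general: dict[str, EEModel] = field(default_factory=dict)
    per_activity: dict[tuple[str, str], EEModel] = field(default_factory=dict)
    routing: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(DEFAULT_ROUTING))

    def routed_model(self, activity: str) -> tuple[EEModel, str]:
        if activity not in self.routing:
            raise KeyError(f"no routing entry for activity {activity!r}")
        view, family = self.routing[activity]
        key = (activity, view)
        if key not in self.per_activity:
            raise KeyError(f"registry holds no model for activity={activity!r}, view={view!r}")
        model = self.per_activity[key]
        if model.family != family:
            raise KeyError(
                f"routing expects a {family} model for {activity!r}/{view!r}, "
                f"registry holds {model.family}"
            )
        return model, view

    def validate(self) -> None:
        missing = [a for a in self.routing if (a, self.routing[a][0]) not in self.per_activity]
        if missing:
            raise KeyError(f"routing references missing models for: {missing}")


def hierarchical_predict(
    registry: ModelRegistry,
    classifier: ClassifierModel,
    per_view_features: dict[str, FeatureMatrix | np.ndarray],
    classifier_view: str = "side",
) -> tuple[np.ndarray, np.ndarray]:
    """Classify-then-route MET estimation.

    Every row is first classified from ``classifier_view`` features, then
    scored by the model the routing table assigns to its predicted
    activity, using that model's own view's features.  Returns the per-row
    MET estimates and the per-row predicted labels.
    """
    if classifier_view not in per_view_features:
        raise KeyError(f"classifier view {classifier_view!r} missing from per_view_features")
    needed_views = {view for view, _family in registry.routing.values()}
    missing = needed_views - set(per_view_features)
    if missing:
        raise KeyError(f"routing needs features for view(s) {sorted(missing)}")

    values_by_view = {v: _as_values(f) for v, f in per_view_features.items()}
    n = values_by_view[classifier_view].shape[0]
    for view, vals in values_by_view.items():
        if vals.shape[0] != n:
            raise ValueError(f"view {view!r} has {vals.shape[0]} rows, expected {n}")

    labels = classifier.predict(per_view_features[classifier_view])
    met = np.empty(n)
    for activity in CLASS_ORDER:
        mask = labels == activity
        if not np.any(mask):
            continue
        model, view = registry.routed_model(activity)
        met[mask] = model.predict(values_by_view[view][mask])
    return met, labels


def met_to_kcal(met_value: float, weight: float, duration: float) -> float:
    """Energy in kcal: MET x body mass (kg) x duration (h).

    Follows directly from the MET unit (1 MET = 1 kcal per kg per hour);
    bilinear in weight and duration.
    """
    if met_value < 0 or weight < 0 or duration < 0:
        raise ValueError("met_value, weight and duration must be non-negative")
    return float(met_value * weight * duration)
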