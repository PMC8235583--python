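"""Model/Results front-end for MET estimation.

`EnergyExpenditureModel` bundles the velocity features, MET targets and
(optionally) activity labels of one dataset and exposes ``fit()`` in the
style of statistical modelling packages: the returned
:class:`EnergyExpenditureResults` carries the trained estimator(s),
in-sample and cross-validated error metrics, and a ``summary()`` table.

Two strategies are supported: a *general* model of one family trained on
all rows, or a *hierarchical* classify-then-route model that trains one
one-vs-all SVM activity classifier plus one regressor per activity and
dispatches each row through its predicted activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import CLASS_ORDER, ClassifierModel, train_classifier
from .estimation import EEModel, ModelRegistry, hierarchical_predict, train_family
from .features import FeatureMatrix
from .harness import kfold_cv
from .metrics import MetricsReport

__all__ = ["EnergyExpenditureModel", "EnergyExpenditureResults"]


class EnergyExpenditureModel:
    """MET regression on velocity features.

    Parameters
    ----------
    features : (n, p) array or :class:`FeatureMatrix` of joint velocities.
    met : (n,) ground-truth MET values.
    activity : optional (n,) activity labels; required for the
        hierarchical strategy.
    family : "lr" | "mlp" | "cnn" — regressor family (for the hierarchical
        strategy, the family used for every activity unless ``routing_families``
        overrides it).
    strategy : "general" or "hierarchical".
    **train_kwargs : forwarded to the family trainer (e.g. ``n_nodes``).
    """

    def __init__(
        self,
        features: FeatureMatrix | np.ndarray,
        met,
        activity=None,
        family: str = "mlp",
        strategy: str = "general",
        routing_families: dict[str, str] | None = None,
        **train_kwargs,
    ) -> None:
        self.X = features.values if isinstance(features, FeatureMatrix) else np.atleast_2d(
            np.asarray(features, dtype=float)
        )
        self.met = np.asarray(met, dtype=float).ravel()
        if self.met.shape[0] != self.X.shape[0]:
            raise ValueError("features and met must have equal length")
        self.activity = None if activity is None else np.asarray(activity)
        if strategy not in ("general", "hierarchical"):
            raise ValueError("strategy must be 'general' or 'hierarchical'")
        if strategy == "hierarchical" and self.activity is None:
            raise ValueError("the hierarchical strategy needs activity labels")
        self.family = family
        self.strategy = strategy
        self.routing_families = routing_families or {}
        self.train_kwargs = train_kwargs

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        met_col: str = "met",
        activity_col: str | None = "activity",
        feature_cols: list[str] | None = None,
        **kwargs,
    ) -> "EnergyExpenditureModel":
        """Build a model from a tidy frame of feature columns + targets."""
        if met_col not in df.columns:
            raise KeyError(f"dataframe lacks the target column {met_col!r}")
        activity = None
        if activity_col is not None and activity_col in df.columns:
            activity = df[activity_col].to_numpy()
        if feature_cols is None:
            drop = {met_col, activity_col, "timestamp_s", "subject", "view"}
            feature_cols = [c for c in df.columns if c not in drop]
        return cls(df[feature_cols].to_numpy(float), df[met_col].to_numpy(float), activity, **kwargs)

    def fit(self, seed: int = 0, cv_folds: int | None = None) -> "EnergyExpenditureResults":
        """Train the model; optionally also run k-fold CV for the summary."""
        seed_kw = {} if self.family == "lr" else {"seed": seed}
        if self.strategy == "general":
            estimator = train_family(self.family, self.X, self.met, **self.train_kwargs, **seed_kw)
            classifier = None
            registry = None
        else:
            classifier = train_classifier(self.X, self.activity, seed=seed)
            registry = ModelRegistry(routing={})
            for act in (a for a in CLASS_ORDER if a in set(self.activity)):
                fam = self.routing_families.get(act, self.family)
                mask = self.activity == act
                fam_seed = {} if fam == "lr" else {"seed": seed}
                registry.per_activity[(act, "default")] = train_family(
                    fam, self.X[mask], self.met[mask], **self.train_kwargs, **fam_seed
                )
                registry.routing[act] = ("default", fam)
            estimator = None

        cv_report = None
        if cv_folds is not None and self.strategy == "general":
            cv_report = kfold_cv(
                self.X,
                self.met,
                family=self.family,
                k=cv_folds,
                seed=seed,
                stratify=self.activity,
                train_kwargs=self.train_kwargs,
            )

        results = EnergyExpenditureResults(
            model=self,
            estimator=estimator,
            classifier=classifier,
            registry=registry,
            seed=seed,
            cv_report=cv_report,
        )
        results._score_in_sample()
        return results


@dataclass
class EnergyExpenditureResults:
    """Fitted MET model: estimates, errors, diagnostics."""

    model: EnergyExpenditureModel
    estimator: EEModel | None
    classifier: ClassifierModel | None
    registry: ModelRegistry | None
    seed: int
    cv_report: MetricsReport | None = None
    fittedvalues: np.ndarray = field(default=None, repr=False)
    in_sample: MetricsReport | None = None

    def predict(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        """Per-row MET estimates for new feature rows."""
        if self.estimator is not None:
            return self.estimator.predict(features)
        values = features.values if isinstance(features, FeatureMatrix) else np.atleast_2d(
            np.asarray(features, dtype=float)
        )
        met, _ = hierarchical_predict(
            self.registry, self.classifier, {"default": values}, classifier_view="default"
        )
        return met

    def _score_in_sample(self) -> None:
        self.fittedvalues = self.predict(self.model.X)
        self.in_sample = MetricsReport.from_predictions(self.fittedvalues, self.model.met)

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self.model.met

    @property
    def mae(self) -> float:
        return self.in_sample.mae

    @property
    def mse(self) -> float:
        return self.in_sample.mse

    @property
    def rmse(self) -> float:
        return self.in_sample.rmse

    def summary(self) -> str:
        """Plain-text summary in the style of statistical model results."""
        m = self.model
        lines = [
            "        Energy Expenditure Regression Results",
            "=" * 56,
            f"Strategy:        {m.strategy:<12}  Rows:      {m.X.shape[0]}",
            f"Family:          {m.family:<12}  Features:  {m.X.shape[1]}",
            f"Seed:            {self.seed}",
        ]
        if self.estimator is not None:
            lines.append(f"Architecture:    {self.estimator.architecture}")
        if self.registry is not None:
            routed = ", ".join(
                f"{a}->{fam}" for a, (_v, fam) in sorted(self.registry.routing.items())
            )
            lines.append(f"Routing:         {routed}")
        lines += [
            "-" * 56,
            "In-sample errors (MET):",
            f"  MAE  {self.mae:8.4f}    MSE  {self.mse:8.4f}    RMSE  {self.rmse:8.4f}",
        ]
        if self.cv_report is not None:
            lines += [
                "Cross-validated errors (MET):",
                f"  MAE  {self.cv_report.mae:8.4f}    MSE  {self.cv_report.mse:8.4f}"
                f"    RMSE  {self.cv_report.rmse:8.4f}",
            ]
        lines.append("=" * 56)
        return "\n".join(lines)
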