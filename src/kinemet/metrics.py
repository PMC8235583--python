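"""Error metrics for MET estimation: MAE, MSE and RMSE.

For estimates Y-hat and calorimeter ground truth Y over N rows:
MAE = mean |Y-hat - Y| (MET), MSE = mean (Y-hat - Y)^2 (MET^2),
RMSE = sqrt(MSE) (MET).  Every report checks the identities
RMSE = sqrt(MSE) and MAE <= RMSE (Jensen) on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["mae", "mse", "rmse", "MetricsReport"]


def _residuals(predicted, truth) -> np.ndarray:
    predicted = np.asarray(predicted, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if predicted.shape != truth.shape:
        raise ValueError(
            f"predicted ({predicted.shape[0]}) and truth ({truth.shape[0]}) differ in length"
        )
    if predicted.size == 0:
        raise ValueError("cannot compute a metric over zero rows")
    return predicted - truth


def mae(predicted, truth) -> float:
    """Mean absolute error in MET."""
    return float(np.mean(np.abs(_residuals(predicted, truth))))


def mse(predicted, truth) -> float:
    """Mean squared error in MET^2."""
    return float(np.mean(_residuals(predicted, truth) ** 2))


def rmse(predicted, truth) -> float:
    """Root mean squared error in MET."""
    return float(np.sqrt(mse(predicted, truth)))


@dataclass
class MetricsReport:
    """MAE/MSE/RMSE for one evaluation cell.

    ``keys`` identifies the cell (view, model family, activity or
    "general", PCA flag, ...); ``n`` is the number of scored rows.
    """

    mae: float
    mse: float
    rmse: float
    n: int
    keys: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.mae, self.mse, self.rmse) < 0:
            raise ValueError("metrics must be non-negative")
        if not np.isclose(self.rmse, np.sqrt(self.mse), rtol=1e-9, atol=1e-12):
            raise ValueError(f"RMSE {self.rmse} is not sqrt(MSE {self.mse})")
        if self.mae > self.rmse * (1 + 1e-9) + 1e-12:
            raise ValueError(f"MAE {self.mae} exceeds RMSE {self.rmse}")

    @classmethod
    def from_predictions(cls, predicted, truth, **keys) -> "MetricsReport":
        m = mse(predicted, truth)
        return cls(
            mae=mae(predicted, truth),
            mse=m,
            rmse=float(np.sqrt(m)),
            n=int(np.asarray(predicted).ravel().shape[0]),
            keys=keys,
        )

    @classmethod
    def average(cls, reports: list["MetricsReport"], **keys) -> "MetricsReport":
        """Unweighted mean over folds; RMSE is recomputed from the averaged
        MSE so the sqrt identity keeps holding."""
        if not reports:
            raise ValueError("cannot average zero reports")
        mean_mse = float(np.mean([r.mse for r in reports]))
        return cls(
            mae=float(np.mean([r.mae for r in reports])),
            mse=mean_mse,
            rmse=float(np.sqrt(mean_mse)),
            n=int(sum(r.n for r in reports)),
            keys=keys,
        )

    def as_dict(self) -> dict:
        return {**self.keys, "mae": self.mae, "mse": self.mse, "rmse": self.rmse, "n": self.n}
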