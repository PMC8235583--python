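"""Cross-validated evaluation harness.

Assembles per-view datasets from the simulator (or from files), runs
10-fold cross-validation with fold-local standardisation and PCA (no
leakage into held-out folds), and produces the full evaluation grid:

1. general MET models per view x family x PCA flag;
2. activity-classification accuracy per view x PCA flag;
3. per-activity MET models per activity x view x family;
4. the hierarchical (classify-then-route) vs general comparison.

Rendered tables round to 2 decimals; machine-readable CSV output keeps
full precision.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from . import preprocessing
from .classification import classification_accuracy, train_classifier
from .estimation import DEFAULT_ROUTING, ModelRegistry, train_family
from .features import FeatureMatrix, apply_pca, fit_pca, select_joints, velocities
from .metrics import MetricsReport
from .simulate import Protocol, simulate_protocol

__all__ = [
    "ViewDataset",
    "ExperimentConfig",
    "ExperimentResult",
    "build_datasets",
    "kfold_cv",
    "classification_cv",
    "run_experiment",
    "render_table",
    "parse_table",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class ViewDataset:
    """All frame-pair rows of one camera view, with aligned targets.

    ``X`` is (n, 18) velocities; ``met`` the step-interpolated calorimeter
    value at each row's timestamp; ``activity`` the true label;
    ``subject`` the subject id (for subject-grouped CV).
    """

    view: str
    X: np.ndarray
    met: np.ndarray
    activity: np.ndarray
    subject: np.ndarray
    columns: tuple[str, ...]

    def __len__(self) -> int:
        return self.X.shape[0]

    def as_feature_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(values=self.X, columns=self.columns, view=self.view)

    def subsample(self, max_rows: int, seed: int = 0) -> "ViewDataset":
        """Stratified (by activity) row subsample for cheaper experiments."""
        if len(self) <= max_rows:
            return self
        rng = np.random.default_rng(seed)
        keep: list[np.ndarray] = []
        frac = max_rows / len(self)
        for act in np.unique(self.activity):
            idx = np.flatnonzero(self.activity == act)
            take = max(1, int(round(frac * idx.size)))
            keep.append(rng.choice(idx, size=take, replace=False))
        idx = np.sort(np.concatenate(keep))
        return replace(
            self,
            X=self.X[idx],
            met=self.met[idx],
            activity=self.activity[idx],
            subject=self.subject[idx],
        )


def build_datasets(
    protocol: Protocol,
    seed: int = 0,
    discard_min: float = 3.0,
    keep_min: float = 2.0,
) -> dict[str, ViewDataset]:
    """Simulate a protocol and run the full preprocessing + feature chain.

    Every recording is recentred to the shoulder centre, smoothed, trimmed
    to its steady-state window, restricted to the six left-side joints and
    differenced into velocity rows; rows from all subjects and bouts are
    stacked per camera view.
    """
    recordings = simulate_protocol(protocol, seed=seed)
    by_view: dict[str, dict[str, list]] = {}
    columns: tuple[str, ...] | None = None
    for rec in recordings:
        seq = preprocessing.preprocess(rec.sequence, discard_min, keep_min)
        fm = velocities(select_joints(seq))
        met = rec.met_trace.at_times(fm.timestamps)
        acc = by_view.setdefault(rec.view.name, {"X": [], "met": [], "act": [], "subj": []})
        acc["X"].append(fm.values)
        acc["met"].append(met)
        acc["act"].append(np.full(len(fm), rec.bout.activity))
        acc["subj"].append(np.full(len(fm), rec.subject.subject_id))
        columns = fm.columns
    out = {}
    for view, acc in by_view.items():
        out[view] = ViewDataset(
            view=view,
            X=np.concatenate(acc["X"]),
            met=np.concatenate(acc["met"]),
            activity=np.concatenate(acc["act"]),
            subject=np.concatenate(acc["subj"]),
            columns=columns,
        )
        logger.info("view %s: %d feature rows", view, len(out[view]))
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _fold_splitter(k: int, seed: int, stratify, groups):
    if groups is not None:
        return GroupKFold(n_splits=k), groups
    if stratify is not None:
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed), stratify
    return KFold(n_splits=k, shuffle=True, random_state=seed), None


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    family: str = "lr",
    k: int = 10,
    seed: int = 0,
    pca: bool = False,
    pca_threshold: float = 0.90,
    stratify: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    train_kwargs: dict | None = None,
    **report_keys,
) -> MetricsReport:
    """Fold-averaged MAE/MSE/RMSE of one regressor family.

    Standardisation and (optional) PCA are fitted on each training fold
    only and applied to its held-out fold, so no test statistics leak into
    the transform.  Fold assignment is reproducible per seed; folds are
    stratified by activity when ``stratify`` labels are given, or grouped
    by subject when ``groups`` ids are given.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if k < 2:
        raise ValueError("k must be at least 2")
    if X.shape[0] < k:
        raise ValueError(f"{k}-fold CV needs at least {k} rows, got {X.shape[0]}")
    train_kwargs = dict(train_kwargs or {})
    splitter, strat_arg = _fold_splitter(k, seed, stratify, groups)
    split_args = (X, strat_arg) if strat_arg is not None else (X,)
    fold_reports = []
    for fold, (tr, te) in enumerate(splitter.split(*split_args)):
        Xtr, Xte = X[tr], X[te]
        if pca:
            scaler = StandardScaler().fit(Xtr)
            transform = fit_pca(scaler.transform(Xtr), pca_threshold)
            Xtr = transform.transform(scaler.transform(Xtr))
            Xte = transform.transform(scaler.transform(Xte))
        if family != "lr":
            train_kwargs.setdefault("seed", seed)
        model = train_family(family, Xtr, y[tr], **train_kwargs)
        fold_reports.append(
            MetricsReport.from_predictions(model.predict(Xte), y[te], fold=fold)
        )
    return MetricsReport.average(fold_reports, **report_keys)


def classification_cv(
    X: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    pca: bool = False,
    pca_threshold: float = 0.90,
    groups: np.ndarray | None = None,
    C: float = 1.0,
    gamma: float | str = "scale",
) -> float:
    """Fold-averaged one-vs-all SVM accuracy, PCA optionally per fold."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    splitter, strat_arg = _fold_splitter(k, seed, labels if groups is None else None, groups)
    split_args = (X, strat_arg) if strat_arg is not None else (X,)
    accuracies = []
    for tr, te in splitter.split(*split_args):
        Xtr, Xte = X[tr], X[te]
        if pca:
            scaler = StandardScaler().fit(Xtr)
            transform = fit_pca(scaler.transform(Xtr), pca_threshold)
            Xtr = transform.transform(scaler.transform(Xtr))
            Xte = transform.transform(scaler.transform(Xte))
        model = train_classifier(Xtr, labels[tr], C=C, gamma=gamma, seed=seed)
        accuracies.append(classification_accuracy(model.predict(Xte), labels[te]))
    return float(np.mean(accuracies))


# ---------------------------------------------------------------------------
# the experiment grid
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """What to run: views, families, PCA settings, CV folds, sizes."""

    protocol: Protocol = field(default_factory=Protocol)
    views: tuple[str, ...] = ("side", "rear_side", "rear")
    families: tuple[str, ...] = ("lr", "mlp", "cnn")
    pca_options: tuple[bool, ...] = (False, True)
    folds: int = 10
    seed: int = 0
    discard_min: float = 3.0
    keep_min: float = 2.0
    max_rows_per_view: int | None = None
    group_by_subject: bool = False
    classifier_view: str = "side"
    routing: dict = field(default_factory=lambda: dict(DEFAULT_ROUTING))
    mlp_nodes: int = 70
    train_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if not self.views or not self.families:
            raise ValueError("at least one view and one model family are required")


@dataclass
class ExperimentResult:
    """Machine-readable tables of the full evaluation grid."""

    general: pd.DataFrame  # view x family x pca -> mae/mse/rmse
    classification: pd.DataFrame  # view x pca -> accuracy
    per_activity: pd.DataFrame  # activity x view x family -> mae/mse/rmse
    hierarchical: pd.DataFrame  # hierarchical vs general, per activity
    reports: list[MetricsReport] = field(default_factory=list)


def _family_kwargs(config: ExperimentConfig, family: str) -> dict:
    kw = dict(config.train_kwargs.get(family, {}))
    if family == "mlp":
        kw.setdefault("n_nodes", config.mlp_nodes)
    return kw


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the three-part evaluation plus the hierarchical comparison."""
    datasets = build_datasets(
        config.protocol, config.seed, config.discard_min, config.keep_min
    )
    missing = set(config.views) - set(datasets)
    if missing:
        raise KeyError(f"no simulated data for requested view(s): {sorted(missing)}")
    datasets = {v: datasets[v] for v in config.views}
    if config.max_rows_per_view is not None:
        datasets = {
            v: d.subsample(config.max_rows_per_view, config.seed) for v, d in datasets.items()
        }

    def cv_args(ds: ViewDataset) -> dict:
        if config.group_by_subject:
            return {"groups": ds.subject}
        return {"stratify": ds.activity}

    reports: list[MetricsReport] = []

    # part 1: general model per view x family x pca
    general_rows = []
    for view, ds in datasets.items():
        for family in config.families:
            for pca in config.pca_options:
                kwargs = _family_kwargs(config, family)
                if family == "cnn" and pca:
                    # the conv net needs the full 18-wide input; the with-PCA
                    # cell zero-pads the reduced features back to 18
                    kwargs = {**kwargs, "pad_to_width": True}
                rep = kfold_cv(
                    ds.X,
                    ds.met,
                    family=family,
                    k=config.folds,
                    seed=config.seed,
                    pca=pca,
                    train_kwargs=kwargs,
                    view=view,
                    family_name=family,
                    activity="general",
                    pca_flag=pca,
                    **cv_args(ds),
                )
                reports.append(rep)
                general_rows.append(rep.as_dict())
                logger.info("general %s/%s pca=%s rmse=%.3f", view, family, pca, rep.rmse)
    general = pd.DataFrame(general_rows)

    # part 2: classification accuracy per view x pca
    cls_rows = []
    for view, ds in datasets.items():
        for pca in config.pca_options:
            acc = classification_cv(
                ds.X,
                ds.activity,
                k=config.folds,
                seed=config.seed,
                pca=pca,
                groups=ds.subject if config.group_by_subject else None,
            )
            cls_rows.append({"view": view, "pca_flag": pca, "accuracy": acc})
            logger.info("classification %s pca=%s acc=%.4f", view, pca, acc)
    classification = pd.DataFrame(cls_rows)

    # part 3: per-activity models (no PCA, following the part-2 outcome)
    activity_rows = []
    for view, ds in datasets.items():
        for activity in np.unique(ds.activity):
            mask = ds.activity == activity
            for family in config.families:
                rep = kfold_cv(
                    ds.X[mask],
                    ds.met[mask],
                    family=family,
                    k=config.folds,
                    seed=config.seed,
                    train_kwargs=_family_kwargs(config, family),
                    view=view,
                    family_name=family,
                    activity=activity,
                    pca_flag=False,
                    **(
                        {"groups": ds.subject[mask]}
                        if config.group_by_subject
                        else {}
                    ),
                )
                reports.append(rep)
                activity_rows.append(rep.as_dict())
    per_activity = pd.DataFrame(activity_rows)

    # part 4: hierarchical vs general on a held-out split
    hierarchical = _hierarchical_comparison(config, datasets)

    return ExperimentResult(
        general=general,
        classification=classification,
        per_activity=per_activity,
        hierarchical=hierarchical,
        reports=reports,
    )


def _hierarchical_comparison(
    config: ExperimentConfig, datasets: dict[str, ViewDataset]
) -> pd.DataFrame:
    """Train the routed registry and the general model on a common train
    split and compare their per-activity RMSE on the held-out rows."""
    from .estimation import hierarchical_predict

    # restrict routed families to the families this run actually trains
    routing = {
        act: (view, fam if fam in config.families else config.families[0])
        for act, (view, fam) in config.routing.items()
    }
    needed_views = {view for view, _ in routing.values()} | {config.classifier_view}
    missing = needed_views - set(datasets)
    if missing:
        raise KeyError(f"hierarchical routing needs view(s) {sorted(missing)}")

    ref = datasets[config.classifier_view]
    n = len(ref)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_test = max(1, n // config.folds)
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    registry = ModelRegistry(routing=routing)
    for activity, (view, family) in routing.items():
        ds = datasets[view]
        mask = np.zeros(n, dtype=bool)
        mask[train_idx] = True
        sel = mask & (ds.activity == activity)
        registry.per_activity[(activity, view)] = train_family(
            family,
            ds.X[sel],
            ds.met[sel],
            **(
                _family_kwargs(config, family)
                | ({} if family == "lr" else {"seed": config.seed})
            ),
        )
    registry.validate()

    general_family = "mlp" if "mlp" in config.families else config.families[0]
    general_model = train_family(
        general_family,
        ref.X[train_idx],
        ref.met[train_idx],
        **(
            _family_kwargs(config, general_family)
            | ({} if general_family == "lr" else {"seed": config.seed})
        ),
    )
    classifier = train_classifier(ref.X[train_idx], ref.activity[train_idx], seed=config.seed)

    per_view_test = {v: d.X[test_idx] for v, d in datasets.items()}
    met_hat, _labels = hierarchical_predict(
        registry, classifier, per_view_test, classifier_view=config.classifier_view
    )
    general_hat = general_model.predict(ref.X[test_idx])
    truth = ref.met[test_idx]
    true_act = ref.activity[test_idx]

    rows = []
    for activity in list(routing) + ["all"]:
        mask = np.ones(len(truth), bool) if activity == "all" else true_act == activity
        if not np.any(mask):
            continue
        rows.append(
            {
                "activity": activity,
                "hierarchical_rmse": MetricsReport.from_predictions(
                    met_hat[mask], truth[mask]
                ).rmse,
                "general_rmse": MetricsReport.from_predictions(
                    general_hat[mask], truth[mask]
                ).rmse,
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------


def render_table(df: pd.DataFrame, decimals: int = 2) -> str:
    """Aligned plain-text table, metrics rounded to ``decimals``."""
    shown = df.copy()
    for col in shown.columns:
        if pd.api.types.is_float_dtype(shown[col]):
            shown[col] = shown[col].round(decimals)
    return shown.to_string(index=False)


def parse_table(text: str) -> pd.DataFrame:
    """Parse a table rendered by :func:`render_table` back to a DataFrame."""
    return pd.read_csv(_io.StringIO(text), sep=r"\s+")
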