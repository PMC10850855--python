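"""Training, validation and deployment of the detection-curation SVM.

The classifier decides per detected cell whether its segmentation is
trustworthy (label 1, *good*) or artifactual (label 0, *bad*), from the 26
mesh/intensity features. Hyperparameters are chosen by stratified k-fold
cross-validated accuracy over a small grid — linear and RBF kernels,
C in {100, 1000, 10000}, gamma in {0.001, 0.01, 0.1} — and the winning
setting is refit on the full training split. Features are standardized
(training mean/sd) inside the model. For large training sets the RBF kernel
is replaced by a Nystrom low-rank feature map followed by a linear SVM,
which at full rank reproduces the exact kernel machine.

`CurationSVC` is a scikit-learn-compatible estimator; the module-level
functions (`prepare_training_data`, `split`, `grid_search`, `fit_final`,
`predict`, `roc_curve_auc`, `confusion_report`, `bias_ratios`, `curate`,
`save_model`/`load_model`) are the pipeline-facing surface built on it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.kernel_approximation import Nystroem
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import FormatError, ValidationError
from .features import FEATURE_NAMES, CellFeatureExtractor

logger = logging.getLogger(__name__)

MODEL_SCHEMA = "cellcurate.curation_model/1"


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters (defaults follow the standard workflow)."""

    test_fraction: float = 0.5
    kernels: tuple[str, ...] = ("linear", "rbf")
    C_grid: tuple[float, ...] = (100.0, 1000.0, 10000.0)
    gamma_grid: tuple[float, ...] = (0.001, 0.01, 0.1)
    folds: int = 5
    use_nystrom: bool | str = "auto"
    nystrom_components: int = 1000
    nystrom_threshold: int = 5000
    class_weight: str | dict | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if not self.C_grid or not self.gamma_grid or not self.kernels:
            raise ValidationError("hyperparameter grids must be non-empty")
        bad = set(self.kernels) - {"linear", "rbf"}
        if bad:
            raise ValidationError(f"unsupported kernels: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def prepare_training_data(labeled_tables) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Concatenate labeled feature tables and drop incomplete rows.

    Rows with any missing feature value or a missing/ambiguous label
    (Questionmark) are removed. Returns (X, y, report) where X holds the 26
    feature columns in manifest order and y is in {0, 1}.
    """
    if isinstance(labeled_tables, pd.DataFrame):
        labeled_tables = [labeled_tables]
    tables = list(labeled_tables)
    if not tables:
        raise ValidationError("no labeled tables supplied")
    merged = pd.concat(tables, ignore_index=True)
    missing_cols = [c for c in FEATURE_NAMES if c not in merged.columns]
    if missing_cols:
        raise ValidationError(f"tables lack feature columns: {missing_cols}")
    if "label" not in merged.columns:
        raise ValidationError("tables lack the 'label' column; label detections first")
    n_total = len(merged)
    has_label = merged["label"].notna()
    complete = merged[FEATURE_NAMES].notna().all(axis=1)
    kept = merged[has_label & complete]
    report = {
        "n_input": n_total,
        "n_dropped_unlabeled": int((~has_label).sum()),
        "n_dropped_missing_features": int((has_label & ~complete).sum()),
        "n_kept": len(kept),
    }
    if kept.empty:
        raise ValidationError("no complete labeled rows remain after NaN removal")
    y = kept["label"].astype(int).to_numpy()
    for cls, name in ((1, "good"), (0, "bad")):
        if not np.any(y == cls):
            raise ValidationError(f"class {name!r} absent from the labeled data")
    X = kept[FEATURE_NAMES].reset_index(drop=True)
    return X, y[: len(X)], report


def split(X, y, config: TrainConfig):
    """Stratified train/test split with per-partition class proportions."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present before splitting")
    X_train, X_test, y_train, y_test = train_test_split(
        X,
        y,
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed,
    )
    def _props(labels):
        labels = np.asarray(labels)
        return {"good": float(np.mean(labels == 1)), "bad": float(np.mean(labels == 0))}

    proportions = {"train": _props(y_train), "test": _props(y_test)}
    for name, part in (("train", y_train), ("test", y_test)):
        if len(np.unique(part)) < 2:
            raise ValidationError(f"{name} partition lost a class; adjust the split")
    return (X_train, y_train), (X_test, y_test), proportions


def correlation_matrix(X) -> pd.DataFrame:
    """Pearson feature-feature correlation (unit diagonal, symmetric)."""
    X = pd.DataFrame(X)
    if len(X) < 3:
        raise ValidationError("need >= 3 rows for a correlation matrix")
    constant = X.columns[X.std(ddof=0) == 0].tolist()
    if constant:
        warnings.warn(f"constant features yield undefined correlations: {constant}")
    return X.corr(method="pearson")


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------


def _candidate_grid(config: TrainConfig):
    """Deterministic candidate order; ties resolve to the earliest entry
    under the sort key used in fit (smaller C, then linear, then smaller gamma)."""
    grid = []
    for C in config.C_grid:
        if "linear" in config.kernels:
            grid.append({"kernel": "linear", "C": float(C), "gamma": None})
        if "rbf" in config.kernels:
            for gamma in config.gamma_grid:
                grid.append({"kernel": "rbf", "C": float(C), "gamma": float(gamma)})
    return grid


class CurationSVC(BaseEstimator, ClassifierMixin):
    """Grid-searched SVM for good/bad detection curation.

    fit(X, y) standardizes the features, runs stratified k-fold CV over the
    kernel/C/gamma grid, refits the winning setting on all of X, and exposes
    ``best_params_``, ``cv_results_``, ``classes_`` and the feature manifest
    ``feature_names_``. When ``use_nystrom`` is active the RBF candidates use
    a Nystrom map + linear SVM instead of the exact kernel.

    Prediction (labels and decision scores) runs through a plain-numpy
    decision path extracted from the fitted scikit-learn objects, so a model
    reloaded from disk reproduces predictions bit-identically.
    """

    def __init__(
        self,
        kernels=("linear", "rbf"),
        C_grid=(100.0, 1000.0, 10000.0),
        gamma_grid=(0.001, 0.01, 0.1),
        folds=5,
        use_nystrom="auto",
        nystrom_components=1000,
        nystrom_threshold=5000,
        class_weight=None,
        random_state=0,
    ):
        self.kernels = kernels
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.folds = folds
        self.use_nystrom = use_nystrom
        self.nystrom_components = nystrom_components
        self.nystrom_threshold = nystrom_threshold
        self.class_weight = class_weight
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _config(self) -> TrainConfig:
        return TrainConfig(
            kernels=tuple(self.kernels),
            C_grid=tuple(self.C_grid),
            gamma_grid=tuple(self.gamma_grid),
            folds=self.folds,
            use_nystrom=self.use_nystrom,
            nystrom_components=self.nystrom_components,
            nystrom_threshold=self.nystrom_threshold,
            class_weight=self.class_weight,
            seed=self.random_state,
        )

    def _validate_X(self, X, *, fitting: bool):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            if fitting:
                self.feature_names_ = names
            elif getattr(self, "feature_names_", None) is not None:
                if names != self.feature_names_:
                    raise ValidationError(
                        "feature names/order differ from the training manifest"
                    )
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if fitting:
                self.feature_names_ = None
            elif getattr(self, "feature_names_", None) is not None:
                if values.ndim != 2 or values.shape[1] != len(self.feature_names_):
                    raise ValidationError(
                        f"expected {len(self.feature_names_)} features in manifest order"
                    )
        if values.ndim != 2:
            raise ValidationError("X must be 2-D")
        if np.isnan(values).any():
            rows = np.unique(np.nonzero(np.isnan(values))[0]).tolist()
            raise ValidationError(f"X contains missing values in rows {rows[:20]}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("X contains non-finite values")
        return values

    def _nystrom_active(self, n_train: int) -> bool:
        if self.use_nystrom == "auto":
            return n_train > self.nystrom_threshold
        return bool(self.use_nystrom)

    def _make_pipeline(self, params: dict, n_train: int) -> Pipeline:
        steps = [("scaler", StandardScaler())]
        common = dict(class_weight=self.class_weight)
        if params["kernel"] == "rbf" and self._nystrom_active(n_train):
            n_comp = min(self.nystrom_components, n_train)
            steps.append(
                (
                    "nystrom",
                    Nystroem(
                        kernel="rbf",
                        gamma=params["gamma"],
                        n_components=n_comp,
                        random_state=self.random_state,
                    ),
                )
            )
            steps.append(("svc", SVC(kernel="linear", C=params["C"], **common)))
        elif params["kernel"] == "rbf":
            steps.append(
                ("svc", SVC(kernel="rbf", C=params["C"], gamma=params["gamma"], **common))
            )
        else:
            steps.append(("svc", SVC(kernel="linear", C=params["C"], **common)))
        return Pipeline(steps)

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y):
        config = self._config()
        values = self._validate_X(X, fitting=True)
        y = np.asarray(y).astype(int)
        if y.shape[0] != values.shape[0]:
            raise ValidationError("X and y lengths differ")
        classes = np.unique(y)
        if not np.array_equal(classes, np.array([0, 1])):
            raise ValidationError("y must contain both classes, encoded 0/1")
        n_train = values.shape[0]

        cv = StratifiedKFold(
            n_splits=self.folds, shuffle=True, random_state=self.random_state
        )
        fold_indices = list(cv.split(values, y))
        for _, (tr, _te) in enumerate(fold_indices):
            if len(np.unique(y[tr])) < 2:
                raise ValidationError(
                    "a CV fold lost a class; use fewer folds or more data"
                )

        rows = []
        for params in _candidate_grid(config):
            scores = []
            for tr, te in fold_indices:
                pipe = self._make_pipeline(params, len(tr))
                pipe.fit(values[tr], y[tr])
                scores.append(float(np.mean(pipe.predict(values[te]) == y[te])))
            rows.append(
                {
                    "kernel": params["kernel"],
                    "C": params["C"],
                    "gamma": params["gamma"],
                    "mean_cv_accuracy": float(np.mean(scores)),
                    "fold_accuracies": scores,
                }
            )
        self.cv_results_ = pd.DataFrame(rows)

        def _key(row):
            # argmax accuracy; ties -> smaller C, linear before rbf, smaller gamma
            return (
                -row["mean_cv_accuracy"],
                row["C"],
                0 if row["kernel"] == "linear" else 1,
                row["gamma"] if row["gamma"] is not None else 0.0,
            )

        best = min(rows, key=_key)
        self.best_params_ = {k: best[k] for k in ("kernel", "C", "gamma")}
        self.cv_best_score_ = best["mean_cv_accuracy"]

        self.pipeline_ = self._make_pipeline(self.best_params_, n_train)
        self.pipeline_.fit(values, y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = values.shape[1]
        self.class_proportions_ = {
            "good": float(np.mean(y == 1)),
            "bad": float(np.mean(y == 0)),
        }
        self._decision_path_ = _extract_decision_path(self.pipeline_, self.best_params_)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed score, monotone in predicted goodness (> 0 means good)."""
        if not hasattr(self, "_decision_path_"):
            raise ValidationError("model is not fitted")
        values = self._validate_X(X, fitting=False)
        return _apply_decision_path(self._decision_path_, values)

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y).astype(int)))


def _extract_decision_path(pipeline: Pipeline, best_params: dict) -> dict:
    """Plain-array decision function of a fitted pipeline."""
    scaler: StandardScaler = pipeline.named_steps["scaler"]
    svc: SVC = pipeline.named_steps["svc"]
    path = {
        "mean": np.asarray(scaler.mean_, dtype=float),
        "scale": np.asarray(scaler.scale_, dtype=float),
        "intercept": float(svc.intercept_[0]),
        "best_params": dict(best_params),
    }
    if "nystrom" in pipeline.named_steps:
        nys: Nystroem = pipeline.named_steps["nystrom"]
        path["kind"] = "nystrom_linear"
        path["gamma"] = float(nys.gamma)
        path["components"] = np.asarray(nys.components_, dtype=float)
        path["normalization"] = np.asarray(nys.normalization_, dtype=float)
        path["coef"] = np.asarray(svc.coef_, dtype=float)[0]
    elif svc.kernel == "linear":
        path["kind"] = "linear"
        path["coef"] = np.asarray(svc.coef_, dtype=float)[0]
    else:
        path["kind"] = "rbf"
        path["gamma"] = float(svc._gamma)
        path["support_vectors"] = np.asarray(svc.support_vectors_, dtype=float)
        path["dual_coef"] = np.asarray(svc.dual_coef_, dtype=float)[0]
    return path


def _apply_decision_path(path: dict, values: np.ndarray) -> np.ndarray:
    z = (values - path["mean"]) / path["scale"]
    if path["kind"] == "linear":
        return z @ path["coef"] + path["intercept"]
    if path["kind"] == "nystrom_linear":
        feats = rbf_kernel(z, path["components"], gamma=path["gamma"]) @ path[
            "normalization"
        ].T
        return feats @ path["coef"] + path["intercept"]
    k = rbf_kernel(z, path["support_vectors"], gamma=path["gamma"])
    return k @ path["dual_coef"] + path["intercept"]


# ---------------------------------------------------------------------------
# Pipeline-facing wrappers
# ---------------------------------------------------------------------------


def _estimator_from_config(config: TrainConfig, **overrides) -> CurationSVC:
    kwargs = dict(
        kernels=config.kernels,
        C_grid=config.C_grid,
        gamma_grid=config.gamma_grid,
        folds=config.folds,
        use_nystrom=config.use_nystrom,
        nystrom_components=config.nystrom_components,
        nystrom_threshold=config.nystrom_threshold,
        class_weight=config.class_weight,
        random_state=config.seed,
    )
    kwargs.update(overrides)
    return CurationSVC(**kwargs)


def grid_search(train_set, config: TrainConfig):
    """(best hyperparameters, CV score table) for the training split."""
    X_train, y_train = train_set
    model = _estimator_from_config(config).fit(X_train, y_train)
    return model.best_params_, model.cv_results_


def fit_final(train_set, best_params: dict, config: TrainConfig) -> CurationSVC:
    """Refit the chosen hyperparameter setting on the full training split."""
    X_train, y_train = train_set
    kernels = (best_params["kernel"],)
    gammas = (
        (best_params["gamma"],) if best_params["gamma"] is not None else config.gamma_grid
    )
    model = _estimator_from_config(
        config, kernels=kernels, C_grid=(best_params["C"],), gamma_grid=gammas
    )
    return model.fit(X_train, y_train)


def train(train_set, config: TrainConfig) -> CurationSVC:
    """Grid search + final refit in one call."""
    X_train, y_train = train_set
    return _estimator_from_config(config).fit(X_train, y_train)


def predict(model: CurationSVC, X) -> tuple[np.ndarray, np.ndarray]:
    """(labels in {0,1}, continuous decision scores); 1 = good detection."""
    scores = model.decision_function(X)
    return (scores > 0).astype(int), scores


def roc_curve_auc(truth, scores):
    """ROC points by threshold sweep and the trapezoidal area under them."""
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(truth)) < 2:
        raise ValidationError("ROC needs both classes in the truth labels")
    fpr, tpr, thresholds = _sk_roc_curve(truth, scores)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, auc


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and derived metrics (positive class = good = 1)."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float | None = None
    roc_points: pd.DataFrame | None = field(default=None, compare=False)
    bias: pd.DataFrame | None = field(default=None, compare=False)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        out = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return float("nan")
    return num / den


def confusion_report(truth, predicted) -> EvaluationReport:
    """Confusion matrix and the five derived performance metrics.

    False positives — bad detections that the model would keep — are the
    costly error mode for curation; they are reported first-class here so a
    user can weigh precision over raw accuracy.
    """
    truth = np.asarray(truth).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if truth.shape != predicted.shape:
        raise ValidationError("truth and predicted labels differ in length")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    n = tp + fp + tn + fn
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    return EvaluationReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=_safe_ratio(tp + tn, n, "accuracy"),
        precision=precision,
        recall=recall,
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        f1=_safe_ratio(2 * precision * recall, precision + recall, "F1")
        if not (np.isnan(precision) or np.isnan(recall))
        else float("nan"),
    )


def bias_ratios(
    feature_table: pd.DataFrame,
    manual_keep_mask,
    model_keep_mask,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Per-feature mean(model-kept) / mean(manually-kept) ratios.

    A ratio deviating from 1 by more than ``tolerance`` flags a curation
    bias for that feature; such a model should not be deployed.
    """
    manual = np.asarray(manual_keep_mask, dtype=bool)
    model = np.asarray(model_keep_mask, dtype=bool)
    if not manual.any() or not model.any():
        raise ValidationError("both keep masks must select at least one row")
    rows = []
    for name in FEATURE_NAMES:
        manual_mean = float(feature_table.loc[manual, name].mean())
        model_mean = float(feature_table.loc[model, name].mean())
        if manual_mean == 0:
            warnings.warn(f"manual mean of {name} is zero; ratio undefined")
            ratio = float("nan")
        else:
            ratio = model_mean / manual_mean
        rows.append(
            {
                "feature": name,
                "manual_mean": manual_mean,
                "model_mean": model_mean,
                "ratio": ratio,
                "biased": bool(abs(ratio - 1) > tolerance) if np.isfinite(ratio) else True,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: CurationSVC, path) -> Path:
    """Write a fitted model as a self-describing JSON archive."""
    if not hasattr(model, "_decision_path_"):
        raise ValidationError("cannot save an unfitted model")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dp = model._decision_path_
    arrays = {
        k: np.asarray(v).tolist()
        for k, v in dp.items()
        if isinstance(v, np.ndarray)
    }
    payload = {
        "schema": MODEL_SCHEMA,
        "params": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in model.get_params().items()
        },
        "feature_names": model.feature_names_,
        "best_params": model.best_params_,
        "cv_best_score": model.cv_best_score_,
        "class_proportions": model.class_proportions_,
        "n_features_in": model.n_features_in_,
        "decision": {
            "kind": dp["kind"],
            "intercept": dp["intercept"],
            "gamma": dp.get("gamma"),
            "arrays": arrays,
        },
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path) -> CurationSVC:
    """Rebuild a model saved with :func:`save_model`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema") != MODEL_SCHEMA:
        raise FormatError(f"{path} is not a {MODEL_SCHEMA} archive")
    try:
        params = dict(payload["params"])
        for key in ("kernels", "C_grid", "gamma_grid"):
            params[key] = tuple(params[key])
        model = CurationSVC(**params)
        model.feature_names_ = payload["feature_names"]
        model.best_params_ = payload["best_params"]
        model.cv_best_score_ = payload["cv_best_score"]
        model.class_proportions_ = payload["class_proportions"]
        model.n_features_in_ = payload["n_features_in"]
        model.classes_ = np.array([0, 1])
        decision = payload["decision"]
        dp = {
            "kind": decision["kind"],
            "intercept": float(decision["intercept"]),
            "best_params": payload["best_params"],
        }
        if decision["gamma"] is not None:
            dp["gamma"] = float(decision["gamma"])
        for key, value in decision["arrays"].items():
            dp[key] = np.asarray(value, dtype=float)
        model._decision_path_ = dp
    except (KeyError, TypeError) as exc:
        raise FormatError(f"model archive {path} is malformed: {exc}") from exc
    return model


# ---------------------------------------------------------------------------
# Deployment
# ---------------------------------------------------------------------------


def curate(records, images, model: CurationSVC, pixel_size: float = 1.0):
    """Apply a trained model to new detections.

    Returns (kept records, discarded records, report); records whose feature
    extraction fails are discarded separately and counted as ``n_failed``.
    """
    records = list(records)
    if not records:
        empty = {
            "n_input": 0,
            "n_kept": 0,
            "n_discarded": 0,
            "n_failed": 0,
            "failed_records": [],
            "score_mean": float("nan"),
            "score_min": float("nan"),
            "score_max": float("nan"),
        }
        return [], [], empty
    frames = sorted({r.frame for r in records})
    missing = [f for f in frames if f not in images]
    if missing:
        raise ValidationError(f"no image for frames {missing}")
    extractor = CellFeatureExtractor(pixel_size=pixel_size)
    table = extractor.transform(records, images)
    complete = table[FEATURE_NAMES].notna().all(axis=1).to_numpy()
    failed = [rec for rec, ok in zip(records, complete) if not ok]
    usable = [rec for rec, ok in zip(records, complete) if ok]
    kept, discarded = [], []
    scores = np.array([])
    if usable:
        X = table.loc[complete, FEATURE_NAMES]
        if model.feature_names_ is None:
            X = X.to_numpy(dtype=float)
        labels, scores = predict(model, X)
        for rec, label in zip(usable, labels):
            (kept if label == 1 else discarded).append(rec)
    report = {
        "n_input": len(records),
        "n_kept": len(kept),
        "n_discarded": len(discarded),
        "n_failed": len(failed),
        "failed_records": failed,
        "score_mean": float(scores.mean()) if scores.size else float("nan"),
        "score_min": float(scores.min()) if scores.size else float("nan"),
        "score_max": float(scores.max()) if scores.size else float("nan"),
    }
    return kept, discarded, report
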