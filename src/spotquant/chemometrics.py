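"""Concentration prediction from 51-feature vectors with support-vector regression.

The predictor is an epsilon-SVR on standardized features with target
log10(concentration in mM), so one model spans both the physiological
(0.5–20 mM) and the high-intake (0.1–0.5 M) assay ranges.  Because kernel
machines weight every standardized dimension equally, a univariate filter
(SelectKBest on the F statistic against the log target) sits between the
scaler and the SVR: channels that track concentration correlate with the
target near r = 1, while moment features dominated by per-image noise show
only chance correlation, so the filter separates them sharply.  The number
of retained features is a grid-search hyperparameter alongside C, epsilon
and gamma, all chosen by grouped-CV; replicate groups never straddle the
train/test split or the CV folds, so replicate-level correlation cannot
leak.  Feature standardization and selection are fitted on the training
split only.

An optional coarse range classifier (SVC on the same features) triages a
sample into the mM vs M regime before regression, mirroring how the assay
is read out at two dilution ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.feature_selection import SelectKBest, f_regression
from sklearn.metrics import r2_score
from sklearn.model_selection import GridSearchCV, GroupKFold, GroupShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .features import FEATURE_NAMES, FEATURE_SCHEMA_VERSION


class SchemaMismatch(ValueError):
    """Raised when features do not match the trained model's schema."""


def robust_f_regression(X, y):
    """F scores for univariate selection, hardened at the extremes.

    ``f_regression`` computes F = r^2/(1-r^2)·dof; when a feature is
    (numerically) perfectly correlated with the target, cancellation can
    make 1-r^2 slightly negative and the returned F negative or infinite,
    which would rank a perfect feature *last*.  Such scores are remapped to
    a large finite value; NaN scores (constant features) become 0.
    """
    F, p = f_regression(X, y)
    big = np.finfo(np.float64).max / 4
    F = np.asarray(F, dtype=float)
    F[np.isnan(F)] = 0.0
    F[~np.isfinite(F) | (F < 0)] = big
    return F, p


@dataclass
class AssayDataset:
    """Matched feature matrix, concentrations and replicate groups."""

    features: pd.DataFrame
    concentrations: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.groups = np.asarray(self.groups)
        n = len(self.features)
        if not (n == self.concentrations.size == self.groups.size):
            raise ValueError("features, concentrations and groups must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        missing = [c for c in FEATURE_NAMES if c not in self.features.columns]
        if missing:
            raise SchemaMismatch(f"feature table lacks columns {missing[:3]}...")
        # canonical column order
        self.features = self.features.loc[:, list(FEATURE_NAMES)]


@dataclass
class ModelReport:
    """Held-out evaluation of a trained predictor."""

    r_squared: float
    pairs: pd.DataFrame  # columns: actual_mM, predicted_mM
    hyperparameters: dict
    n_train: int
    n_test: int
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "r_squared": self.r_squared,
            "hyperparameters": self.hyperparameters,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class ConcentrationPredictor:
    """A fitted SVR pipeline plus the feature schema it expects."""

    pipeline: Pipeline
    feature_names: tuple[str, ...] = FEATURE_NAMES
    schema_version: str = FEATURE_SCHEMA_VERSION
    log10_range: tuple[float, float] = field(default=(-np.inf, np.inf))

    def _coerce(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in features.columns]
            if missing:
                raise SchemaMismatch(f"missing feature columns {missing[:3]}...")
            return features.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        arr = np.atleast_2d(np.asarray(features, dtype=float))
        if arr.shape[1] != len(self.feature_names):
            raise SchemaMismatch(
                f"expected {len(self.feature_names)} features, got {arr.shape[1]}"
            )
        return arr

    def predict(self, features, with_flag: bool = False):
        """Concentration estimates in mM (10**predicted-log-target).

        With ``with_flag=True`` also returns booleans marking predictions
        whose log-target falls outside the training target range
        (extrapolated).
        """
        x = self._coerce(features)
        log_pred = self.pipeline.predict(x)
        conc = 10.0**log_pred
        if with_flag:
            lo, hi = self.log10_range
            return conc, (log_pred < lo) | (log_pred > hi)
        return conc

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "ConcentrationPredictor":
        obj = joblib.load(Path(path))
        if obj.schema_version != FEATURE_SCHEMA_VERSION:
            raise SchemaMismatch(
                f"model schema {obj.schema_version!r} != {FEATURE_SCHEMA_VERSION!r}"
            )
        return obj


def _default_grid(kernel: str, n_features: int) -> list[dict]:
    c_grid = [0.1, 1.0, 10.0, 100.0]
    eps_grid = [0.01, 0.1]
    k_grid = [k for k in (12, 24, n_features) if k <= n_features]
    if kernel == "rbf":
        # per-k gamma around the "scale" heuristic (features are standardized,
        # so scale ~ 1/k after selecting k features)
        return [
            {
                "sel__k": [k],
                "svr__C": c_grid,
                "svr__epsilon": eps_grid,
                "svr__gamma": [0.5 / k, 1.0 / k, 2.0 / k],
            }
            for k in k_grid
        ]
    if kernel == "linear":
        return [{"sel__k": k_grid, "svr__C": c_grid, "svr__epsilon": eps_grid}]
    if kernel == "polynomial":
        return [{
            "sel__k": k_grid,
            "svr__C": c_grid,
            "svr__epsilon": eps_grid,
            "svr__degree": [2, 3],
        }]
    raise ValueError(f"unknown kernel {kernel!r}")


def train_predictor(
    data: AssayDataset,
    kernel: str = "rbf",
    cv_folds: int = 3,
    seed: int = 0,
    test_size: float = 0.3,
    param_grid: list[dict] | None = None,
) -> tuple[ConcentrationPredictor, ModelReport]:
    """Grid-searched SVR on log10(concentration) with a grouped hold-out.

    The dataset is split ~(1-test_size)/test_size by replicate group;
    hyperparameters are selected by GroupKFold CV inside the training
    split; the report's R² is computed on the held-out split in log10
    space (the scale on which predicted-vs-actual is assessed).
    """
    y = np.log10(data.concentrations)
    if np.unique(y).size < 2:
        raise ValueError("training requires at least two distinct concentrations")
    x = data.features.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    groups = data.groups

    n_groups = np.unique(groups).size
    if n_groups < 2:
        raise ValueError("need at least two replicate groups to split")
    splitter = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=seed)
    train_idx, test_idx = next(splitter.split(x, y, groups))

    train_groups = groups[train_idx]
    n_train_groups = np.unique(train_groups).size
    folds = min(cv_folds, n_train_groups)
    if folds < 2:
        raise ValueError(
            f"cv_folds={cv_folds} needs >=2 replicate groups in the training split"
        )

    sk_kernel = {"polynomial": "poly"}.get(kernel, kernel)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("sel", SelectKBest(robust_f_regression, k="all")),
            ("svr", SVR(kernel=sk_kernel)),
        ]
    )
    grid = param_grid if param_grid is not None else _default_grid(kernel, x.shape[1])
    search = GridSearchCV(pipe, grid, cv=GroupKFold(n_splits=folds), scoring="r2")
    search.fit(x[train_idx], y[train_idx], groups=train_groups)
    best: Pipeline = search.best_estimator_

    log_pred = best.predict(x[test_idx])
    r2 = float(r2_score(y[test_idx], log_pred))
    pairs = pd.DataFrame(
        {
            "actual_mM": data.concentrations[test_idx],
            "predicted_mM": 10.0**log_pred,
        }
    )
    model = ConcentrationPredictor(
        pipeline=best,
        log10_range=(float(y[train_idx].min()), float(y[train_idx].max())),
    )
    report = ModelReport(
        r_squared=r2,
        pairs=pairs,
        hyperparameters={"kernel": kernel, **search.best_params_},
        n_train=int(train_idx.size),
        n_test=int(test_idx.size),
        train_idx=train_idx,
        test_idx=test_idx,
    )
    return model, report


def predict_concentration(model: ConcentrationPredictor, features, with_flag: bool = False):
    """Functional alias for :meth:`ConcentrationPredictor.predict`."""
    return model.predict(features, with_flag=with_flag)


def train_range_classifier(data: AssayDataset, threshold_mM: float = 50.0, seed: int = 0):
    """Coarse SVC triage of samples into mM-range vs M-range.

    Returns a fitted pipeline predicting True for concentrations above
    ``threshold_mM`` (the high-intake regime).
    """
    y = data.concentrations > threshold_mM
    if np.unique(y).size < 2:
        raise ValueError("both concentration regimes must be present")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", C=1.0, random_state=seed)),
    ])
    pipe.fit(data.features.to_numpy(dtype=float), y)
    return pipe
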