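"""Visual-acuity regression from OCTA biomarkers.

The decimal VA (0, 1] is regressed on its logMAR-style scale,
``-log10(decimal)``, which maps the clinical range [0.1, 1.0] onto [1, 0]
with equidistant steps.  An epsilon-SVR on standardised features is fitted
with an exhaustive hyperparameter search scored by 5-fold cross-validated
mean absolute error on the 80% training split; the held-out 20% yields the
reported MAE and RMSE (both on the log scale) and the "increment", the
relative excess of RMSE over MAE,

    increment = 100 * (RMSE - MAE) / RMSE,

a summary of how heavy-tailed the error distribution is.

Two entry points: the functional operations (``split_train_test``,
``grid_search_cv``, ``train``, ``evaluate``) and a statsmodels-style
:class:`VisualAcuityModel` whose :meth:`~VisualAcuityModel.fit` returns a
:class:`VAResults` carrying the trained estimator, the CV audit table, the
held-out report and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import ParameterError, ValidationError
from .image_io import FeatureTable
from .quadrant_features import FeatureLayout


# -- VA scale --------------------------------------------------------------

def va_to_log10(decimal) -> np.ndarray | float:
    """Decimal VA -> logMAR-style scale: -log10(decimal); 1.0 -> 0.0."""
    arr = np.asarray(decimal, dtype=float)
    if np.any(arr <= 0):
        raise ParameterError("decimal VA must be > 0")
    out = -np.log10(arr)
    return float(out) if np.isscalar(decimal) or arr.ndim == 0 else out


def va_from_log10(log10_scale) -> np.ndarray | float:
    """Inverse transform: 10 ** (-x)."""
    arr = np.asarray(log10_scale, dtype=float)
    out = np.power(10.0, -arr)
    return float(out) if np.isscalar(log10_scale) or arr.ndim == 0 else out


# -- configuration ---------------------------------------------------------

@dataclass(frozen=True)
class SearchConfig:
    """Hyperparameter grid and resampling plan for the exhaustive search."""

    kernels: tuple[str, ...] = ("rbf", "linear")
    C: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    epsilon: tuple[float, ...] = (0.01, 0.05, 0.1)
    gamma: tuple = ("scale", 0.01, 0.1)
    folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")
        if not 0 < self.test_fraction < 1:
            raise ParameterError("test_fraction must be in (0, 1)")
        if not (self.kernels and self.C and self.epsilon and self.gamma):
            raise ParameterError("hyperparameter grids must be non-empty")

    def grid(self) -> list[dict]:
        """Grid points in a fixed, documented order (first wins on ties)."""
        points = []
        for kernel in self.kernels:
            gammas = self.gamma if kernel == "rbf" else (None,)
            for C in self.C:
                for eps in self.epsilon:
                    for g in gammas:
                        p = {"kernel": kernel, "C": C, "epsilon": eps}
                        if g is not None:
                            p["gamma"] = g
                        points.append(p)
        return points


@dataclass(frozen=True)
class EvalReport:
    """Held-out errors on the log10 VA scale."""

    mae: float
    rmse: float
    increment_pct: float
    n_test: int
    degenerate: bool = False  # RMSE == 0: increment reported as 0 by convention


@dataclass(frozen=True)
class TrainedVAModel:
    """Fitted scaler+SVR pipeline with the metadata needed to reuse it."""

    pipeline: Pipeline
    feature_names: tuple[str, ...]
    params: dict
    layout: FeatureLayout
    seed: int
    n_train: int

    def predict_log10(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} features, got shape {X.shape}"
            )
        return self.pipeline.predict(X)

    def predict_decimal(self, X: np.ndarray) -> np.ndarray:
        return va_from_log10(self.predict_log10(X))


# -- functional operations -------------------------------------------------

def split_train_test(n_samples: int, config: SearchConfig
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle, then split with train = floor((1 - test_fraction) n).

    The split is per consultation (rows of the feature table), never per
    image.  215 samples at 20% test -> 172 train / 43 test.
    """
    config.validate()
    if n_samples < config.folds + 1:
        raise ValidationError(
            f"need at least folds+1={config.folds + 1} samples, got {n_samples}"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n_samples)
    n_train = int(np.floor((1.0 - config.test_fraction) * n_samples))
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def grid_search_cv(X: np.ndarray, y: np.ndarray, config: SearchConfig
                   ) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search scored by k-fold CV mean MAE.

    Standardisation is fitted inside each fold (no leakage).  Returns the
    argmin hyperparameters (first grid point on ties) and the full score
    table for audit.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("NaN in features or targets")
    kf = KFold(n_splits=config.folds)
    splits = list(kf.split(X))
    rows = []
    for params in config.grid():
        fold_maes = []
        for tr, va in splits:
            pipe = _make_pipeline(params)
            pipe.fit(X[tr], y[tr])
            fold_maes.append(float(np.mean(np.abs(pipe.predict(X[va]) - y[va]))))
        rows.append({**params, "cv_mae": float(np.mean(fold_maes))})
    table = pd.DataFrame(rows)
    best_idx = int(np.argmin(table["cv_mae"].to_numpy()))  # first minimiser
    best = config.grid()[best_idx]
    return best, table


def _make_pipeline(params: dict) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svr", SVR(**params)),
    ])


def train(
    X: np.ndarray,
    y_log10: np.ndarray,
    params: dict,
    feature_names: Sequence[str] | None = None,
    layout: FeatureLayout | None = None,
    seed: int = 0,
) -> TrainedVAModel:
    """Fit standardisation + epsilon-SVR with the given hyperparameters."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_log10, dtype=float)
    if len(X) != len(y):
        raise ValidationError(f"X has {len(X)} rows, y has {len(y)}")
    if len(X) < 2:
        raise ValidationError("need at least 2 training samples")
    constant = np.flatnonzero(X.std(axis=0) == 0)
    if constant.size:
        warnings.warn(
            f"feature columns {constant.tolist()} are constant in training data; "
            "retained with zero-variance guard",
            stacklevel=2,
        )
    pipe = _make_pipeline(params)
    pipe.fit(X, y)
    layout = layout or FeatureLayout()
    names = tuple(feature_names) if feature_names is not None else layout.names[: X.shape[1]]
    if len(names) != X.shape[1]:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    return TrainedVAModel(
        pipeline=pipe,
        feature_names=names,
        params=dict(params),
        layout=layout,
        seed=seed,
        n_train=len(X),
    )


def increment_pct(mae: float, rmse: float) -> float:
    """Relative excess of RMSE over MAE in percent; 0 when RMSE is 0."""
    if rmse < 0 or mae < 0:
        raise ParameterError("errors must be non-negative")
    if rmse == 0:
        return 0.0
    return 100.0 * (rmse - mae) / rmse


def evaluate(model: TrainedVAModel, X_test: np.ndarray,
             y_test_log10: np.ndarray) -> EvalReport:
    """MAE/RMSE on the log10 scale plus the RMSE-over-MAE increment."""
    X_test = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test_log10, dtype=float)
    if len(y) == 0:
        raise ValidationError("empty test set")
    pred = model.predict_log10(X_test)
    err = pred - y
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    assert mae <= rmse + 1e-12, "power-mean inequality violated"
    return EvalReport(
        mae=mae,
        rmse=rmse,
        increment_pct=increment_pct(mae, rmse),
        n_test=len(y),
        degenerate=rmse == 0.0,
    )


# -- statsmodels-style interface ------------------------------------------

class VisualAcuityModel:
    """VA estimator built from a feature table.

    Parameters
    ----------
    X : (n, d) feature matrix (FAZ area + sector densities).
    va_decimal : decimal VA in (0, 1] per consultation.
    feature_names : optional column names; defaults to the standard layout.

    ``fit`` performs the 80/20 split, the cross-validated grid search on
    the training part, refits on the full training part, and evaluates on
    the held-out part.
    """

    def __init__(self, X, va_decimal, feature_names=None,
                 layout: FeatureLayout | None = None):
        self.X = np.asarray(X, dtype=float)
        self.va_decimal = np.asarray(va_decimal, dtype=float)
        if self.X.ndim != 2 or len(self.X) != len(self.va_decimal):
            raise ValidationError("X must be 2-D with one VA per row")
        if np.any((self.va_decimal <= 0) | (self.va_decimal > 1)):
            raise ValidationError("decimal VA values must lie in (0, 1]")
        self.layout = layout or FeatureLayout()
        if feature_names is not None:
            self.feature_names = tuple(feature_names)
        elif self.X.shape[1] == len(self.layout):
            self.feature_names = self.layout.names
        else:
            self.feature_names = tuple(f"x{i}" for i in range(self.X.shape[1]))
        self.y_log10 = va_to_log10(self.va_decimal)

    @classmethod
    def from_feature_table(cls, table: FeatureTable) -> "VisualAcuityModel":
        return cls(table.X, table.va_decimal,
                   feature_names=table.layout.names, layout=table.layout)

    def fit(self, config: SearchConfig | None = None) -> "VAResults":
        config = config or SearchConfig()
        config.validate()
        train_idx, test_idx = split_train_test(len(self.X), config)
        best, cv_table = grid_search_cv(
            self.X[train_idx], self.y_log10[train_idx], config
        )
        model = train(
            self.X[train_idx], self.y_log10[train_idx], best,
            feature_names=self.feature_names, layout=self.layout,
            seed=config.seed,
        )
        report = evaluate(model, self.X[test_idx], self.y_log10[test_idx])
        return VAResults(
            model=self, trained=model, report=report, cv_table=cv_table,
            config=config, train_idx=train_idx, test_idx=test_idx,
        )


@dataclass(frozen=True)
class VAResults:
    """Fit artefacts: trained estimator, CV audit table, held-out report."""

    model: VisualAcuityModel
    trained: TrainedVAModel
    report: EvalReport
    cv_table: pd.DataFrame
    config: SearchConfig
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def params(self) -> dict:
        return self.trained.params

    def predict(self, X, scale: str = "log10") -> np.ndarray:
        if scale == "log10":
            return self.trained.predict_log10(X)
        if scale == "decimal":
            return self.trained.predict_decimal(X)
        raise ParameterError(f"unknown scale {scale!r}")

    def summary(self) -> str:
        lines = [
            "Visual acuity SVR results",
            "=" * 46,
            f"{'n train / n test':<28}{len(self.train_idx)} / {len(self.test_idx)}",
            f"{'features':<28}{len(self.trained.feature_names)}",
            f"{'grid points evaluated':<28}{len(self.cv_table)}",
            f"{'CV folds':<28}{self.config.folds}",
            f"{'selected hyperparameters':<28}"
            + ", ".join(f"{k}={v}" for k, v in self.params.items()),
            f"{'CV MAE (best)':<28}{self.cv_table['cv_mae'].min():.4f}",
            "-" * 46,
            f"{'test MAE  (log10 VA)':<28}{self.report.mae:.4f}",
            f"{'test RMSE (log10 VA)':<28}{self.report.rmse:.4f}",
            f"{'RMSE-over-MAE increment':<28}{self.report.increment_pct:.2f}%",
            "=" * 46,
        ]
        return "\n".join(lines)
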