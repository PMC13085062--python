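"""Cross-validated 6MWD regression and agreement analysis.

Five regressor families (random forest, linear regression, RBF support
vector machine, and two gradient-boosting variants) are compared with a
nested scheme: a seeded, shuffled outer 5-fold split, and a 3-fold grid
search over a small documented hyperparameter grid inside each training
fold.  Metrics (R², MAE) and the Bland–Altman agreement statistics are
computed on the pooled out-of-fold predictions, which supplies exactly
one prediction per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "MODEL_REGISTRY",
    "BlandAltmanStats",
    "EvalReport",
    "r_squared",
    "mean_absolute_error",
    "bland_altman",
    "crossval_evaluate",
]


def _model_registry() -> dict[str, tuple[object, dict]]:
    """Estimator factory + hyperparameter grid per model family.

    Grids are deliberately small: tuning is per training fold, and the
    grids bound the search space so runs are reproducible at desk scale.
    """
    from lightgbm import LGBMRegressor
    from xgboost import XGBRegressor

    return {
        "rf": (
            RandomForestRegressor(random_state=0),
            {"model__n_estimators": [200, 500], "model__max_depth": [None, 6]},
        ),
        "lr": (LinearRegression(), {}),
        "svm": (
            SVR(kernel="rbf", gamma="scale"),
            {"model__C": [1.0, 10.0, 100.0]},
        ),
        "xgb": (
            XGBRegressor(random_state=0, n_estimators=300, verbosity=0),
            {"model__learning_rate": [0.05, 0.1], "model__max_depth": [3, 6]},
        ),
        "lgbm": (
            LGBMRegressor(
                random_state=0, n_estimators=300, min_child_samples=5, verbose=-1
            ),
            {"model__learning_rate": [0.05, 0.1]},
        ),
    }


MODEL_REGISTRY = ("rf", "lr", "svm", "xgb", "lgbm")


def r_squared(pred: np.ndarray, actual: np.ndarray) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (SS_tot about the
    actual mean)."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.size < 2:
        raise ValueError("pred and actual must be equal-length with >= 2 entries")
    ss_res = float(np.sum((actual - pred) ** 2))
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual values are constant; R² undefined")
    return 1.0 - ss_res / ss_tot


def mean_absolute_error(pred: np.ndarray, actual: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have equal length")
    return float(np.mean(np.abs(pred - actual)))


@dataclass(frozen=True)
class BlandAltmanStats:
    """Agreement between predicted and measured 6MWD (metres)."""

    bias: float  # mean of predicted − actual
    sd_diff: float  # SD of differences, n−1 denominator
    loa_low: float  # bias − 1.96·sd_diff
    loa_high: float  # bias + 1.96·sd_diff

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def bland_altman(pred: np.ndarray, actual: np.ndarray) -> BlandAltmanStats:
    """Bland–Altman limits of agreement from paired predictions.

    Differences d = pred − actual; limits of agreement are
    bias ± 1.96·SD(d) with the n−1 SD denominator, the interval expected
    to contain ~95% of differences under normality.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape or pred.size < 2:
        raise ValueError("need >= 2 paired values")
    d = pred - actual
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanStats(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


@dataclass
class ModelResult:
    r2: float
    mae: float
    oof_pred: np.ndarray
    fold_params: list[dict]
    bland_altman: BlandAltmanStats


@dataclass
class EvalReport:
    """Cross-validation outcome for every model family."""

    models: dict[str, ModelResult] = field(default_factory=dict)
    fold_assignment: np.ndarray | None = None  # test-fold index per subject
    actual: np.ndarray | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "fold_assignment": self.fold_assignment.tolist(),
            "models": {
                name: {
                    "r2": res.r2,
                    "mae": res.mae,
                    "oof_pred": res.oof_pred.tolist(),
                    "fold_params": res.fold_params,
                    "bland_altman": res.bland_altman.to_dict(),
                }
                for name, res in self.models.items()
            },
        }


def crossval_evaluate(
    table: pd.DataFrame,
    models: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    inner_folds: int = 3,
) -> EvalReport:
    """Nested cross-validated comparison of the requested model families.

    Outer folds are a seeded shuffled partition of the subjects; inside
    each training fold a grid search (``inner_folds``-fold) picks the
    hyperparameters used to predict the held-out fold.  Standardization is
    fit inside each training fold (pipeline), preventing leakage.
    """
    models = list(models) if models else list(MODEL_REGISTRY)
    registry = _model_registry()
    unknown = [m for m in models if m not in registry]
    if unknown:
        raise ValueError(f"unknown model id(s): {unknown}")
    feats = [c for c in table.columns if c not in ("subject_id", "distance")]
    if "distance" not in table.columns:
        raise KeyError("table has no 'distance' column")
    X = table[feats].to_numpy(dtype=float)
    y = table["distance"].to_numpy(dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in features or distance")
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least {folds} subjects for {folds}-fold CV")

    outer = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_assignment = np.empty(n, dtype=int)
    splits = list(outer.split(X))
    for k, (_, test_idx) in enumerate(splits):
        fold_assignment[test_idx] = k

    report = EvalReport(fold_assignment=fold_assignment, actual=y.copy(), seed=seed)
    for name in models:
        base, grid = registry[name]
        oof = np.empty(n, dtype=float)
        fold_params: list[dict] = []
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper records feature names even for
            # ndarray input, tripping a spurious validation warning
            warnings.filterwarnings(
                "ignore", message=".*does not have valid feature names.*"
            )
            _run_folds(splits, X, y, base, grid, inner_folds, seed, oof, fold_params)
        report.models[name] = ModelResult(
            r2=r_squared(oof, y),
            mae=mean_absolute_error(oof, y),
            oof_pred=oof,
            fold_params=fold_params,
            bland_altman=bland_altman(oof, y),
        )
    return report


def _run_folds(splits, X, y, base, grid, inner_folds, seed, oof, fold_params):
    for train_idx, test_idx in splits:
        pipe = Pipeline([("scale", StandardScaler()), ("model", base)])
        if grid:
            search = GridSearchCV(
                pipe,
                grid,
                cv=KFold(inner_folds, shuffle=True, random_state=seed),
                scoring="neg_mean_absolute_error",
                n_jobs=1,
            )
            search.fit(X[train_idx], y[train_idx])
            best = search.best_estimator_
            fold_params.append(dict(search.best_params_))
        else:
            best = pipe.fit(X[train_idx], y[train_idx])
            fold_params.append({})
        oof[test_idx] = best.predict(X[test_idx])
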