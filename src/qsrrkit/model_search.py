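"""Automated model building: randomization, scaling, RFE feature selection,
nested cross-validated learner/hyperparameter selection, outer-CV reporting,
and the final fit.

The training pipeline, applied identically inside every cross-validation
fold and for the final model, is::

    median imputation -> per-feature standardization -> recursive feature
    elimination (random-forest importance, inner-CV choice of subset size)
    -> learner search (linear / random forest / rbf-SVR grid) -> fit

Nothing computed from held-out rows ever enters the pipeline: imputation
medians, scaler statistics, the selected feature subset and the chosen
hyperparameters are all derived from fold-training rows only.

Candidate learners mirror common QSRR practice: ordinary linear regression,
a 500-tree random forest, and support vector regression with an rbf kernel
whose ``C`` (error penalty) and ``gamma`` (kernel width) are grid-searched
over 7 log-spaced values each spanning [0.001, 1000].  The winner is the
candidate with the best mean inner-CV r-squared; ties fall to lower mean
inner-CV absolute error, then to the simplicity order
linear < svr < random forest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE, RFECV
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import __version__
from .compound_io import CompoundTable
from .descriptors import apply_imputer, fit_imputer
from .errors import (
    DegenerateTargetError,
    InsufficientDataError,
    ValidationError,
)

MIN_TRAINING_ROWS = 10

#: tie-break order when inner-CV scores are identical (simpler first)
_SIMPLICITY = {"linear": 0, "svr": 1, "random_forest": 2}


@dataclass(frozen=True)
class SearchConfig:
    """Settings for feature selection and model search.

    Defaults reproduce the reference workflow: 5-fold outer CV, 5-fold inner
    CV, 500-tree random forests (both for feature ranking and as a
    candidate), and an rbf-SVR grid with C and gamma between 0.001 and 1000.
    """

    method: str = "auto"  # auto | linear | random_forest | svr
    outer_folds: int = 5
    inner_folds: int = 5
    rf_trees: int = 500
    svr_c_bounds: tuple[float, float] = (1e-3, 1e3)
    svr_gamma_bounds: tuple[float, float] = (1e-3, 1e3)
    grid_points: int = 7
    rfe_step: float = 0.1
    forced_n_features: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("auto", "linear", "random_forest", "svr"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValidationError("fold counts must be >= 2")
        for name in ("svr_c_bounds", "svr_gamma_bounds"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be positive with low <= high")
        if self.forced_n_features is not None and self.forced_n_features < 1:
            raise ValidationError("forced_n_features must be >= 1")
        if self.rf_trees < 1 or self.grid_points < 1:
            raise ValidationError("rf_trees and grid_points must be >= 1")


@dataclass
class TrainedModel:
    """Everything needed to predict retention times without the training data."""

    learner_kind: str
    hyperparameters: dict
    feature_means: pd.Series
    feature_sds: pd.Series
    imputation: pd.Series
    selected_features: list[str]
    train_rt_min: float
    train_rt_max: float
    seed: int
    estimator: object
    config: Optional[dict] = None
    version: str = __version__

    def predict_matrix(self, matrix: pd.DataFrame) -> pd.Series:
        """Predict retention times (minutes) from a descriptor matrix.

        Replays the training pipeline: restrict to the selected features,
        impute with training medians, standardize with training statistics,
        apply the learner.
        """
        missing = [c for c in self.selected_features if c not in matrix.columns]
        if missing:
            raise ValidationError(f"descriptor matrix lacks selected feature(s): {missing}")
        X = matrix[self.selected_features]
        X = apply_imputer(self.imputation, X)
        Z = (X - self.feature_means) / self.feature_sds
        preds = self.estimator.predict(Z.to_numpy())
        return pd.Series(preds, index=matrix.index, name="predicted_rt")


@dataclass
class CVReport:
    """Per-fold and aggregate outer-CV performance."""

    fold_r2: list[float] = field(default_factory=list)
    fold_mae: list[float] = field(default_factory=list)
    fold_learner: list[str] = field(default_factory=list)
    fold_n_features: list[int] = field(default_factory=list)
    # per-fold training-scaler statistics, for leakage auditing
    fold_scaler_means: list[pd.Series] = field(default_factory=list)
    fold_scaler_sds: list[pd.Series] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.fold_r2)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def median_r2(self) -> float:
        return float(np.median(self.fold_r2))

    @property
    def mean_mae(self) -> float:
        return float(np.mean(self.fold_mae))

    @property
    def mae_sd(self) -> float:
        return float(np.std(self.fold_mae, ddof=1)) if self.n_folds > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": range(self.n_folds),
                "r2": self.fold_r2,
                "mae_min": self.fold_mae,
                "learner": self.fold_learner,
                "n_features": self.fold_n_features,
            }
        )

    def summary(self) -> str:
        return (
            f"outer CV ({self.n_folds} folds): mean r2 = {self.mean_r2:.4f}, "
            f"median r2 = {self.median_r2:.4f}, "
            f"mean MAE = {self.mean_mae:.4f} min (sd {self.mae_sd:.4f}); "
            f"learners: {', '.join(self.fold_learner)}"
        )


# ---------------------------------------------------------------------------
# order randomization


def permutation_for(n: int, seed: int) -> np.ndarray:
    """The seeded row permutation used everywhere rows are shuffled."""
    return np.random.default_rng(seed).permutation(n)


def randomize_order(table: CompoundTable, seed: int) -> CompoundTable:
    """Seeded shuffle of a compound table's rows."""
    perm = permutation_for(len(table), seed)
    names = [table.names[i] for i in perm]
    return table.subset(names)


def randomize_xy(X: pd.DataFrame, y: pd.Series, seed: int) -> tuple[pd.DataFrame, pd.Series]:
    """Seeded joint shuffle of a descriptor matrix and its target vector."""
    perm = permutation_for(len(X), seed)
    return X.iloc[perm], y.iloc[perm]


# ---------------------------------------------------------------------------
# pipeline stages


def _check_rows_target(X: pd.DataFrame, y: pd.Series) -> None:
    if len(X) < MIN_TRAINING_ROWS:
        raise InsufficientDataError(
            f"need at least {MIN_TRAINING_ROWS} training rows, got {len(X)}"
        )
    if np.ptp(y.to_numpy()) == 0:
        raise DegenerateTargetError("retention-time target is constant")


def _ranking_forest(cfg: SearchConfig) -> RandomForestRegressor:
    return RandomForestRegressor(n_estimators=cfg.rf_trees, random_state=cfg.seed % (2**31))


def select_features(Z: pd.DataFrame, y: pd.Series, cfg: SearchConfig) -> list[str]:
    """Choose a descriptor subset by recursive feature elimination.

    Features are ranked by random-forest importance and eliminated in steps
    of ``rfe_step`` (a fraction of the feature count); with
    ``forced_n_features`` unset, an ``inner_folds``-fold CV picks the subset
    size minimising mean absolute error, otherwise elimination runs to
    exactly that count.
    """
    _check_rows_target(Z, y)
    cols = list(Z.columns)
    if len(cols) == 1:
        return cols
    if cfg.forced_n_features is not None:
        if cfg.forced_n_features >= len(cols):
            return cols
        selector = RFE(
            _ranking_forest(cfg),
            n_features_to_select=cfg.forced_n_features,
            step=cfg.rfe_step,
        )
    else:
        selector = RFECV(
            _ranking_forest(cfg),
            step=cfg.rfe_step,
            cv=KFold(n_splits=cfg.inner_folds),
            scoring="neg_mean_absolute_error",
            min_features_to_select=1,
        )
    selector.fit(Z.to_numpy(), y.to_numpy())
    selected = [c for c, keep in zip(cols, selector.support_) if keep]
    assert selected, "feature selection returned an empty subset"
    return selected


def _make_estimator(kind: str, params: dict, cfg: SearchConfig):
    if kind == "linear":
        return LinearRegression()
    if kind == "random_forest":
        return RandomForestRegressor(
            n_estimators=params.get("n_estimators", cfg.rf_trees),
            random_state=cfg.seed % (2**31),
        )
    if kind == "svr":
        return SVR(kernel="rbf", C=params["C"], gamma=params["gamma"])
    raise ValidationError(f"unknown learner kind {kind!r}")


def _inner_cv_scores(estimator, Z: np.ndarray, y: np.ndarray, folds: int) -> tuple[float, float]:
    """Mean inner-CV (r2, MAE) over contiguous folds."""
    r2s, maes = [], []
    for tr, te in KFold(n_splits=folds).split(Z):
        est = clone(estimator)
        est.fit(Z[tr], y[tr])
        pred = est.predict(Z[te])
        r2s.append(r2_score(y[te], pred))
        maes.append(mean_absolute_error(y[te], pred))
    return float(np.mean(r2s)), float(np.mean(maes))


def _svr_grid(cfg: SearchConfig) -> list[dict]:
    cs = np.geomspace(*cfg.svr_c_bounds, num=cfg.grid_points)
    gammas = np.geomspace(*cfg.svr_gamma_bounds, num=cfg.grid_points)
    return [{"C": float(c), "gamma": float(g)} for c in cs for g in gammas]


def _pick_winner(rows: list[dict]) -> dict:
    """Best mean r2; ties to lower mean MAE, then to simplicity order."""
    best = rows[0]
    for row in rows[1:]:
        if row["mean_r2"] > best["mean_r2"]:
            best = row
        elif row["mean_r2"] == best["mean_r2"]:
            if row["mean_mae"] < best["mean_mae"]:
                best = row
            elif row["mean_mae"] == best["mean_mae"] and (
                _SIMPLICITY[row["learner"]] < _SIMPLICITY[best["learner"]]
            ):
                best = row
    return best


def search_model(
    Z: pd.DataFrame, y: pd.Series, cfg: SearchConfig
) -> tuple[str, dict, pd.DataFrame]:
    """Select the learner (and SVR hyperparameters) by inner-CV grid search.

    ``Z`` must already be scaled and feature-selected using the calling
    fold's training rows only.  Returns the winning learner kind, its
    hyperparameters, and the full inner-CV score table.
    """
    if np.ptp(y.to_numpy()) == 0:
        raise DegenerateTargetError("retention-time target is constant")
    Za, ya = Z.to_numpy(), y.to_numpy()
    folds = cfg.inner_folds
    rows: list[dict] = []

    def consider(kind: str, params: dict) -> dict:
        r2, mae = _inner_cv_scores(_make_estimator(kind, params, cfg), Za, ya, folds)
        row = {"learner": kind, **params, "mean_r2": r2, "mean_mae": mae}
        rows.append(row)
        return row

    candidates: list[dict] = []
    if cfg.method in ("auto", "linear"):
        candidates.append(consider("linear", {}))
    if cfg.method in ("auto", "svr"):
        cells = [consider("svr", p) for p in _svr_grid(cfg)]
        candidates.append(_pick_winner(cells))
    if cfg.method in ("auto", "random_forest"):
        candidates.append(consider("random_forest", {"n_estimators": cfg.rf_trees}))

    winner = _pick_winner(candidates)
    params = {k: v for k, v in winner.items() if k not in ("learner", "mean_r2", "mean_mae")}
    return winner["learner"], params, pd.DataFrame(rows)


@dataclass
class _FittedPipeline:
    """Internal: one fully-fitted pipeline (fold or final)."""

    imputation: pd.Series
    means: pd.Series  # over selected features
    sds: pd.Series
    selected_features: list[str]
    learner_kind: str
    hyperparameters: dict
    estimator: object
    # full pre-selection scaler statistics, kept for leakage audits
    all_means: pd.Series
    all_sds: pd.Series

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xs = apply_imputer(self.imputation, X[self.selected_features])
        Z = (Xs - self.means) / self.sds
        return self.estimator.predict(Z.to_numpy())


def _fit_pipeline(X: pd.DataFrame, y: pd.Series, cfg: SearchConfig) -> _FittedPipeline:
    _check_rows_target(X, y)
    medians = fit_imputer(X)
    Xi = apply_imputer(medians, X)
    means = Xi.mean(axis=0)
    sds = Xi.std(axis=0, ddof=0)
    usable = list(sds.index[sds > 0])  # fold-constant columns carry no information
    if not usable:
        raise ValidationError("every descriptor is constant on the training rows")
    Z = (Xi[usable] - means[usable]) / sds[usable]

    selected = select_features(Z, y, cfg)
    kind, params, _ = search_model(Z[selected], y, cfg)
    estimator = _make_estimator(kind, params, cfg)
    estimator.fit(Z[selected].to_numpy(), y.to_numpy())
    return _FittedPipeline(
        imputation=medians[selected],
        means=means[selected],
        sds=sds[selected],
        selected_features=selected,
        learner_kind=kind,
        hyperparameters=params,
        estimator=estimator,
        all_means=means[usable],
        all_sds=sds[usable],
    )


def outer_cv(X: pd.DataFrame, y: pd.Series, cfg: SearchConfig) -> CVReport:
    """Score the whole pipeline with an outer cross-validation.

    Folds are contiguous blocks of the (already randomized) row order; the
    entire pipeline is refit on each fold's training rows and scored on its
    held-out rows.
    """
    if len(X) < cfg.outer_folds:
        raise InsufficientDataError(
            f"need at least outer_folds={cfg.outer_folds} rows, got {len(X)}"
        )
    report = CVReport()
    for tr, te in KFold(n_splits=cfg.outer_folds).split(X):
        pipe = _fit_pipeline(X.iloc[tr], y.iloc[tr], cfg)
        pred = pipe.predict(X.iloc[te])
        report.fold_r2.append(float(r2_score(y.iloc[te], pred)))
        report.fold_mae.append(float(mean_absolute_error(y.iloc[te], pred)))
        report.fold_learner.append(pipe.learner_kind)
        report.fold_n_features.append(len(pipe.selected_features))
        report.fold_scaler_means.append(pipe.all_means)
        report.fold_scaler_sds.append(pipe.all_sds)
    return report


def fit_final(X: pd.DataFrame, y: pd.Series, cfg: SearchConfig) -> TrainedModel:
    """Refit the full pipeline on all rows and package it for standalone use."""
    pipe = _fit_pipeline(X, y, cfg)
    return TrainedModel(
        learner_kind=pipe.learner_kind,
        hyperparameters=pipe.hyperparameters,
        feature_means=pipe.means,
        feature_sds=pipe.sds,
        imputation=pipe.imputation,
        selected_features=pipe.selected_features,
        train_rt_min=float(y.min()),
        train_rt_max=float(y.max()),
        seed=cfg.seed,
        estimator=pipe.estimator,
        config=dataclasses.asdict(cfg),
    )


def train(
    X: pd.DataFrame, y: pd.Series, cfg: SearchConfig
) -> tuple[TrainedModel, CVReport]:
    """Randomize row order, run the outer CV, then fit the final model.

    ``X`` must already be descriptor-filtered; ``y`` is retention time in
    minutes, aligned with ``X``'s rows.
    """
    Xr, yr = randomize_xy(X, y, cfg.seed)
    report = outer_cv(Xr, yr, cfg)
    model = fit_final(Xr, yr, cfg)
    return model, report
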