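"""Experimental protocols: randomized train/test splits, replicate models,
training-set-size series, and feature-usage consistency summaries.

The canonical protocol is: shuffle the data, take the first 75% (or a fixed
compound count) as the training set and the rest as the test set; build
several replicate models per split; exclude test compounds whose observed
retention time falls outside the training window; evaluate each model on
its split's surviving test compounds.  Replicates within a split share the
test set and differ only through seed-derived randomness.

Seeds are fully deterministic: split ``s`` shuffles with
``base_seed + 1000*s`` and replicate ``r`` of split ``s`` trains with
``base_seed + 1000*s + r``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .descriptors import FilterConfig, apply_filters
from .errors import ValidationError
from .model_search import SearchConfig, fit_final, permutation_for
from .prediction import EvaluationReport, evaluate, exclude_extrapolated


@dataclass(frozen=True)
class SplitPlan:
    """How to build randomized train/test splits."""

    n_splits: int = 5
    train_fraction: Optional[float] = 0.75
    train_n: Optional[int] = None  # absolute training size; overrides train_fraction
    replicates: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 1 or self.replicates < 1:
            raise ValidationError("n_splits and replicates must be >= 1")
        if self.train_n is None:
            if self.train_fraction is None or not (0 < self.train_fraction < 1):
                raise ValidationError("train_fraction must be in (0, 1) when train_n is unset")
        elif self.train_n < 1:
            raise ValidationError("train_n must be >= 1")

    def split_seed(self, split: int) -> int:
        return self.base_seed + 1000 * split

    def model_seed(self, split: int, replicate: int) -> int:
        return self.base_seed + 1000 * split + replicate

    def train_size(self, n: int) -> int:
        if self.train_n is not None:
            if not (1 <= self.train_n < n):
                raise ValidationError(f"train_n={self.train_n} must be in [1, {n})")
            return self.train_n
        size = int(np.ceil(self.train_fraction * n))
        if size >= n:
            raise ValidationError("split leaves an empty test set")
        return size


def make_splits(n: int, plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index splits: each is a fresh seeded shuffle cut at the training size."""
    size = plan.train_size(n)
    splits = []
    for s in range(plan.n_splits):
        perm = permutation_for(n, plan.split_seed(s))
        splits.append((perm[:size], perm[size:]))
    return splits


@dataclass
class ModelRunRecord:
    """Bookkeeping for one split x replicate model."""

    split: int
    replicate: int
    learner_kind: str
    n_features: int
    selected_features: list[str]
    test_mae: float  # mean |pred - obs| on the surviving test compounds, minutes
    report: EvaluationReport


@dataclass
class ProtocolResult:
    """All replicate evaluations plus the cross-model feature-usage summary."""

    runs: list[ModelRunRecord] = field(default_factory=list)
    failures: list[tuple[int, int, str]] = field(default_factory=list)  # (split, rep, reason)

    @property
    def reports(self) -> list[EvaluationReport]:
        return [r.report for r in self.runs]

    @property
    def feature_usage(self) -> pd.Series:
        """Per descriptor: in how many models it was selected."""
        counts: dict[str, int] = {}
        for run in self.runs:
            for name in run.selected_features:
                counts[name] = counts.get(name, 0) + 1
        return pd.Series(counts, dtype=int).sort_values(ascending=False)

    def mean_test_mae(self) -> float:
        """Mean over models of each model's mean absolute test error (minutes)."""
        return float(np.mean([run.test_mae for run in self.runs]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for run in self.runs:
            row = {
                "split": run.split,
                "replicate": run.replicate,
                "learner": run.learner_kind,
                "n_features": run.n_features,
                "test_mae": run.test_mae,
            }
            row.update(vars(run.report))
            rows.append(row)
        return pd.DataFrame(rows)


def run_protocol(
    X: pd.DataFrame,
    y: pd.Series,
    plan: SplitPlan,
    search_cfg: SearchConfig | None = None,
    filter_cfg: FilterConfig | None = None,
) -> ProtocolResult:
    """Run the full split/replicate protocol on a descriptor matrix.

    For every split x replicate: descriptor filters and the whole training
    pipeline are fit on the training rows only; test compounds outside the
    training retention window are excluded; the survivors are predicted and
    evaluated.  A failed replicate is recorded in ``failures``, never
    silently dropped.
    """
    if y.isna().any():
        raise ValidationError("protocol requires a retention time for every compound")
    search_cfg = search_cfg or SearchConfig()
    result = ProtocolResult()
    for s, (train_idx, test_idx) in enumerate(make_splits(len(X), plan)):
        X_tr, y_tr = X.iloc[train_idx], y.iloc[train_idx]
        X_te, y_te = X.iloc[test_idx], y.iloc[test_idx]
        for r in range(plan.replicates):
            cfg = dataclasses.replace(search_cfg, seed=plan.model_seed(s, r))
            try:
                X_trf, _ = apply_filters(X_tr, filter_cfg)
                model = fit_final(X_trf, y_tr, cfg)
                kept_obs, excluded = exclude_extrapolated(
                    y_te, model.train_rt_min, model.train_rt_max
                )
                preds = model.predict_matrix(X_te.loc[kept_obs.index])
                report = evaluate(preds, kept_obs, n_excluded=len(excluded))
                result.runs.append(
                    ModelRunRecord(
                        split=s,
                        replicate=r,
                        learner_kind=model.learner_kind,
                        n_features=len(model.selected_features),
                        selected_features=list(model.selected_features),
                        test_mae=float((preds - kept_obs).abs().mean()),
                        report=report,
                    )
                )
            except Exception as exc:
                result.failures.append((s, r, f"{type(exc).__name__}: {exc}"))
    return result


def training_size_series(
    X: pd.DataFrame,
    y: pd.Series,
    train_sizes: list[int],
    plan: SplitPlan,
    search_cfg: SearchConfig | None = None,
    filter_cfg: FilterConfig | None = None,
) -> dict[int, ProtocolResult]:
    """Repeat the protocol at several absolute training-set sizes.

    Compounds not used for training move to the test set, so smaller
    training sets are scored on more predictions.
    """
    out = {}
    for size in train_sizes:
        sized = dataclasses.replace(plan, train_n=size, train_fraction=None)
        out[size] = run_protocol(X, y, sized, search_cfg, filter_cfg)
    return out
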