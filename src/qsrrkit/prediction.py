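"""Prediction on new compounds, exclusion filters, and evaluation statistics.

Evaluation follows chromatographic QSRR conventions:

* the best-fit line regresses *predicted* retention time (ordinate) on
  *measured* retention time (abscissa), so a perfect model gives
  y = x with r2 = 1;
* signed errors are ``predicted - observed`` minutes; percent errors are
  relative to the observed time;
* test compounds whose *observed* time falls outside the training-set
  retention window are excluded before scoring (extrapolated predictions
  are unreliable); at prediction time, where no observed value exists, the
  flag is instead raised when the *predicted* time leaves the training
  window — both behaviours are exposed;
* the relative-error validity filter drops a prediction when its percent
  error strictly exceeds ``max_pct`` (default 35%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compound_io import CompoundTable
from .descriptors import DescriptorFailure, compute_descriptors
from .errors import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from .model_search import TrainedModel


@dataclass(frozen=True)
class PredictionResult:
    """One predicted compound."""

    name: str
    predicted_rt: float  # minutes
    extrapolation_flag: bool


@dataclass
class EvaluationReport:
    """Agreement between predicted and measured retention times."""

    slope: float
    intercept: float
    r2: float
    median_error: float  # minutes, signed
    median_pct_error: float  # percent, signed
    frac_within_1min: float
    frac_within_2min: float
    n_used: int
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])

    def summary(self) -> str:
        return (
            f"fit: pred = {self.slope:.4f}*obs + {self.intercept:.4f}, r2 = {self.r2:.4f}; "
            f"median error {self.median_error:+.3f} min ({self.median_pct_error:+.2f}%); "
            f"{100 * self.frac_within_1min:.0f}% within 1 min, "
            f"{100 * self.frac_within_2min:.0f}% within 2 min "
            f"(n = {self.n_used}, excluded {self.n_excluded})"
        )


def predict(
    model: TrainedModel,
    table: CompoundTable,
    matrix: Optional[pd.DataFrame] = None,
) -> tuple[list[PredictionResult], list[DescriptorFailure]]:
    """Predict retention times for every compound in ``table``.

    Descriptors are calculated from SMILES unless a precomputed ``matrix``
    is supplied.  Compounds whose descriptors cannot be computed are
    reported and skipped, not fatal.  The extrapolation flag marks
    predictions outside the model's training retention-time window.
    """
    if matrix is None:
        matrix, failures = compute_descriptors(table)
    else:
        failures = []
    preds = model.predict_matrix(matrix)
    results = [
        PredictionResult(
            name=str(name),
            predicted_rt=float(p),
            extrapolation_flag=not (model.train_rt_min <= p <= model.train_rt_max),
        )
        for name, p in preds.items()
    ]
    return results, failures


def predictions_frame(results: Sequence[PredictionResult], table: CompoundTable) -> pd.DataFrame:
    """Prediction output table: name, SMILES, predicted rt, extrapolation flag."""
    smiles = {r.name: r.smiles for r in table.records}
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "smiles": [smiles.get(r.name, "") for r in results],
            "predicted_rt": [r.predicted_rt for r in results],
            "extrapolation_flag": [r.extrapolation_flag for r in results],
        }
    )


def exclude_extrapolated(
    observed: pd.Series, train_rt_min: float, train_rt_max: float
) -> tuple[pd.Series, pd.Series]:
    """Partition observed retention times into (kept, excluded).

    Excluded iff the observed time is strictly outside
    [train_rt_min, train_rt_max]; boundary-equal values are kept.
    """
    if observed.isna().any():
        raise ValidationError("observed retention times must all be present")
    outside = (observed < train_rt_min) | (observed > train_rt_max)
    return observed[~outside], observed[outside]


def filter_relative_error(
    predicted: pd.Series, observed: pd.Series, max_pct: float = 35.0
) -> pd.Series:
    """Boolean keep-mask: drop iff percent error strictly exceeds ``max_pct``.

    Percent error is 100*|pred - obs| / obs; observed must be positive.
    """
    predicted, observed = _align(predicted, observed)
    bad = observed[~(observed > 0)]
    if len(bad):
        raise ValidationError(
            f"observed retention time must be > 0; offending: {list(bad.index)}"
        )
    pct = 100.0 * (predicted - observed).abs() / observed
    return pct <= max_pct


def _align(predicted: pd.Series, observed: pd.Series) -> tuple[pd.Series, pd.Series]:
    if len(predicted) != len(observed):
        raise ValidationError(
            f"predicted ({len(predicted)}) and observed ({len(observed)}) lengths differ"
        )
    return predicted.astype(float), observed.astype(float)


def evaluate(
    predicted: pd.Series, observed: pd.Series, n_excluded: int = 0
) -> EvaluationReport:
    """Score predictions against measurements.

    Ordinary least squares of predicted on measured; r2 is the squared
    Pearson correlation; median error is median(pred - obs); band fractions
    count |pred - obs| <= 1 and <= 2 minutes.
    """
    predicted, observed = _align(predicted, observed)
    if len(predicted) < 3:
        raise InsufficientDataError("evaluation needs at least 3 paired values")
    if np.ptp(observed.to_numpy()) == 0:
        raise UndefinedStatisticError("observed retention times have zero variance; fit undefined")
    fit = stats.linregress(observed.to_numpy(), predicted.to_numpy())
    err = predicted.to_numpy() - observed.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * err / observed.to_numpy()
    return EvaluationReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        median_error=float(np.median(err)),
        median_pct_error=float(np.median(pct)),
        frac_within_1min=float(np.mean(np.abs(err) <= 1.0)),
        frac_within_2min=float(np.mean(np.abs(err) <= 2.0)),
        n_used=len(predicted),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# t-tests (textbook Student formulas; p-values from the t distribution)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired two-sided Student t-test on equal-length samples.

    Identical samples (all differences zero) return (0, 1); constant
    nonzero differences leave the statistic undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"paired samples must have equal length ({len(a)} vs {len(b)})")
    n = len(a)
    if n < 3:
        raise InsufficientDataError("paired t-test needs at least 3 pairs")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        raise UndefinedStatisticError("differences have zero variance and nonzero mean")
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def unpaired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-sided Student t-test with pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 3 or nb < 3:
        raise InsufficientDataError("unpaired t-test needs at least 3 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise UndefinedStatisticError("both samples have zero variance")
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = (a.mean() - b.mean()) / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(p)
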