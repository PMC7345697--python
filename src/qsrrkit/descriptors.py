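"""Molecular descriptors from SMILES, and descriptor hygiene.

Descriptors are the full 2-D descriptor set shipped with RDKit (~210
constitutional, topological, and electrotopological quantities; no
conformers, no fingerprint bit-vectors).  The Wildman–Crippen octanol/water
partition coefficient is exposed under its usual field name ``SLogP``.

Before modeling, three filters are applied, in this order:

1. *high-missing* — drop a descriptor when the fraction of missing cells is
   at or above ``missing_fraction`` (default 0.75);
2. *near-constant* — drop when the modal non-missing value covers at least
   ``dup_fraction`` of compounds (default 0.90);
3. *correlated* — a greedy scan in column order that drops a descriptor
   when its absolute Pearson correlation with an already-kept descriptor is
   at or above ``corr_threshold`` (default 0.90); the earlier column wins.

All three boundaries are inclusive ("0.9 or more" drops).  Correlations use
pairwise-complete observations with at least 3 shared points.  Residual
missing cells after filtering are imputed with training-column medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors as _RDDescriptors

from .compound_io import CompoundTable
from .errors import DescriptorError, ValidationError

RDLogger.DisableLog("rdApp.*")

#: RDKit descriptor names whose conventional field name differs.
_RENAMES = {"MolLogP": "SLogP"}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the three descriptor filters; all in (0, 1], inclusive drop."""

    dup_fraction: float = 0.90
    missing_fraction: float = 0.75
    corr_threshold: float = 0.90

    def __post_init__(self) -> None:
        for name in ("dup_fraction", "missing_fraction", "corr_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")


@dataclass
class FilterReport:
    """Which descriptors were dropped, and why (exactly one reason each)."""

    dropped: dict[str, str] = field(default_factory=dict)
    kept: list[str] = field(default_factory=list)

    @property
    def kept_count(self) -> int:
        return len(self.kept)

    def by_reason(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, reason in self.dropped.items():
            key = reason.split("(")[0]
            out.setdefault(key, []).append(name)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(n, "dropped", r) for n, r in self.dropped.items()]
        rows += [(n, "kept", "") for n in self.kept]
        return pd.DataFrame(rows, columns=["descriptor", "status", "reason"])


@dataclass
class DescriptorFailure:
    name: str
    smiles: str
    reason: str


def compute_descriptors(
    table: CompoundTable,
) -> tuple[pd.DataFrame, list[DescriptorFailure]]:
    """Compute 2-D descriptors for every compound in ``table``.

    Returns a compounds x descriptors DataFrame (NaN marks a missing value)
    and the list of compounds whose SMILES could not be parsed; those are
    excluded from the matrix.  User-supplied ``extra_descriptors`` are
    merged in, taking precedence over calculated columns of the same name.

    Raises :class:`DescriptorError` if every compound fails.
    """
    rows: dict[str, dict[str, float]] = {}
    failures: list[DescriptorFailure] = []
    for rec in table.records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            failures.append(DescriptorFailure(rec.name, rec.smiles, "unparseable SMILES"))
            continue
        try:
            values = _RDDescriptors.CalcMolDescriptors(mol)
        except Exception as exc:  # pragma: no cover - backend failure
            failures.append(DescriptorFailure(rec.name, rec.smiles, f"descriptor backend error: {exc}"))
            continue
        rows[rec.name] = {
            _RENAMES.get(k, k): _as_float_or_nan(v) for k, v in values.items()
        }
    if not rows:
        raise DescriptorError(
            "descriptor calculation failed for every compound: "
            + "; ".join(f"{f.name}: {f.reason}" for f in failures)
        )
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix = matrix.loc[[r.name for r in table.records if r.name in rows]]

    if table.extra_descriptors is not None:
        extra = table.extra_descriptors.loc[matrix.index]
        # user columns take precedence on a name collision
        calculated = matrix.drop(columns=[c for c in extra.columns if c in matrix.columns])
        matrix = pd.concat([calculated, extra], axis=1)
    return matrix, failures


def _as_float_or_nan(value) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        return float("nan")
    return v if math.isfinite(v) else float("nan")


def drop_high_missing(
    matrix: pd.DataFrame, missing_fraction: float = 0.75
) -> tuple[pd.DataFrame, list[str]]:
    """Drop descriptors whose missing-cell fraction is >= ``missing_fraction``."""
    frac = matrix.isna().mean(axis=0)
    dropped = list(frac.index[frac >= missing_fraction])
    return matrix.drop(columns=dropped), dropped


def drop_near_constant(
    matrix: pd.DataFrame, dup_fraction: float = 0.90
) -> tuple[pd.DataFrame, list[str]]:
    """Drop descriptors whose modal non-missing value covers >= ``dup_fraction`` of compounds.

    The denominator is the number of compounds, so heavily-missing columns
    are not near-constant by this rule alone (the missing filter owns them).
    """
    n = len(matrix)
    dropped = []
    for col in matrix.columns:
        counts = matrix[col].value_counts(dropna=True)
        modal = int(counts.iloc[0]) if len(counts) else 0
        if n > 0 and modal / n >= dup_fraction:
            dropped.append(col)
    return matrix.drop(columns=dropped), dropped


def drop_correlated(
    matrix: pd.DataFrame, corr_threshold: float = 0.90
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Greedy correlation pruning in column order.

    Scans descriptors left to right, keeping a set of survivors; a candidate
    is dropped — recording the first offending kept partner — iff its
    |Pearson r| (pairwise-complete, >= 3 shared observations) is at or above
    ``corr_threshold`` against any kept descriptor.  The surviving set
    contains no pair at or above the threshold.
    """
    corr = matrix.corr(min_periods=3).abs()
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for col in matrix.columns:
        partner = None
        for other in kept:
            r = corr.at[col, other]
            if not np.isnan(r) and r >= corr_threshold:
                partner = other
                break
        if partner is None:
            kept.append(col)
        else:
            dropped.append((col, partner))
    return matrix[kept], dropped


def apply_filters(
    matrix: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Run high-missing -> near-constant -> correlated filters, in that order."""
    if matrix.shape[1] == 0 or matrix.shape[0] == 0:
        raise ValidationError("descriptor matrix is empty")
    if matrix.columns.duplicated().any():
        dupes = sorted(set(matrix.columns[matrix.columns.duplicated()]))
        raise ValidationError(f"duplicate descriptor name(s): {dupes}")
    cfg = cfg or FilterConfig()
    report = FilterReport()

    matrix, missing = drop_high_missing(matrix, cfg.missing_fraction)
    for name in missing:
        report.dropped[name] = "high_missing"
    matrix, constant = drop_near_constant(matrix, cfg.dup_fraction)
    for name in constant:
        report.dropped[name] = "near_constant"
    matrix, correlated = drop_correlated(matrix, cfg.corr_threshold)
    for name, partner in correlated:
        report.dropped[name] = f"correlated({partner})"
    report.kept = list(matrix.columns)
    if not report.kept:
        raise ValidationError("no descriptors survive filtering; model search is impossible")
    return matrix, report


def fit_imputer(matrix: pd.DataFrame) -> pd.Series:
    """Training-column medians for residual missing cells.

    Must be fit on training rows only.  A column that is entirely missing at
    fit time cannot occur after the high-missing filter and is asserted
    against.
    """
    medians = matrix.median(axis=0, skipna=True)
    assert not medians.isna().any(), "all-missing column after filtering (filter contract violated)"
    return medians


def apply_imputer(medians: pd.Series, matrix: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells with fit-time medians; unseen columns are an error."""
    unknown = [c for c in matrix.columns if c not in medians.index]
    if unknown:
        raise ValidationError(f"column(s) unseen at imputer fit time: {unknown}")
    return matrix.fillna(medians[matrix.columns])


def export_filtered(
    matrix: pd.DataFrame, report: FilterReport, matrix_path, report_path
) -> None:
    """Audit export of the filtered matrix and the filter report as CSV."""
    matrix.to_csv(matrix_path, index_label="name")
    report.to_frame().to_csv(report_path, index=False)
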