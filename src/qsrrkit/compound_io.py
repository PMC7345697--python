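"""Compound table I/O and model persistence.

The on-disk interchange format is a plain CSV with a header row naming, at
minimum, a ``name`` column and a ``smiles`` column, plus an ``rt`` column
(retention time, minutes) for training tables.  Header matching is
case-insensitive after whitespace stripping, and a few common aliases for
the retention-time column are accepted.  Any additional numeric columns are
carried along as user-supplied descriptors and take precedence over
calculated descriptors of the same name downstream.

Trained models are persisted as self-describing joblib archives with a
format version and the complete preprocessing state embedded, so a reloaded
model predicts without access to the training data.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import joblib
import pandas as pd

from .errors import (
    CorruptModelError,
    FormatError,
    IncompatibleModelError,
    ValidationError,
)

#: Current model-bundle format version.  Bump on any incompatible change to
#: the persisted layout.
FORMAT_VERSION = 1

_NAME_ALIASES = {"name", "compound", "compound name", "compound_name"}
_SMILES_ALIASES = {"smiles"}
_RT_ALIASES = {"rt", "rt (min)", "rt_min", "retention time", "retention_time", "retention time (min)"}

# Canonical headers used when writing.
NAME_COL = "name"
SMILES_COL = "smiles"
RT_COL = "rt"


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: identifier, structure, optional retention time (minutes)."""

    name: str
    smiles: str
    rt: Optional[float] = None


@dataclass
class CompoundTable:
    """Ordered compound records plus optional user-supplied descriptor columns.

    ``extra_descriptors``, when present, is indexed by compound name with one
    row per record.
    """

    records: list[CompoundRecord]
    extra_descriptors: Optional[pd.DataFrame] = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    @property
    def rt(self) -> pd.Series:
        """Retention times as a Series indexed by name (NaN where absent)."""
        return pd.Series(
            [r.rt if r.rt is not None else float("nan") for r in self.records],
            index=self.names,
            name=RT_COL,
            dtype=float,
        )

    def subset(self, names: list[str]) -> "CompoundTable":
        """Row subset (and reorder) by compound name."""
        by_name = {r.name: r for r in self.records}
        records = [by_name[n] for n in names]
        extra = None
        if self.extra_descriptors is not None:
            extra = self.extra_descriptors.loc[names]
        return CompoundTable(records=records, extra_descriptors=extra)


@dataclass
class ParseReport:
    """Outcome of reading a compound CSV."""

    rows_read: int = 0
    rejected: dict[int, str] = field(default_factory=dict)  # data-row index -> reason

    @property
    def rows_kept(self) -> int:
        return self.rows_read - len(self.rejected)


def _normalize(header: str) -> str:
    return " ".join(str(header).strip().lower().split())


def _find_column(columns: list[str], aliases: set[str]) -> Optional[str]:
    for col in columns:
        if _normalize(col) in aliases:
            return col
    return None


def write_template(path: str | Path, include_rt: bool = True) -> Path:
    """Write an empty compound-table template CSV (header row only)."""
    path = Path(path)
    cols = [NAME_COL, SMILES_COL] + ([RT_COL] if include_rt else [])
    pd.DataFrame(columns=cols).to_csv(path, index=False)
    return path


def read_table(path: str | Path, require_rt: bool = False) -> tuple[CompoundTable, ParseReport]:
    """Read a compound CSV into a :class:`CompoundTable`.

    Rows with a blank name or SMILES are rejected (recorded in the report);
    duplicate names and, under ``require_rt``, missing/non-numeric/non-positive
    retention times are hard validation errors.  Columns beyond
    name/smiles/rt become ``extra_descriptors`` (coerced to numeric; cells
    that do not parse become missing).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse as CSV: {exc}") from exc

    cols = list(df.columns)
    name_col = _find_column(cols, _NAME_ALIASES)
    smiles_col = _find_column(cols, _SMILES_ALIASES)
    rt_col = _find_column(cols, _RT_ALIASES)
    if name_col is None or smiles_col is None:
        raise FormatError(
            f"{path}: missing mandatory column(s): expected a name column and a smiles column, got {cols}"
        )
    if require_rt and rt_col is None:
        raise FormatError(f"{path}: a retention-time column is required but none was found in {cols}")

    report = ParseReport(rows_read=len(df))
    records: list[CompoundRecord] = []
    kept_idx: list[int] = []
    bad_rt: list[str] = []
    for i, row in df.iterrows():
        name = str(row[name_col]).strip()
        smiles = str(row[smiles_col]).strip()
        if not name:
            report.rejected[i] = "blank name"
            continue
        if not smiles:
            report.rejected[i] = "blank SMILES"
            continue
        rt: Optional[float] = None
        if rt_col is not None:
            raw = str(row[rt_col]).strip()
            if raw:
                try:
                    rt = float(raw)
                except ValueError:
                    rt = None
            if rt is not None and not (math.isfinite(rt) and rt > 0):
                rt = None
            if rt is None and require_rt:
                bad_rt.append(f"row {i} ({name!r}): rt={raw!r}")
                continue
        elif require_rt:
            bad_rt.append(f"row {i} ({name!r}): rt missing")
            continue
        records.append(CompoundRecord(name=name, smiles=smiles, rt=rt))
        kept_idx.append(i)

    if bad_rt:
        raise ValidationError(
            "retention time must be a finite positive number for every compound; offending rows: "
            + "; ".join(bad_rt)
        )

    names = [r.name for r in records]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValidationError(f"duplicate compound name(s): {', '.join(dupes)}")

    extra_cols = [c for c in cols if c not in (name_col, smiles_col, rt_col)]
    extra = None
    if extra_cols:
        extra = df.loc[kept_idx, extra_cols].apply(pd.to_numeric, errors="coerce")
        extra.index = names
        extra.columns = [str(c).strip() for c in extra_cols]
    return CompoundTable(records=records, extra_descriptors=extra), report


def write_table(table: CompoundTable, path: str | Path) -> Path:
    """Write a compound table back to CSV (round-trips through :func:`read_table`)."""
    path = Path(path)
    out = pd.DataFrame(
        {
            NAME_COL: table.names,
            SMILES_COL: [r.smiles for r in table.records],
            RT_COL: [r.rt for r in table.records],
        }
    )
    if table.rt.isna().all():
        out = out.drop(columns=[RT_COL])
    if table.extra_descriptors is not None:
        extra = table.extra_descriptors.reset_index(drop=True)
        out = pd.concat([out, extra], axis=1)
    out.to_csv(path, index=False)
    return path


@dataclass
class ModelBundle:
    """A trained model plus persistence metadata."""

    model: "TrainedModel"  # noqa: F821 - defined in model_search
    format_version: int = FORMAT_VERSION
    created: str = ""
    seed: Optional[int] = None
    config: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()


def save_model(bundle: ModelBundle, path: str | Path) -> Path:
    """Persist a model bundle (joblib archive, stable across runs)."""
    from .model_search import TrainedModel  # local import to avoid cycle

    if not isinstance(bundle.model, TrainedModel):
        raise ValidationError("bundle.model must be a TrainedModel")
    missing = [
        f.name
        for f in dataclasses.fields(bundle.model)
        if getattr(bundle.model, f.name) is None and f.name != "config"
    ]
    if missing:
        raise ValidationError(f"incomplete TrainedModel; unset fields: {missing}")
    path = Path(path)
    joblib.dump({"format_version": bundle.format_version, "bundle": bundle}, path)
    return path


def load_model(path: str | Path) -> ModelBundle:
    """Load a bundle saved by :func:`save_model`.

    Raises :class:`CorruptModelError` on undeserialisable files and
    :class:`IncompatibleModelError` on unknown format versions.
    """
    path = Path(path)
    try:
        payload = joblib.load(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise CorruptModelError(f"{path}: not a readable model bundle: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload or "bundle" not in payload:
        raise CorruptModelError(f"{path}: not a qsrrkit model bundle")
    version = payload["format_version"]
    if version != FORMAT_VERSION:
        raise IncompatibleModelError(
            f"{path}: bundle format version {version} is not supported (this build reads version {FORMAT_VERSION})"
        )
    return payload["bundle"]
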