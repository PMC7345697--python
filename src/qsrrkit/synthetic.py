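"""Synthetic inputs with the statistical structure real QSRR tables have.

Two generators:

* :func:`gen_matrix` builds a descriptor matrix directly — i.i.d. standard
  normal noise features, a handful of informative features that drive
  retention time (linearly or through a smooth nonlinearity), optional
  correlated blocks, near-constant columns and high-missing columns placed
  to cross the default filter thresholds.  Ground truth (which features
  matter, and how) is returned alongside, so feature recovery can be scored
  exactly.
* :func:`gen_series` builds a homologous series of real molecules
  (linear-chain alcohols or fatty acids) whose retention time is linear in
  chain length — the pattern reverse-phase lipid chromatography shows, with
  hydrophobicity (SLogP) as the known monotone driver.

Default retention noise is 0.1 min, in the middle of the 0.005-0.2 min
replicate spread typical of well-behaved LC-MS features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compound_io import CompoundRecord, CompoundTable
from .errors import ValidationError


@dataclass(frozen=True)
class MatrixSpec:
    """Recipe for a synthetic descriptor matrix with planted structure."""

    n_compounds: int = 100
    n_noise_features: int = 50
    informative: tuple[tuple[int, float], ...] = ((0, 2.0), (1, -2.0), (2, 2.0))
    corr_blocks: tuple[tuple[int, int, float], ...] = ()  # (source idx, copies, jitter sd)
    n_near_constant: int = 0
    n_high_missing: int = 0
    rt_mechanism: str = "linear"  # linear | rbf_nonlinear
    noise_sd: float = 0.1  # minutes
    rt_offset: float = 18.0  # minutes; > 5 sd of the default signal, keeps rt positive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_noise_features < 0:
            raise ValidationError("counts must be non-negative (and at least one compound)")
        if self.n_near_constant < 0 or self.n_high_missing < 0:
            raise ValidationError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.rt_mechanism not in ("linear", "rbf_nonlinear"):
            raise ValidationError(f"unknown rt_mechanism {self.rt_mechanism!r}")
        for idx, _ in self.informative:
            if not (0 <= idx < self.n_noise_features):
                raise ValidationError(f"informative index {idx} out of range")
        for src, copies, sd in self.corr_blocks:
            if not (0 <= src < self.n_noise_features) or copies < 1 or sd < 0:
                raise ValidationError(f"bad corr_block {(src, copies, sd)}")


@dataclass
class MatrixGroundTruth:
    """What was planted, for exact scoring of recovery."""

    informative_features: list[str]
    coefficients: dict[str, float]
    correlated_copies: dict[str, str]  # copy name -> source name
    near_constant: list[str]
    high_missing: list[str]
    rt_mechanism: str
    noise_sd: float


def _feature_name(i: int) -> str:
    return f"f{i:03d}"


def gen_matrix(spec: MatrixSpec) -> tuple[pd.DataFrame, pd.Series, MatrixGroundTruth]:
    """Generate (descriptor matrix, retention times, ground truth) from ``spec``.

    Retention times are ``rt_offset + signal + N(0, noise_sd)`` where the
    signal is a weighted sum of the informative features (linear) or of
    ``sin(2*feature)`` terms (rbf_nonlinear).  Raises if any generated
    retention time is non-positive.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    names = [f"cmpd{i:04d}" for i in range(n)]
    base = rng.standard_normal((n, spec.n_noise_features))
    cols = [_feature_name(i) for i in range(spec.n_noise_features)]
    X = pd.DataFrame(base, index=names, columns=cols)

    truth = MatrixGroundTruth(
        informative_features=[_feature_name(i) for i, _ in spec.informative],
        coefficients={_feature_name(i): c for i, c in spec.informative},
        correlated_copies={},
        near_constant=[],
        high_missing=[],
        rt_mechanism=spec.rt_mechanism,
        noise_sd=spec.noise_sd,
    )

    signal = np.zeros(n)
    for i, coef in spec.informative:
        if spec.rt_mechanism == "linear":
            signal += coef * base[:, i]
        else:
            signal += coef * np.sin(2.0 * base[:, i])
    rt = spec.rt_offset + signal + rng.normal(0.0, spec.noise_sd, size=n)
    if (rt <= 0).any():
        raise ValidationError(
            "spec produced non-positive retention times; raise rt_offset or shrink coefficients"
        )

    for src, copies, jitter in spec.corr_blocks:
        src_name = _feature_name(src)
        for j in range(copies):
            a = rng.uniform(0.5, 2.0)
            b = rng.uniform(-1.0, 1.0)
            col = f"{src_name}_copy{j}"
            X[col] = a * base[:, src] + b + rng.normal(0.0, jitter, size=n)
            truth.correlated_copies[col] = src_name

    for j in range(spec.n_near_constant):
        col = f"const{j:02d}"
        vals = np.zeros(n)
        n_odd = max(0, int(np.floor(0.05 * n)))  # 95% identical: crosses the 90% default
        odd_idx = rng.choice(n, size=n_odd, replace=False)
        vals[odd_idx] = rng.standard_normal(n_odd)
        X[col] = vals
        truth.near_constant.append(col)

    for j in range(spec.n_high_missing):
        col = f"sparse{j:02d}"
        vals = rng.standard_normal(n)
        n_missing = int(np.ceil(0.80 * n))  # 80% missing: crosses the 75% default
        missing_idx = rng.choice(n, size=n_missing, replace=False)
        vals[missing_idx] = np.nan
        X[col] = vals
        truth.high_missing.append(col)

    y = pd.Series(rt, index=names, name="rt")
    return X, y, truth


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for a homologous compound series with programmed retention."""

    family: str = "n_alkanols"  # n_alkanols | n_fatty_acids
    chain_min: int = 2
    chain_max: int = 41
    rt_intercept: float = 1.0  # minutes at chain length 0
    rt_per_carbon: float = 0.35  # minutes per CH2
    noise_sd: float = 0.1  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chain_min < 2 or self.chain_max < self.chain_min:
            raise ValidationError("chain lengths must satisfy 2 <= chain_min <= chain_max")
        if self.rt_per_carbon <= 0:
            raise ValidationError("rt_per_carbon must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.family not in ("n_alkanols", "n_fatty_acids"):
            raise ValidationError(f"unknown family {self.family!r}")


def _series_smiles(family: str, chain: int) -> tuple[str, str]:
    if family == "n_alkanols":
        return f"C{chain}-alkanol", "C" * chain + "O"
    # straight-chain saturated fatty acid with `chain` carbons total
    return f"C{chain}-fatty-acid", "C" * (chain - 1) + "C(=O)O"


def gen_series(spec: SeriesSpec) -> CompoundTable:
    """Generate a homologous series table (valid SMILES, rt linear in chain length)."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for chain in range(spec.chain_min, spec.chain_max + 1):
        name, smiles = _series_smiles(spec.family, chain)
        rt = spec.rt_intercept + spec.rt_per_carbon * chain + rng.normal(0.0, spec.noise_sd)
        if rt <= 0:
            raise ValidationError(f"chain {chain}: generated rt {rt:.3f} <= 0")
        records.append(CompoundRecord(name=name, smiles=smiles, rt=float(rt)))
    return CompoundTable(records=records)
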