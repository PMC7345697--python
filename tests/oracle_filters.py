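"""Brute-force reference for the descriptor filter stack.

Independent of the package implementation: explicit loops, the textbook
Pearson formula, and the same stated rules (inclusive thresholds, filter
order missing -> constant -> correlated, greedy keep-earlier scan).  Used
to cross-check :func:`qsrrkit.apply_filters` on small matrices.
"""

import math

import numpy as np
import pandas as pd


def pearson_pairwise(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r on pairwise-complete observations; NaN if < 3 shared."""
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        return float("nan")
    xs, ys = x[mask], y[mask]
    mx, my = xs.mean(), ys.mean()
    sxx = ((xs - mx) ** 2).sum()
    syy = ((ys - my) ** 2).sum()
    if sxx == 0 or syy == 0:
        return float("nan")
    return float(((xs - mx) * (ys - my)).sum() / math.sqrt(sxx * syy))


def brute_force_filters(matrix: pd.DataFrame, dup=0.90, miss=0.75, corr=0.90):
    """Return (kept column list, {column: reason}) by direct enumeration."""
    n = len(matrix)
    dropped = {}
    cols = list(matrix.columns)

    survivors = []
    for c in cols:
        values = matrix[c].to_numpy(dtype=float)
        if np.isnan(values).sum() / n >= miss:
            dropped[c] = "high_missing"
        else:
            survivors.append(c)

    cols, survivors = survivors, []
    for c in cols:
        values = matrix[c].to_numpy(dtype=float)
        present = values[~np.isnan(values)]
        modal = 0
        for v in set(present.tolist()):
            modal = max(modal, int((present == v).sum()))
        if modal / n >= dup:
            dropped[c] = "near_constant"
        else:
            survivors.append(c)

    kept = []
    for c in survivors:
        partner = None
        for k in kept:
            r = pearson_pairwise(
                matrix[c].to_numpy(dtype=float), matrix[k].to_numpy(dtype=float)
            )
            if not math.isnan(r) and abs(r) >= corr:
                partner = k
                break
        if partner is None:
            kept.append(c)
        else:
            dropped[c] = f"correlated({partner})"
    return kept, dropped


def random_planted_matrix(seed: int) -> pd.DataFrame:
    """A small random matrix with planted constant, high-missing and duplicated columns."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 21))
    p = int(rng.integers(5, 12))
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"c{j}" for j in range(p)]
    )
    X["const"] = 1.25
    sparse = rng.standard_normal(n)
    sparse[: int(np.ceil(0.8 * n))] = np.nan
    X["sparse"] = sparse
    X["dup"] = X["c0"] * rng.uniform(0.5, 3.0) + rng.uniform(-1, 1)
    # sprinkle a few missing cells elsewhere
    for _ in range(int(rng.integers(0, 5))):
        X.iat[int(rng.integers(0, n)), int(rng.integers(0, p))] = np.nan
    return X
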