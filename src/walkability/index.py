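"""Composite walkability index construction.

The index is the unweighted mean of the z-standardized seven components,
min-max scaled to 0-100 within the supplied unit universe.  Important:
standardization and scaling are relative to *whatever universe of units is
in the table* (one scale at a time) — indices built on different universes
are not comparable.  Leave-one-out partial indices (each the mean of six
z-scores, independently rescaled to 0-100) support the attenuation
analysis; quintiles and the component correlation matrix support the
descriptive tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .components import COMPONENTS

Z_COLUMNS = tuple(f"z_{c}" for c in COMPONENTS)


def zscore_components(table: pd.DataFrame,
                      components=COMPONENTS) -> pd.DataFrame:
    """Append ``z_<component>`` columns: (x - mean) / SD with sample (n-1) SD.

    Standardization is over all rows of ``table``; callers must pass a
    single scale at a time.  A constant component has no z-score and is
    reported as an error rather than silently zeroed.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 units to standardize")
    out = table.copy()
    for c in components:
        x = table[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if np.ptp(x) == 0 or not np.isfinite(sd):
            raise ValueError(f"component {c!r} is constant (SD = 0); cannot z-score")
        out[f"z_{c}"] = (x - x.mean()) / sd
    return out


def composite_index(ztable: pd.DataFrame, zcols=Z_COLUMNS) -> np.ndarray:
    """Unweighted mean of the component z-scores (raw, unscaled index)."""
    missing = [c for c in zcols if c not in ztable.columns]
    if missing:
        raise ValueError(f"missing z-score column(s): {missing}")
    return ztable[list(zcols)].to_numpy(dtype=float).mean(axis=1)


def minmax_scale(values) -> np.ndarray:
    """Affine rescale onto [0, 100]; the min maps to 0 and the max to 100."""
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("all values identical; min-max scaling undefined")
    return (x - lo) / (hi - lo) * 100.0


def leave_one_out_indices(ztable: pd.DataFrame, components=COMPONENTS,
                          scaled: bool = True) -> pd.DataFrame:
    """Seven partial indices, each omitting one component.

    Each partial is the mean of the remaining six z-scores, min-max scaled
    to 0-100 *independently*, so a "per 10 points" effect is comparable
    across partial indices.  Columns are ``partial_<omitted component>``.
    ``scaled=False`` returns the raw six-component means instead (the mean
    of the seven raw partials reproduces the full raw index exactly).
    """
    zcols = [f"z_{c}" for c in components]
    missing = [c for c in zcols if c not in ztable.columns]
    if missing:
        raise ValueError(f"missing z-score column(s): {missing}")
    z = ztable[zcols].to_numpy(dtype=float)
    out = {}
    for k, omitted in enumerate(components):
        partial_raw = np.delete(z, k, axis=1).mean(axis=1)
        out[f"partial_{omitted}"] = (minmax_scale(partial_raw) if scaled
                                     else partial_raw)
    return pd.DataFrame(out, index=ztable.index)


def quintile_assign(values) -> np.ndarray:
    """Rank-based quintile labels 1-5; ties share the label of their average rank."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 units for quintiles")
    ranks = stats.rankdata(x, method="average")
    return np.ceil(5.0 * ranks / n).astype(int)


def correlation_matrix(table: pd.DataFrame, columns=None):
    """Pairwise Pearson r with two-sided p-values (t transform).

    Returns ``(r, p)`` as symmetric DataFrames with unit diagonal.
    """
    cols = list(columns) if columns is not None else list(COMPONENTS)
    if len(table) < 3:
        raise ValueError("need at least 3 units for correlations")
    X = table[cols].to_numpy(dtype=float)
    constant = [c for c, col in zip(cols, X.T) if np.ptp(col) == 0]
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    n = len(X)
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def build_index_table(components_table: pd.DataFrame) -> pd.DataFrame:
    """Full index pipeline for one scale: z-scores -> composite -> 0-100.

    Returns the input plus ``z_*`` columns, ``walkability_raw`` (mean z),
    ``walkability`` (0-100), ``quintile`` and seven ``partial_*`` columns.
    """
    z = zscore_components(components_table)
    z["walkability_raw"] = composite_index(z)
    z["walkability"] = minmax_scale(z["walkability_raw"])
    z["quintile"] = quintile_assign(z["walkability"])
    partials = leave_one_out_indices(z)
    return pd.concat([z, partials], axis=1)
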