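"""Covariate construction: composite IQ and rough-fix imputation.

Sites contributed different IQ instruments (WISC/WASI variants), leaving a
site-predictive missingness pattern over the verbal, performance and
full-scale measures.  The pipeline collapses them to a single composite —
the median of whatever measures a subject has — and then fills any
remaining gaps column-wise with the median (quantitative) or mode
(categorical) of the observed values, i.e. the classic random-forest
"rough fix".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import IQ_COLUMNS

__all__ = ["composite_iq", "add_composite_iq", "roughfix_impute", "prepare_phenotypes"]


def composite_iq(measures) -> float:
    """Median of the available (non-missing) IQ measures.

    Accepts a mapping or sequence of values with NaN marking missingness.
    Returns NaN when no measure is observed.  An even number of observed
    values yields the mean of the two central ones (ordinary median).
    """
    if isinstance(measures, dict):
        values = np.asarray(list(measures.values()), dtype=float)
    else:
        values = np.asarray(list(measures), dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size == 0:
        return float("nan")
    return float(np.median(observed))


def add_composite_iq(table: pd.DataFrame, iq_columns=IQ_COLUMNS) -> pd.DataFrame:
    """Append an ``iq_composite`` column (median over the IQ measures).

    Computed before any imputation, so the composite reflects only what
    each subject actually has; subjects with no observed measure get NaN
    and are left for :func:`roughfix_impute`.
    """
    missing_cols = [c for c in iq_columns if c not in table.columns]
    if missing_cols:
        raise KeyError(f"phenotype table lacks IQ columns {missing_cols}")
    out = table.copy()
    out["iq_composite"] = out[list(iq_columns)].median(axis=1, skipna=True)
    return out


def _mode_lexicographic(series: pd.Series):
    """Most frequent observed level; ties broken by sorted level order."""
    counts = series.dropna().value_counts()
    top = counts.max()
    candidates = sorted(str(level) for level, n in counts.items() if n == top)
    return candidates[0]


def roughfix_impute(table: pd.DataFrame, skip_columns=("subject_id",)) -> pd.DataFrame:
    """Median/mode imputation of every column, observed values untouched.

    Quantitative columns get their observed median, categorical columns the
    observed mode (lexicographically smallest level on ties).  Idempotent.

    Raises
    ------
    ValueError
        If a column (outside ``skip_columns``) has no observed value at all,
        naming the column.
    """
    out = table.copy()
    for col in out.columns:
        if col in skip_columns:
            continue
        series = out[col]
        if not series.isna().any():
            continue
        if series.isna().all():
            raise ValueError(f"column {col!r} has no observed values to impute from")
        if pd.api.types.is_numeric_dtype(series):
            fill = series.median(skipna=True)
        else:
            fill = _mode_lexicographic(series)
        out[col] = series.fillna(fill)
    return out


def prepare_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Composite IQ then rough-fix imputation — the standard covariate prep."""
    return roughfix_impute(add_composite_iq(table))
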