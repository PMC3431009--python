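"""Inference on the motor-network correlations.

Beyond prediction, the 10 inter-parcel correlations are interesting in
their own right.  This module provides the three standard summaries:

* per-group (overall / TD / combined / inattentive) means and SDs of each
  pairwise correlation;
* three nested multinomial logistic models per pair with the 3-level
  outcome (TD, ADHD-combined, ADHD-inattentive — the rare
  hyperactive/impulsive subtype is dropped): Model 1 uses the pair alone,
  Model 2 adds the four demographics (age, composite IQ, gender,
  handedness), Model 3 adds site; each pair's contribution is tested by a
  likelihood-ratio test (2 df);
* ten binary logistic regressions of ADHD-vs-TD status on one pair plus
  the four demographics, reporting the pair coefficient, its sign and
  p-value, with an optional site-adjusted variant for direction-stability
  checks.

Raw p-values are reported; no multiplicity correction is applied.
Non-convergence or separation is flagged per cell (NaN p-value), never
raised.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .constants import PAIR_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "subtype_correlation_summary",
    "subtype_association_models",
    "pairwise_logistic_models",
]

#: demographic covariates used by Models 2/3 and the binary models
DEMOGRAPHICS = ("age", "iq_composite", "gender", "handedness")

_MULTINOMIAL_LEVELS = ("TD", "COMBINED", "INATTENTIVE")


def subtype_correlation_summary(features: pd.DataFrame, labels) -> pd.DataFrame:
    """Group means and SDs of each pairwise correlation.

    ``features`` must carry the 10 canonical pair columns; rows align with
    ``labels``.  Groups with fewer than 2 subjects are omitted with a
    warning.  Returns a frame indexed by (group, statistic).
    """
    missing = [c for c in PAIR_NAMES if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks pair columns: {missing}")
    y = np.asarray([str(v) for v in labels])
    if len(y) != len(features):
        raise ValueError("labels and feature rows length mismatch")
    block = features[list(PAIR_NAMES)]
    rows = {}
    groups = {"OVERALL": np.ones(len(y), dtype=bool)}
    for level in ("TD", "COMBINED", "INATTENTIVE"):
        groups[level] = y == level
    for name, sel in groups.items():
        if sel.sum() < 2:
            warnings.warn(
                f"group {name!r} has fewer than 2 subjects; omitted",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        sub = block[sel]
        rows[(name, "mean")] = sub.mean(axis=0)
        rows[(name, "sd")] = sub.std(axis=0, ddof=1)
    out = pd.DataFrame(rows).T
    out.index = pd.MultiIndex.from_tuples(out.index, names=["group", "stat"])
    return out


def _standardize_numeric(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score numeric columns (fit stability; p-values are scale-invariant)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_numeric_dtype(out[col]):
            sd = out[col].std(ddof=0)
            if sd > 0:
                out[col] = (out[col] - out[col].mean()) / sd
    return out


def _design(covariates: pd.DataFrame | None, cols) -> pd.DataFrame:
    if covariates is None or not cols:
        return pd.DataFrame(index=covariates.index if covariates is not None else None)
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns: {missing}")
    sub = covariates[list(cols)]
    sub = _standardize_numeric(sub)
    return pd.get_dummies(sub, drop_first=True, dtype=float)


def _fit_mnlogit(y_codes: np.ndarray, X: np.ndarray):
    """MNLogit fit with a quiet Newton/BFGS fallback; None on failure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method, maxiter in (("newton", 100), ("bfgs", 500)):
            try:
                res = sm.MNLogit(y_codes, X).fit(
                    method=method, maxiter=maxiter, disp=0
                )
            except Exception:  # separation, singular Hessian, ...
                continue
            if np.isfinite(res.llf):
                return res
    return None


def subtype_association_models(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    labels,
) -> pd.DataFrame:
    """Likelihood-ratio p-values for each pair under Models 1-3.

    Outcome: 3-level (TD / COMBINED / INATTENTIVE); rows with other labels
    are dropped.  For each pair and model, the p-value compares the model
    with and without the pair's coefficients (chi-square, 2 df).  Cells
    where either fit fails are NaN with the flag column set.
    """
    y = np.asarray([str(v) for v in labels])
    keep = np.isin(y, _MULTINOMIAL_LEVELS)
    if keep.sum() < len(y):
        logger.info("dropping %d subjects outside the 3-level outcome", (~keep).sum())
    y = y[keep]
    if len(set(y)) < 3:
        raise ValueError("need all three outcome levels (TD, COMBINED, INATTENTIVE)")
    feats = features.loc[keep].reset_index(drop=True)
    covs = covariates.loc[keep].reset_index(drop=True)
    codes = np.array([_MULTINOMIAL_LEVELS.index(v) for v in y])

    model_covs = {
        "model1": (),
        "model2": DEMOGRAPHICS,
        "model3": DEMOGRAPHICS + ("site",),
    }
    records = []
    for pair in PAIR_NAMES:
        x_pair = feats[pair].to_numpy(dtype=float)
        sd = x_pair.std()
        row: dict = {"pair": pair}
        for model_name, cols in model_covs.items():
            if sd <= 1e-12:
                row[model_name] = np.nan
                row[f"{model_name}_flag"] = "non-identifiable"
                continue
            Z = _design(covs, cols).to_numpy(dtype=float)
            base = np.column_stack([np.ones(len(codes)), Z])
            full = np.column_stack([base, (x_pair - x_pair.mean()) / sd])
            fit_full = _fit_mnlogit(codes, full)
            fit_base = _fit_mnlogit(codes, base)
            if fit_full is None or fit_base is None:
                row[model_name] = np.nan
                row[f"{model_name}_flag"] = "non-convergence"
                continue
            lr = 2.0 * (fit_full.llf - fit_base.llf)
            df = 2  # one pair coefficient in each non-reference equation
            row[model_name] = float(stats.chi2.sf(max(lr, 0.0), df))
            row[f"{model_name}_flag"] = ""
        records.append(row)
    return pd.DataFrame(records).set_index("pair")


def pairwise_logistic_models(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    binary_labels,
    adjust_site: bool = False,
) -> pd.DataFrame:
    """Ten binary logistic fits: ADHD status on one pair + demographics.

    ``binary_labels`` is 0/1 (or TD / anything-else).  Returns one row per
    pair with the pair coefficient (on the standardized pair scale), its
    direction, Wald p-value and a convergence flag.
    """
    y_raw = list(binary_labels)
    if set(map(str, y_raw)) <= {"0", "1"}:
        y = np.array([int(str(v)) for v in y_raw])
    else:
        y = np.array([0 if str(v) == "TD" else 1 for v in y_raw])
    if len(y) != len(features):
        raise ValueError("labels and feature rows length mismatch")
    if len(set(y.tolist())) < 2:
        raise ValueError("need both classes for logistic regression")
    cols = DEMOGRAPHICS + (("site",) if adjust_site else ())
    Z = _design(covariates, cols).to_numpy(dtype=float)
    records = []
    for pair in PAIR_NAMES:
        x_pair = features[pair].to_numpy(dtype=float)
        sd = x_pair.std()
        if sd <= 1e-12:
            records.append(
                {"pair": pair, "coef": np.nan, "direction": "", "pvalue": np.nan,
                 "converged": False}
            )
            continue
        X = np.column_stack([np.ones(len(y)), Z, (x_pair - x_pair.mean()) / sd])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", False))
                coef = float(res.params[-1])
                pval = float(res.pvalues[-1])
            except Exception:
                converged, coef, pval = False, np.nan, np.nan
        records.append(
            {
                "pair": pair,
                "coef": coef,
                "direction": "" if not np.isfinite(coef) else ("negative" if coef < 0 else "positive"),
                "pvalue": pval,
                "converged": converged,
            }
        )
    return pd.DataFrame(records).set_index("pair")
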