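"""Competition scoring, binary diagnostic metrics, and data splitting.

The hierarchical scoring rule awards, per subject:

* 1 point for an exact label match (TD or the correct ADHD subtype);
* 0.5 points when both truth and prediction are ADHD but the subtype is
  wrong (the primary diagnosis was right);
* 0 otherwise — including a TD child called any flavour of ADHD.

"Accuracy" is points as a percent of the maximum (one point per subject).
Binary metrics collapse the three subtypes to a single ADHD class;
Youden's J = sensitivity + specificity - 1 summarises the trade-off, and
the conditional subtype accuracy is the fraction of correctly detected
ADHD subjects whose subtype was also right.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .constants import ADHD_SUBTYPES, DX_LEVELS

__all__ = [
    "ScoreReport",
    "competition_score",
    "binary_metrics",
    "score_report",
    "split_cohort",
    "permutation_pvalue",
]


def _check_labels(truth, pred):
    truth = [str(v) for v in truth]
    pred = [str(v) for v in pred]
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(pred)} predicted")
    bad = sorted((set(truth) | set(pred)) - set(DX_LEVELS))
    if bad:
        raise ValueError(f"labels outside the 4-level diagnosis set: {bad}")
    return truth, pred


def competition_score(truth, pred) -> tuple[float, float]:
    """Return ``(points, percent)`` under the hierarchical scoring rule."""
    truth, pred = _check_labels(truth, pred)
    if not truth:
        raise ValueError("empty label vectors")
    points = 0.0
    for t, p in zip(truth, pred):
        if t == p:
            points += 1.0
        elif t in ADHD_SUBTYPES and p in ADHD_SUBTYPES:
            points += 0.5
    return points, 100.0 * points / len(truth)


@dataclass
class ScoreReport:
    """Everything the competition and the diagnostic summaries report."""

    points: float
    percent: float
    sensitivity: float
    specificity: float
    youden_j: float
    conditional_subtype_accuracy: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def binary_metrics(truth, pred) -> tuple[float, float, float, float]:
    """Sensitivity, specificity, Youden's J and conditional subtype accuracy.

    Subtypes are collapsed to "ADHD" for the binary quantities.  A metric
    whose denominator is empty (no true ADHD, no true TD, or no correctly
    detected ADHD) is returned as NaN rather than raising.
    """
    truth, pred = _check_labels(truth, pred)
    t_adhd = np.array([t in ADHD_SUBTYPES for t in truth])
    p_adhd = np.array([p in ADHD_SUBTYPES for p in pred])
    n_true_adhd = int(t_adhd.sum())
    n_true_td = int((~t_adhd).sum())
    sens = float((t_adhd & p_adhd).sum() / n_true_adhd) if n_true_adhd else float("nan")
    spec = float((~t_adhd & ~p_adhd).sum() / n_true_td) if n_true_td else float("nan")
    youden = sens + spec - 1.0
    detected = t_adhd & p_adhd
    if detected.any():
        correct_subtype = sum(
            1 for t, p, d in zip(truth, pred, detected) if d and t == p
        )
        cond = correct_subtype / int(detected.sum())
    else:
        cond = float("nan")
    return sens, spec, youden, cond


def score_report(truth, pred) -> ScoreReport:
    """Full report: competition points plus the binary diagnostic metrics."""
    points, percent = competition_score(truth, pred)
    sens, spec, youden, cond = binary_metrics(truth, pred)
    return ScoreReport(
        points=points,
        percent=percent,
        sensitivity=sens,
        specificity=spec,
        youden_j=youden,
        conditional_subtype_accuracy=cond,
        n=len(list(truth)),
    )


def split_cohort(items, n_test: int, seed: int = 0) -> tuple[list, list]:
    """Uniformly random disjoint train/test split, reproducible by seed.

    ``items`` may be a sequence (split and returned as two lists) or an
    integer n (index lists are returned).  The classic internal split
    reserved 184 of 776 subjects; pass whatever ``n_test`` fits the cohort.
    """
    if isinstance(items, (int, np.integer)):
        seq = list(range(int(items)))
    else:
        seq = list(items)
    n = len(seq)
    if not 0 < n_test < n:
        raise ValueError(f"n_test={n_test} must lie strictly between 0 and n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return [seq[i] for i in train_idx], [seq[i] for i in test_idx]


def permutation_pvalue(truth, pred, n_perm: int = 500, seed: int = 0) -> float:
    """P-value of the observed competition score under label permutation.

    Permutes the predicted labels across subjects; the p-value is the
    fraction of permutations scoring at least as high as the observed
    assignment (add-one smoothed).  Large values mean the score is
    indistinguishable from chance given the predicted label mix.
    """
    truth, pred = _check_labels(truth, pred)
    obs, _ = competition_score(truth, pred)
    rng = np.random.default_rng(seed)
    pred_arr = np.array(pred)
    count = 0
    for _ in range(n_perm):
        perm_points, _ = competition_score(truth, pred_arr[rng.permutation(len(pred_arr))])
        if perm_points >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)
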