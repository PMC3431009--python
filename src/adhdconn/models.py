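"""Classifier stages and ensembling.

Three model families make up the ensemble:

* a 4-class random forest on the 10 motor-network correlations plus
  demographics;
* a *two-stage* gradient-boosting model — stage 1 separates typically
  developing (TD) from any-ADHD, stage 2 assigns the subtype among
  subjects stage 1 calls ADHD (stage 2 is trained on the true ADHD
  subjects, which avoids leaking stage-1 errors into subtype training);
* a plurality vote over prediction sets, with a designated member
  breaking both 2-2 and all-singleton ties.

Class imbalance is deliberately left unweighted by default: cohorts with a
TD majority push all of these models toward the TD label, which is exactly
the behaviour the competition scoring rewards; pass ``class_weight`` to a
fit function to counteract it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from .constants import ADHD_SUBTYPES, DX_LEVELS

__all__ = [
    "PredictionSet",
    "TabularClassifier",
    "TwoStageModel",
    "fit_random_forest_pipeline",
    "fit_two_stage_gbm",
    "majority_vote",
]


@dataclass
class PredictionSet:
    """Per-subject labels from one model (the ensemble's currency)."""

    subject_ids: list[str]
    labels: list[str]
    source: str

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.labels):
            raise ValueError("subject ids and labels length mismatch")
        # the 4-level diagnosis set, plus the collapsed "ADHD" used by the
        # binary stage-1 gate when inspected on its own
        allowed = set(DX_LEVELS) | {"ADHD"}
        bad = sorted(set(self.labels) - allowed)
        if bad:
            raise ValueError(f"labels outside the diagnosis alphabet: {bad}")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.subject_ids, self.labels))


class _Design:
    """One-hot design builder with level sets frozen at fit time."""

    def __init__(self) -> None:
        self.numeric_cols: list[str] = []
        self.categorical_levels: dict[str, list[str]] = {}

    def fit(self, df: pd.DataFrame) -> "_Design":
        self.numeric_cols = [
            c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
        ]
        self.categorical_levels = {
            c: sorted(df[c].astype(str).unique())
            for c in df.columns
            if c not in self.numeric_cols
        }
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        blocks = []
        if self.numeric_cols:
            block = df[self.numeric_cols].to_numpy(dtype=float)
            if np.isnan(block).any():
                raise ValueError("feature table contains missing numeric values")
            blocks.append(block)
        for col, levels in self.categorical_levels.items():
            values = df[col].astype(str).to_numpy()
            blocks.append(
                np.column_stack([(values == lvl).astype(float) for lvl in levels])
            )
        return np.column_stack(blocks) if blocks else np.empty((len(df), 0))


@dataclass
class TabularClassifier:
    """A fitted sklearn estimator bound to its feature preparation."""

    estimator: object
    design: _Design
    feature_names: list[str]
    source: str
    metadata: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame, subject_ids=None) -> PredictionSet:
        X = self.design.transform(features[self.feature_names])
        labels = [str(v) for v in self.estimator.predict(X)]
        if subject_ids is None:
            subject_ids = [str(i) for i in range(len(labels))]
        return PredictionSet(list(subject_ids), labels, source=self.source)


def _check_features(features: pd.DataFrame, required) -> None:
    if required:
        missing = [c for c in required if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks required columns: {missing}")


def fit_random_forest_pipeline(
    features: pd.DataFrame,
    labels,
    required_columns=None,
    seed: int = 0,
    n_estimators: int = 500,
    class_weight=None,
    source: str = "rf",
    **rf_kwargs,
) -> TabularClassifier:
    """Fit the 4-class random-forest stage on a feature table.

    ``required_columns`` (e.g. the 10 pair correlations plus demographics)
    is checked up front so a mis-assembled table fails loudly.  Training on
    a single-class label vector is an error.
    """
    _check_features(features, required_columns)
    y = np.asarray([str(v) for v in labels])
    if len(y) != len(features):
        raise ValueError("labels and feature rows length mismatch")
    if len(set(y)) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    design = _Design().fit(features)
    X = design.transform(features)
    est = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        class_weight=class_weight,
        **rf_kwargs,
    )
    est.fit(X, y)
    return TabularClassifier(
        estimator=est,
        design=design,
        feature_names=list(features.columns),
        source=source,
        metadata={"seed": seed, "n_estimators": n_estimators, "model": "random_forest"},
    )


class _ConstantClassifier:
    """Degenerate stage-2 fallback when only one subtype is observed."""

    def __init__(self, label: str) -> None:
        self.label = label

    def fit(self, X, y):  # pragma: no cover - trivial
        return self

    def predict(self, X):
        return np.array([self.label] * len(X))


@dataclass
class TwoStageModel:
    """TD-vs-ADHD gate followed by a subtype classifier.

    ``predict`` applies the gate: subjects called TD by stage 1 keep the TD
    label regardless of stage 2; the rest receive stage 2's subtype.
    """

    stage1: TabularClassifier
    stage2: TabularClassifier
    source: str = "gbm2"

    def predict(self, features: pd.DataFrame, subject_ids=None) -> PredictionSet:
        p1 = self.stage1.predict(features, subject_ids)
        p2 = self.stage2.predict(features, subject_ids)
        labels = [
            "TD" if l1 == "TD" else l2 for l1, l2 in zip(p1.labels, p2.labels)
        ]
        return PredictionSet(list(p1.subject_ids), labels, source=self.source)


def fit_two_stage_gbm(
    features: pd.DataFrame,
    labels,
    required_columns=None,
    seed: int = 0,
    n_estimators: int = 200,
    learning_rate: float = 0.05,
    max_depth: int = 3,
    source: str = "gbm2",
) -> TwoStageModel:
    """Fit the two-stage gradient-boosting model.

    Stage 1 learns TD vs any-ADHD on all subjects; stage 2 learns the
    subtype on the true ADHD subjects only.  Requires at least one ADHD
    subject; with a single observed subtype stage 2 degenerates to a
    constant.
    """
    _check_features(features, required_columns)
    y = np.asarray([str(v) for v in labels])
    if len(y) != len(features):
        raise ValueError("labels and feature rows length mismatch")
    is_adhd = np.isin(y, ADHD_SUBTYPES)
    if not is_adhd.any():
        raise ValueError("no ADHD subjects; cannot fit the subtype stage")
    if is_adhd.all():
        raise ValueError("need both TD and ADHD subjects for stage 1")

    design = _Design().fit(features)
    X = design.transform(features)

    y1 = np.where(is_adhd, "ADHD", "TD")
    gb1 = GradientBoostingClassifier(
        n_estimators=n_estimators,
        learning_rate=learning_rate,
        max_depth=max_depth,
        random_state=seed,
    )
    gb1.fit(X, y1)
    stage1 = TabularClassifier(
        estimator=gb1,
        design=design,
        feature_names=list(features.columns),
        source=f"{source}_stage1",
        metadata={"seed": seed, "model": "gbm", "stage": 1},
    )
    y2 = y[is_adhd]
    X2 = X[is_adhd]
    if len(set(y2)) == 1:
        est2 = _ConstantClassifier(y2[0])
    else:
        est2 = GradientBoostingClassifier(
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            max_depth=max_depth,
            random_state=seed + 1,
        )
        est2.fit(X2, y2)
    stage2 = TabularClassifier(
        estimator=est2,
        design=design,
        feature_names=list(features.columns),
        source=f"{source}_stage2",
        metadata={"seed": seed, "model": "gbm", "stage": 2},
    )
    return TwoStageModel(stage1=stage1, stage2=stage2, source=source)


def majority_vote(
    predictions: list[PredictionSet], tiebreak_source: str
) -> PredictionSet:
    """Per-subject plurality label; any tie for the top count defers to the
    tie-breaking member's label.

    All prediction sets must cover the same subjects; the tie-breaker must
    be one of the inputs.
    """
    if not predictions:
        raise ValueError("no prediction sets to combine")
    sources = [p.source for p in predictions]
    if tiebreak_source not in sources:
        raise ValueError(f"tiebreak source {tiebreak_source!r} not among {sources}")
    base_ids = list(predictions[0].subject_ids)
    base_set = set(base_ids)
    maps = []
    for p in predictions:
        if set(p.subject_ids) != base_set or len(p.subject_ids) != len(base_ids):
            raise ValueError(f"prediction set {p.source!r} covers different subjects")
        maps.append(p.as_dict())
    tiebreak_map = maps[sources.index(tiebreak_source)]
    labels = []
    for sid in base_ids:
        votes = Counter(m[sid] for m in maps)
        top = max(votes.values())
        leaders = [label for label, n in votes.items() if n == top]
        labels.append(leaders[0] if len(leaders) == 1 else tiebreak_map[sid])
    return PredictionSet(base_ids, labels, source="ensemble")
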