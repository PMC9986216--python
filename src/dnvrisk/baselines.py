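"""Baseline classifiers, probability combination, and heuristic rules.

Baselines are standard scikit-learn learners (random forest, linear SVM,
logistic regression) tuned by stratified k-fold CV on each learner's own
loss. Linear-SVM decision scores are mapped to [0, 1] by in-batch min-max
rescaling (order-preserving; Platt scaling available via the spec).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import hinge_loss, log_loss, make_scorer
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import LinearSVC

from .errors import ValidationError
from .io_features import (
    FeatureMatrix,
    GeneScoreTable,
    VariantClass,
    VariantRecord,
    align_features,
)

logger = logging.getLogger(__name__)

BASELINE_KINDS = ("random_forest", "linear_svm", "logistic_regression")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100, 500], "max_depth": [None, 10]},
    "linear_svm": {"C": [0.01, 0.1, 1.0, 10.0]},
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0]},
}


@dataclass(frozen=True)
class BaselineSpec:
    kind: str
    grid: Mapping[str, list] | None = None
    seed: int = 0
    svm_probability: str = "minmax"  # or "platt"

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise ValidationError(f"unknown baseline kind {self.kind!r}")
        if self.grid is not None and any(not v for v in self.grid.values()):
            raise ValidationError("hyperparameter grid lists must be non-empty")

    @property
    def effective_grid(self) -> dict[str, list]:
        return dict(self.grid) if self.grid is not None else dict(DEFAULT_GRIDS[self.kind])


def _make_estimator(kind: str, seed: int):
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if kind == "linear_svm":
        return LinearSVC(random_state=seed, dual=False)
    return LogisticRegression(max_iter=2000, random_state=seed)


def _scorer(kind: str):
    if kind == "linear_svm":
        return make_scorer(
            hinge_loss, greater_is_better=False, response_method="decision_function"
        )
    return make_scorer(
        log_loss, greater_is_better=False, response_method="predict_proba"
    )


@dataclass
class TrainedBaseline:
    """A fitted baseline emitting calibrated [0, 1] probabilities."""

    kind: str
    estimator: object
    feature_schema: list[str]
    spec: BaselineSpec

    def predict_proba(self, data: FeatureMatrix) -> np.ndarray:
        x = align_features(data, self.feature_schema)
        if self.kind == "linear_svm" and self.spec.svm_probability == "minmax":
            scores = self.estimator.decision_function(x)
            lo, hi = float(scores.min()), float(scores.max())
            if hi == lo:
                return np.full(len(scores), 0.5)
            return (scores - lo) / (hi - lo)
        return self.estimator.predict_proba(x)[:, 1]


def train_baseline(
    train: FeatureMatrix, spec: BaselineSpec, k: int = 3
) -> TrainedBaseline:
    """Tune by k-fold CV on the learner's own loss, then refit on all rows."""
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValidationError("baseline training requires both classes")
    x = train.values
    grid = spec.effective_grid
    estimator = _make_estimator(spec.kind, spec.seed)

    single_point = all(len(v) == 1 for v in grid.values())
    if single_point:
        estimator.set_params(**{key: v[0] for key, v in grid.items()})
        best = estimator
    else:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
        search = GridSearchCV(
            estimator, grid, scoring=_scorer(spec.kind), cv=cv, n_jobs=1
        )
        search.fit(x, y)
        best = _make_estimator(spec.kind, spec.seed)
        best.set_params(**search.best_params_)

    if spec.kind == "linear_svm" and spec.svm_probability == "platt":
        best = CalibratedClassifierCV(best, method="sigmoid", cv=min(k, 3))
        kind = "logistic_regression"  # calibrated wrapper exposes predict_proba
        best.fit(x, y)
        return TrainedBaseline(kind, best, list(train.feature_names), spec)

    best.fit(x, y)
    return TrainedBaseline(spec.kind, best, list(train.feature_names), spec)


def combined_predict(
    p_lgd: Mapping[str, float],
    p_missense: Mapping[str, float],
    cohort: str = "both_only",
) -> dict[str, float]:
    """Per-sample maximum over the two variant-class-specific models.

    ``both_only`` keeps samples with both variant classes (error on
    one-sided samples); ``all`` passes one-sided samples through with their
    single model's probability.
    """
    if cohort not in ("both_only", "all"):
        raise ValueError(f"unknown cohort mode {cohort!r}")
    if cohort == "both_only":
        one_sided = sorted(set(p_lgd) ^ set(p_missense))
        if one_sided:
            raise ValidationError(
                f"samples present in only one model: {one_sided[:10]}"
            )
        return {s: max(p_lgd[s], p_missense[s]) for s in p_lgd}
    out: dict[str, float] = {}
    for s in set(p_lgd) | set(p_missense):
        if s in p_lgd and s in p_missense:
            out[s] = max(p_lgd[s], p_missense[s])
        elif s in p_lgd:
            out[s] = p_lgd[s]
        else:
            out[s] = p_missense[s]
    return out


def ensemble_predict(
    prob_maps: Sequence[Mapping[str, float]],
) -> dict[str, float]:
    """Arithmetic mean probability per sample across models."""
    if not prob_maps:
        raise ValidationError("ensemble requires at least one probability map")
    keys = set(prob_maps[0])
    for pm in prob_maps[1:]:
        if set(pm) != keys:
            raise ValidationError("probability maps cover different samples")
    return {s: float(np.mean([pm[s] for pm in prob_maps])) for s in keys}


@dataclass(frozen=True)
class HeuristicRule:
    """Classify a sample as a case on an LGD hit in a qualifying gene."""

    rule_kind: str  # gene_list | pli_threshold | loeuf_threshold
    gene_set: frozenset[str] = frozenset()
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.rule_kind not in ("gene_list", "pli_threshold", "loeuf_threshold"):
            raise ValidationError(f"unknown rule kind {self.rule_kind!r}")
        if self.rule_kind == "gene_list" and not self.gene_set:
            raise ValidationError("gene_list rules need a non-empty gene set")


def _gene_qualifies(gene: str, scores: GeneScoreTable, rule: HeuristicRule) -> bool:
    if rule.rule_kind == "gene_list":
        return gene in rule.gene_set
    score_name = "pli" if rule.rule_kind == "pli_threshold" else "loeuf"
    if scores.is_missing(gene, score_name):
        logger.info("gene %s missing %s; treated as non-qualifying", gene, score_name)
        return False
    value = float(scores.table.at[gene, score_name])
    if rule.rule_kind == "pli_threshold":
        return value >= rule.threshold
    return value < rule.threshold


def heuristic_classify(
    variants: Sequence[VariantRecord],
    scores: GeneScoreTable,
    rule: HeuristicRule,
) -> dict[str, int]:
    """1 iff a sample has >=1 LGD variant in a qualifying gene.

    Missense variants never trigger a heuristic; all samples appearing in
    ``variants`` receive a call.
    """
    calls: dict[str, int] = {}
    for v in variants:
        calls.setdefault(v.sample_id, 0)
        if v.variant_class is VariantClass.LGD and _gene_qualifies(
            v.gene, scores, rule
        ):
            calls[v.sample_id] = 1
    return calls
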