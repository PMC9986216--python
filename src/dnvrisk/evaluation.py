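"""Low-FPR metrics and the repeated-split evaluation harness.

Metrics: TPR at FPR < ``fpr_max`` (strict on both the rate and the score
comparison), ROC-AUC as the Mann-Whitney probability with ties at 1/2, and
PR-AUC by step-wise precision-recall integration. The harness repeats
stratified 75/25 splits, hands the identical split to every model, and
aggregates mean, percentile 95% CI, and a z-score against a uniform-random
reference model ((mean_model - mean_random) / sd_random, sd with n-1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .baselines import (
    BaselineSpec,
    TrainedBaseline,
    combined_predict,
    ensemble_predict,
    train_baseline,
)
from .errors import ValidationError
from .io_features import (
    FeatureMatrix,
    GeneScoreTable,
    VariantClass,
    VariantRecord,
    build_feature_matrix,
)
from .snn import SNNHyperparams, optimize_hyperparams, snn_fit, snn_predict

logger = logging.getLogger(__name__)

METRIC_NAMES = ("tpr_at_fpr", "roc_auc", "pr_auc")
BASELINE_MODEL_NAMES = ("random_forest", "linear_svm", "logistic_regression")
DELETERIOUS_THRESHOLD = 0.803  # PrimateAI cut-off for "deleterious" missense


@dataclass(frozen=True)
class SplitPlan:
    """One stratified train/test partition of the sample universe."""

    iteration: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction_train: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValidationError(f"train/test overlap: {sorted(overlap)[:5]}")


def make_split_plans(
    sample_ids: Sequence[str],
    labels: Mapping[str, int],
    n_iter: int,
    fraction_train: float = 0.75,
    seed: int = 0,
) -> list[SplitPlan]:
    """Label-stratified repeated splits with |train| = round(f * n)."""
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    target = int(round(fraction_train * n))
    y = np.array([labels[s] for s in sample_ids])
    by_class = {c: np.flatnonzero(y == c) for c in (1, 0)}
    root = np.random.default_rng(seed)
    plans = []
    for it in range(n_iter):
        rng = np.random.default_rng(root.integers(0, 2**63))
        # largest-remainder allocation of train slots across classes
        quotas = {c: fraction_train * len(idx) for c, idx in by_class.items()}
        counts = {c: int(np.floor(q)) for c, q in quotas.items()}
        short = target - sum(counts.values())
        for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True):
            if short <= 0:
                break
            counts[c] += 1
            short -= 1
        train_idx: list[int] = []
        test_idx: list[int] = []
        for c, idx in by_class.items():
            perm = rng.permutation(idx)
            train_idx.extend(perm[: counts[c]])
            test_idx.extend(perm[counts[c] :])
        plans.append(
            SplitPlan(
                iteration=it,
                train_ids=tuple(sample_ids[i] for i in sorted(train_idx)),
                test_ids=tuple(sample_ids[i] for i in sorted(test_idx)),
                fraction_train=fraction_train,
                seed=seed,
            )
        )
    return plans


def tpr_at_fpr(
    case_scores: Sequence[float] | np.ndarray,
    control_scores: Sequence[float] | np.ndarray,
    fpr_max: float = 0.01,
) -> float:
    """Fraction of cases strictly above the largest admissible threshold.

    With m controls, k is the largest integer satisfying k/m < fpr_max and
    the threshold is the (k+1)-th largest control score; cases must score
    strictly above it. k = 0 reduces to the fraction of cases above the
    maximum control score.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if controls.size == 0:
        raise ValidationError("control score vector is empty; threshold undefined")
    if cases.size == 0:
        raise ValidationError("case score vector is empty")
    if not 0.0 <= fpr_max <= 1.0:
        raise ValidationError("fpr_max must lie in [0, 1]")
    m = controls.size
    k = int(np.floor(m * fpr_max))
    while k > 0 and k >= m * fpr_max:  # enforce strict k/m < fpr_max
        k -= 1
    sorted_controls = np.sort(controls)[::-1]
    threshold = sorted_controls[min(k, m - 1)]
    return float(np.mean(cases > threshold))


def roc_auc(
    case_scores: Sequence[float] | np.ndarray,
    control_scores: Sequence[float] | np.ndarray,
) -> float:
    """Mann-Whitney probability P(case > control), ties counted 1/2."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("both score vectors must be non-empty")
    ranks = rankdata(np.concatenate([cases, controls]))
    rank_sum = ranks[: cases.size].sum()
    n1, n0 = cases.size, controls.size
    return float((rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def pr_auc(
    case_scores: Sequence[float] | np.ndarray,
    control_scores: Sequence[float] | np.ndarray,
) -> float:
    """Average precision: step-wise integral of the PR curve (no interpolation)."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("both score vectors must be non-empty")
    scores = np.concatenate([cases, controls])
    labels = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]

    total_cases = cases.size
    auc = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = scores.size
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:  # process tied scores together
            j += 1
        tp += int(labels[i:j].sum())
        fp += (j - i) - int(labels[i:j].sum())
        recall = tp / total_cases
        precision = tp / (tp + fp)
        auc += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(auc)


def randomized_predictions(
    sample_ids: Sequence[str], seed: int
) -> dict[str, float]:
    """i.i.d. Uniform(0, 1) probability per sample, reproducible under seed."""
    rng = np.random.default_rng(seed)
    return {s: float(rng.uniform()) for s in sample_ids}


def zscore(
    model_values: Sequence[float] | np.ndarray,
    random_values: Sequence[float] | np.ndarray,
) -> float:
    """(mean(model) - mean(random)) / sd(random), sd with n-1 denominator."""
    mv = np.asarray(model_values, dtype=float)
    rv = np.asarray(random_values, dtype=float)
    if mv.size < 2 or rv.size < 2:
        raise ValidationError("z-score needs >= 2 values per vector")
    sd = float(np.std(rv, ddof=1))
    if sd == 0.0:
        raise ValidationError("randomized-model values have zero variance")
    return float((mv.mean() - rv.mean()) / sd)


@dataclass
class MetricsReport:
    """Aggregated per-setting, per-model metric summaries."""

    results: dict  # setting -> model -> metric -> {mean, ci_low, ci_high, z, values}
    n_iter: int
    prevalence: dict  # setting -> list of per-iteration test-set case fractions
    metadata: dict
    splits: list[SplitPlan] = field(default_factory=list)

    def to_dict(self, include_values: bool = True) -> dict:
        results = {}
        for setting, models in self.results.items():
            results[setting] = {}
            for model, metrics in models.items():
                results[setting][model] = {}
                for metric, entry in metrics.items():
                    out = dict(entry)
                    if not include_values:
                        out.pop("values", None)
                    results[setting][model][metric] = out
        return {
            "results": results,
            "n_iter": self.n_iter,
            "prevalence": self.prevalence,
            "metadata": self.metadata,
            "splits": [
                {
                    "iteration": p.iteration,
                    "train_ids": list(p.train_ids),
                    "test_ids": list(p.test_ids),
                }
                for p in self.splits
            ],
        }

    def to_json(self, path: str | Path, include_values: bool = True) -> None:
        Path(path).write_text(json.dumps(self.to_dict(include_values), indent=2))

    def to_tsv(self, path: str | Path) -> None:
        """Flat table: one row per setting x model x metric."""
        lines = ["Setting\tModel\tMetric\tMean\tCI_low\tCI_high\tZ"]
        for setting, models in self.results.items():
            for model, metrics in models.items():
                for metric, entry in metrics.items():
                    z = entry["z"]
                    lines.append(
                        f"{setting}\t{model}\t{metric}\t{entry['mean']!r}\t"
                        f"{entry['ci_low']!r}\t{entry['ci_high']!r}\t"
                        f"{'' if z is None else repr(z)}"
                    )
        Path(path).write_text("\n".join(lines) + "\n")


def _percentile_ci(values: np.ndarray) -> tuple[float, float]:
    return (
        float(np.percentile(values, 2.5)),
        float(np.percentile(values, 97.5)),
    )


def _metrics_for(
    probs: Mapping[str, float], labels: Mapping[str, int], fpr_max: float
) -> dict[str, float]:
    cases = np.array([p for s, p in probs.items() if labels[s] == 1])
    controls = np.array([p for s, p in probs.items() if labels[s] == 0])
    return {
        "tpr_at_fpr": tpr_at_fpr(cases, controls, fpr_max),
        "roc_auc": roc_auc(cases, controls),
        "pr_auc": pr_auc(cases, controls),
    }


def _deleterious_only(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    return [
        v
        for v in variants
        if v.variant_class is not VariantClass.MISSENSE
        or (v.pathogenicity is not None and v.pathogenicity >= DELETERIOUS_THRESHOLD)
    ]


def run_experiment(
    variants: Sequence[VariantRecord],
    scores: GeneScoreTable,
    *,
    models: Sequence[str] = ("snn",) + BASELINE_MODEL_NAMES,
    settings: Sequence[str] = ("lgd", "missense", "combined"),
    n_iter: int = 100,
    seed: int = 0,
    fraction_train: float = 0.75,
    fpr_max: float = 0.01,
    snn_hp: SNNHyperparams | None = None,
    snn_grid: Sequence[SNNHyperparams] | None = None,
    optimize_snn: str = "never",  # never | first | always
    baseline_grids: Mapping[str, Mapping[str, list]] | None = None,
    k_cv: int = 3,
    trivial: bool = False,
    missense_filter: str = "none",  # none | train_deleterious | exclude_non_deleterious
    keep_splits: bool = True,
) -> MetricsReport:
    """Repeated-split evaluation with identical splits shared by all models.

    Per iteration the cohort (union of samples carrying LGD or missense
    variants, as requested by ``settings``) is split 75/25 stratified by
    label; variant-class-specific models train on the training samples that
    carry that class and are scored on the matching test samples. Derived
    rows: ``combined`` (per-sample max over the two class-specific models,
    on samples with both classes), ``ensemble`` (mean over all trained
    models), ``ensemble_minus_snn``, and a uniform ``randomized`` reference.
    """
    if n_iter < 2:
        raise ValidationError("n_iter must be >= 2 for confidence intervals")
    if missense_filter not in ("none", "train_deleterious", "exclude_non_deleterious"):
        raise ValueError(f"unknown missense_filter {missense_filter!r}")
    if optimize_snn not in ("never", "first", "always"):
        raise ValueError(f"unknown optimize_snn {optimize_snn!r}")

    need_lgd = "lgd" in settings or "combined" in settings
    need_mis = "missense" in settings or "combined" in settings
    mode = "trivial" if trivial else "full"

    matrices: dict[str, dict[str, FeatureMatrix]] = {}
    if need_lgd:
        fm = build_feature_matrix(variants, scores, VariantClass.LGD, mode)
        matrices["lgd"] = {"train": fm, "test": fm}
    if need_mis:
        if missense_filter == "none":
            fm = build_feature_matrix(variants, scores, VariantClass.MISSENSE, mode)
            matrices["missense"] = {"train": fm, "test": fm}
        elif missense_filter == "train_deleterious":
            fm_del = build_feature_matrix(
                _deleterious_only(variants), scores, VariantClass.MISSENSE, mode
            )
            fm_all = build_feature_matrix(variants, scores, VariantClass.MISSENSE, mode)
            matrices["missense"] = {"train": fm_del, "test": fm_all}
        else:  # exclude_non_deleterious
            fm_del = build_feature_matrix(
                _deleterious_only(variants), scores, VariantClass.MISSENSE, mode
            )
            matrices["missense"] = {"train": fm_del, "test": fm_del}

    labels: dict[str, int] = {}
    universe: list[str] = []
    for cls in matrices.values():
        for fm in (cls["train"], cls["test"]):
            for s, y in zip(fm.sample_ids, fm.labels):
                if s not in labels:
                    labels[s] = int(y)
                    universe.append(s)

    plans = make_split_plans(universe, labels, n_iter, fraction_train, seed)
    seed_seq = np.random.SeedSequence(seed)
    iter_seeds = seed_seq.generate_state(4 * n_iter, dtype=np.uint32).reshape(n_iter, 4)

    if snn_hp is None:
        snn_hp = SNNHyperparams()
    tuned_hp: dict[str, SNNHyperparams] = {}

    per_iter: dict[str, dict[str, list[dict[str, float]]]] = {
        s: {} for s in settings
    }
    prevalence: dict[str, list[float]] = {s: [] for s in settings}

    for it, plan in enumerate(plans):
        train_set, test_set = set(plan.train_ids), set(plan.test_ids)
        class_probs: dict[str, dict[str, dict[str, float]]] = {}

        for cls_name, pair in matrices.items():
            fm_train_all, fm_test_all = pair["train"], pair["test"]
            train_ids = [s for s in fm_train_all.sample_ids if s in train_set]
            test_ids = [s for s in fm_test_all.sample_ids if s in test_set]
            if not train_ids or not test_ids:
                raise ValidationError(
                    f"iteration {it}: empty {cls_name} train or test subset"
                )
            fm_train = fm_train_all.subset(train_ids)
            fm_test = fm_test_all.subset(test_ids)
            class_probs[cls_name] = {}

            for model_name in models:
                if model_name == "snn":
                    hp = snn_hp
                    if optimize_snn == "always" or (
                        optimize_snn == "first" and cls_name not in tuned_hp
                    ):
                        grid = list(snn_grid) if snn_grid else [snn_hp]
                        hp = optimize_hyperparams(
                            fm_train, grid, k=k_cv, seed=int(iter_seeds[it, 0])
                        )
                        tuned_hp[cls_name] = hp
                    elif optimize_snn == "first":
                        hp = tuned_hp[cls_name]
                    model = snn_fit(fm_train, hp)
                    probs = snn_predict(model, fm_test)
                else:
                    grid = (
                        baseline_grids.get(model_name)
                        if baseline_grids is not None
                        else None
                    )
                    spec = BaselineSpec(
                        kind=model_name, grid=grid, seed=int(iter_seeds[it, 1])
                    )
                    trained = train_baseline(fm_train, spec, k=k_cv)
                    probs = trained.predict_proba(fm_test)
                class_probs[cls_name][model_name] = dict(
                    zip(fm_test.sample_ids, (float(p) for p in probs))
                )

        for setting in settings:
            if setting == "lgd":
                maps = class_probs["lgd"]
            elif setting == "missense":
                maps = class_probs["missense"]
            else:  # combined: samples with both variant classes in the test set
                shared = set(class_probs["lgd"]
                             [next(iter(models))]) & set(
                    class_probs["missense"][next(iter(models))]
                )
                if not shared:
                    raise ValidationError(
                        f"iteration {it}: no test samples carry both variant classes"
                    )
                maps = {
                    m: combined_predict(
                        {s: class_probs["lgd"][m][s] for s in shared},
                        {s: class_probs["missense"][m][s] for s in shared},
                        cohort="both_only",
                    )
                    for m in models
                }

            maps = dict(maps)
            if len(models) >= 2:
                maps["ensemble"] = ensemble_predict([maps[m] for m in models])
                non_snn = [m for m in models if m != "snn"]
                if "snn" in models and non_snn:
                    maps["ensemble_minus_snn"] = ensemble_predict(
                        [maps[m] for m in non_snn]
                    )
            eval_samples = list(next(iter(maps.values())).keys())
            maps["randomized"] = randomized_predictions(
                eval_samples, int(iter_seeds[it, 2]) + list(settings).index(setting)
            )

            prevalence[setting].append(
                float(np.mean([labels[s] for s in eval_samples]))
            )
            for model_name, prob_map in maps.items():
                entry = per_iter[setting].setdefault(model_name, [])
                entry.append(_metrics_for(prob_map, labels, fpr_max))

    results: dict = {}
    for setting in settings:
        results[setting] = {}
        random_vectors = {
            metric: np.array(
                [row[metric] for row in per_iter[setting]["randomized"]]
            )
            for metric in METRIC_NAMES
        }
        for model_name, rows in per_iter[setting].items():
            results[setting][model_name] = {}
            for metric in METRIC_NAMES:
                values = np.array([row[metric] for row in rows])
                ci_low, ci_high = _percentile_ci(values)
                if model_name == "randomized":
                    z = None
                else:
                    try:
                        z = zscore(values, random_vectors[metric])
                    except ValidationError:
                        logger.warning(
                            "degenerate randomized reference for %s/%s/%s; "
                            "z-score undefined",
                            setting,
                            model_name,
                            metric,
                        )
                        z = None
                results[setting][model_name][metric] = {
                    "mean": float(values.mean()),
                    "ci_low": ci_low,
                    "ci_high": ci_high,
                    "z": z,
                    "values": [float(v) for v in values],
                }

    metadata = {
        "seed": seed,
        "fpr_max": fpr_max,
        "fraction_train": fraction_train,
        "trivial": trivial,
        "missense_filter": missense_filter,
        "ci_method": "percentile over iteration values (2.5/97.5)",
        "z_method": "(mean_model - mean_random) / sd_random, ddof=1",
    }
    return MetricsReport(
        results=results,
        n_iter=n_iter,
        prevalence=prevalence,
        metadata=metadata,
        splits=list(plans) if keep_splits else [],
    )
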