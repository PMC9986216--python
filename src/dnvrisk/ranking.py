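"""Gene prioritization via artificial single-variant samples.

Each artificial sample carries exactly one variant in one gene; the mean
predicted case probability over per-iteration trained models ranks genes.
The per-gene case/control enrichment difference is a documented proxy
(the exact published formula is unavailable):

    e_diff(g) = c_g / C - u_g / U

with c_g/u_g the case/control variant counts of the matching class in gene
g and C/U the class totals. The proxy conserves mass: summed over all
mutated genes it equals zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .baselines import TrainedBaseline
from .errors import ValidationError
from .evaluation import make_split_plans
from .io_features import (
    SCORE_NAMES,
    FeatureMatrix,
    GeneScoreTable,
    Phenotype,
    VariantClass,
    VariantRecord,
)
from .snn import SNNHyperparams, SNNModel, snn_fit, snn_predict

logger = logging.getLogger(__name__)

ENRICHMENT_PROXY_NOTE = (
    "e_diff = c_g/C - u_g/U (per-gene case/control variant-share difference); "
    "proxy formula, see module docstring"
)


@dataclass
class ArtificialSampleSet:
    """One feature row per rankable gene, plus bookkeeping flags."""

    matrix: FeatureMatrix
    genes: list[str]
    extrapolated: list[bool]
    excluded: list[str]

    @property
    def variant_class(self) -> VariantClass:
        return self.matrix.variant_class


def make_artificial_samples(
    genes: Sequence[str],
    variant_class: VariantClass,
    scores: GeneScoreTable,
    schema: Sequence[str],
    pathogenicity: float = 1.0,
    extrapolate: bool = False,
) -> ArtificialSampleSet:
    """Build single-variant rows against a trained model's feature schema.

    LGD mode sets the gene indicator to 1 and fills the score columns with
    that gene's (imputed) scores; missense mode sets the gene cell to
    ``pathogenicity`` (default 1.0, the most deleterious). Genes outside
    the schema are excluded, unless ``extrapolate`` is true and the schema
    carries score columns, in which case LGD rows are built from score
    features alone and flagged extrapolated.
    """
    if not genes:
        raise ValidationError("empty gene list")
    if not 0.0 <= pathogenicity <= 1.0:
        raise ValidationError("artificial pathogenicity must lie in [0, 1]")
    schema = list(schema)
    score_cols = [c for c in schema if c in SCORE_NAMES]
    gene_cols = [c for c in schema if c not in SCORE_NAMES]
    gene_pos = {g: j for j, g in enumerate(gene_cols)}
    score_pos = {c: len(gene_cols) + j for j, c in enumerate(score_cols)}

    kept: list[str] = []
    flags: list[bool] = []
    rows: list[np.ndarray] = []
    excluded: list[str] = []
    for gene in genes:
        in_schema = gene in gene_pos
        if not in_schema and not (
            extrapolate and variant_class is VariantClass.LGD and score_cols
        ):
            logger.info("gene %s not in model schema; excluded from ranking", gene)
            excluded.append(gene)
            continue
        row = np.zeros(len(schema))
        if in_schema:
            row[gene_pos[gene]] = (
                1.0 if variant_class is VariantClass.LGD else pathogenicity
            )
        if variant_class is VariantClass.LGD and score_cols:
            gene_scores = dict(zip(SCORE_NAMES, scores.features_for(gene)))
            for col in score_cols:
                row[score_pos[col]] = gene_scores[col]
        kept.append(gene)
        flags.append(not in_schema)
        rows.append(row)
    if not rows:
        raise ValidationError("no genes could be ranked against this schema")

    matrix = FeatureMatrix(
        sample_ids=list(kept),
        gene_columns=gene_cols,
        score_columns=score_cols,
        values=np.vstack(rows),
        labels=np.zeros(len(kept), dtype=int),
        variant_class=variant_class,
    )
    return ArtificialSampleSet(
        matrix=matrix, genes=kept, extrapolated=flags, excluded=excluded
    )


@dataclass
class GeneRanking:
    """Per-gene mean probability, percentile 95% CI, rank, and e_diff."""

    table: pd.DataFrame  # Gene, MeanProbability, CI_low, CI_high, Rank, Extrapolated
    n_iter: int
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _predict_with(model, matrix: FeatureMatrix) -> np.ndarray:
    if isinstance(model, SNNModel):
        return snn_predict(model, matrix)
    if isinstance(model, TrainedBaseline):
        return model.predict_proba(matrix)
    if callable(model):
        return np.asarray(model(matrix), dtype=float)
    raise TypeError(f"cannot predict with object of type {type(model)!r}")


def rank_genes(
    models: Sequence[object],
    artificial: ArtificialSampleSet,
    n_iter: int | None = None,
) -> GeneRanking:
    """Rank genes by mean predicted probability across iteration models.

    Descending probability; ties broken lexicographically by gene symbol.
    Ranking is invariant to the input gene order.
    """
    if not models:
        raise ValidationError("at least one trained model is required")
    n_iter = len(models) if n_iter is None else n_iter
    preds = np.vstack([_predict_with(m, artificial.matrix) for m in models])

    mean = preds.mean(axis=0)
    ci_low = np.percentile(preds, 2.5, axis=0)
    ci_high = np.percentile(preds, 97.5, axis=0)
    frame = pd.DataFrame(
        {
            "Gene": artificial.genes,
            "MeanProbability": mean,
            "CI_low": ci_low,
            "CI_high": ci_high,
            "Extrapolated": artificial.extrapolated,
        }
    )
    frame = frame.sort_values(
        ["MeanProbability", "Gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    frame["Rank"] = np.arange(1, len(frame) + 1)
    frame["E_diff"] = np.nan
    frame = frame[
        ["Gene", "MeanProbability", "CI_low", "CI_high", "Rank", "E_diff", "Extrapolated"]
    ]
    return GeneRanking(
        table=frame,
        n_iter=len(models),
        metadata={"variant_class": artificial.variant_class.value},
    )


def enrichment_diff(
    ranking: GeneRanking,
    variants: Sequence[VariantRecord],
    mutation_class: VariantClass,
    n_bins: int = 20,
) -> tuple[GeneRanking, pd.DataFrame]:
    """Fill per-gene e_diff and return a probability-binned mean curve.

    Bins are equal-width on [0, 1]; the curve reports the mean e_diff and
    gene count per non-empty bin. The proxy formula is recorded in the
    ranking metadata.
    """
    class_variants = [v for v in variants if v.variant_class is mutation_class]
    case_total = sum(1 for v in class_variants if v.phenotype is Phenotype.CASE)
    control_total = len(class_variants) - case_total
    if case_total == 0 or control_total == 0:
        raise ValidationError(
            "e_diff needs at least one case and one control variant of the class"
        )
    case_counts: dict[str, int] = {}
    control_counts: dict[str, int] = {}
    for v in class_variants:
        bucket = case_counts if v.phenotype is Phenotype.CASE else control_counts
        bucket[v.gene] = bucket.get(v.gene, 0) + 1

    table = ranking.table.copy()
    table["E_diff"] = [
        case_counts.get(g, 0) / case_total - control_counts.get(g, 0) / control_total
        for g in table["Gene"]
    ]
    ranking = GeneRanking(
        table=table,
        n_iter=ranking.n_iter,
        metadata={**ranking.metadata, "e_diff_formula": ENRICHMENT_PROXY_NOTE},
    )

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(
        np.digitize(table["MeanProbability"], edges[1:-1], right=False), 0, n_bins - 1
    )
    rows = []
    for b in range(n_bins):
        mask = bin_idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_e_diff": float(table.loc[mask, "E_diff"].mean()),
                "n_genes": int(mask.sum()),
            }
        )
    curve = pd.DataFrame(rows, columns=["bin_low", "bin_high", "mean_e_diff", "n_genes"])
    return ranking, curve


def correlate_with_constraint(
    ranking: GeneRanking, scores: GeneScoreTable
) -> dict[str, dict[str, float]]:
    """Spearman rho/p of mean probability vs each gene score.

    Missing-score genes are excluded pairwise; expected signs are positive
    for pLI/phastCons and negative for LOEUF/RVIS when the ranking tracks
    constraint.
    """
    out: dict[str, dict[str, float]] = {}
    probs = ranking.table.set_index("Gene")["MeanProbability"]
    for name in SCORE_NAMES:
        values = scores.table[name].reindex(probs.index)
        mask = values.notna()
        if mask.sum() < 3:
            raise ValidationError(
                f"need >= 3 genes with non-missing {name} for correlation"
            )
        sub = values[mask]
        if sub.nunique() < 2:
            raise ValidationError(f"{name} score vector is constant; rho undefined")
        rho, p = spearmanr(probs[mask], sub)
        out[name] = {"rho": float(rho), "p_value": float(p)}
    return out


def fit_models_over_splits(
    matrix: FeatureMatrix,
    hp: SNNHyperparams,
    n_iter: int = 100,
    fraction_train: float = 0.75,
    seed: int = 0,
) -> list[SNNModel]:
    """Train one network per stratified train split (ranking convenience)."""
    labels = dict(zip(matrix.sample_ids, (int(y) for y in matrix.labels)))
    plans = make_split_plans(matrix.sample_ids, labels, n_iter, fraction_train, seed)
    return [snn_fit(matrix.subset(list(p.train_ids)), hp) for p in plans]
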