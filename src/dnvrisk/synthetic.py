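"""Synthetic case/control cohorts with planted risk genes.

Per-sample variant counts are Poisson with class-specific rates (defaults
0.21 vs 0.12 LGD events per sample for cases vs controls, i.e. a roughly
twofold case excess). Control variants land uniformly on genes; each case
variant is routed to a planted risk gene with probability
``excess_fraction * risk_gene_share`` where ``excess_fraction`` is the
share of the case rate exceeding the control rate. Risk genes draw skewed
constraint scores (high pLI, low LOEUF); RVIS and phastCons are noisy
monotone transforms of LOEUF and pLI respectively, giving realistic
collinearity. Missense pathogenicity is Beta-distributed, shifted upward
for case variants in risk genes by ``pathogenicity_shift`` (0 makes case
and control distributions identical).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_features import (
    SCORE_NAMES,
    GeneScoreTable,
    Phenotype,
    VariantClass,
    VariantRecord,
)

_PATHO_CONCENTRATION = 4.0  # Beta(a, b) with a + b fixed at this value


@dataclass(frozen=True)
class CohortConfig:
    n_cases: int = 1000
    n_controls: int = 1000
    n_genes: int = 200
    n_risk_genes: int = 20
    lgd_rate_case: float = 0.21
    lgd_rate_control: float = 0.12
    missense_rate_case: float = 0.91
    missense_rate_control: float = 0.76
    risk_gene_share: float = 0.5
    pathogenicity_shift: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1 or self.n_genes < 1:
            raise ValidationError("cohort dimensions must be positive")
        if self.n_risk_genes > self.n_genes:
            raise ValidationError("n_risk_genes cannot exceed n_genes")
        if self.n_risk_genes < 0:
            raise ValidationError("n_risk_genes must be >= 0")
        for rate in (
            self.lgd_rate_case,
            self.lgd_rate_control,
            self.missense_rate_case,
            self.missense_rate_control,
        ):
            if rate < 0:
                raise ValidationError("variant rates must be >= 0")
        if not 0.0 <= self.risk_gene_share <= 1.0:
            raise ValidationError("risk_gene_share must lie in [0, 1]")


def _excess_fraction(rate_case: float, rate_control: float) -> float:
    if rate_case <= 0:
        return 0.0
    return max(0.0, 1.0 - rate_control / rate_case)


def _gene_scores(
    genes: Sequence[str], risk: set[str], rng: np.random.Generator
) -> GeneScoreTable:
    n = len(genes)
    is_risk = np.array([g in risk for g in genes])
    # latent per-gene constraint: high Beta(5,1) for risk genes, low Beta(1,5)
    # otherwise; the four metrics are noisy views of it, which reproduces the
    # strong collinearity among real constraint scores
    latent = np.where(is_risk, rng.beta(5, 1, n), rng.beta(1, 5, n))
    pli = np.clip(latent + rng.normal(0.0, 0.08, n), 0.0, 1.0)
    loeuf = 2.0 * np.clip(1.0 - latent + rng.normal(0.0, 0.08, n), 0.0, 1.0)
    rvis = 3.0 * (loeuf - 1.0) + rng.normal(0.0, 0.5, n)
    phastcons = np.clip(0.8 * pli + 0.2 * rng.uniform(0, 1, n), 0.0, 1.0)
    frame = pd.DataFrame(
        {"pli": pli, "loeuf": loeuf, "rvis": rvis, "phastcons": phastcons},
        index=pd.Index(genes, name="Gene"),
    )
    return GeneScoreTable(frame)


def _pathogenicity(is_shifted: bool, shift: float, rng: np.random.Generator) -> float:
    mean = 0.5 + (shift if is_shifted else 0.0)
    mean = min(max(mean, 0.02), 0.98)
    a = _PATHO_CONCENTRATION * mean
    b = _PATHO_CONCENTRATION * (1.0 - mean)
    return float(rng.beta(a, b))


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[VariantRecord], GeneScoreTable, set[str]]:
    """Generate (variants, gene scores, planted risk-gene set); seeded."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    risk_idx = rng.choice(config.n_genes, size=config.n_risk_genes, replace=False)
    risk = {genes[i] for i in sorted(risk_idx)}
    risk_list = sorted(risk)
    scores = _gene_scores(genes, risk, rng)

    excess = {
        VariantClass.LGD: _excess_fraction(
            config.lgd_rate_case, config.lgd_rate_control
        ),
        VariantClass.MISSENSE: _excess_fraction(
            config.missense_rate_case, config.missense_rate_control
        ),
    }
    rates = {
        (Phenotype.CASE, VariantClass.LGD): config.lgd_rate_case,
        (Phenotype.CONTROL, VariantClass.LGD): config.lgd_rate_control,
        (Phenotype.CASE, VariantClass.MISSENSE): config.missense_rate_case,
        (Phenotype.CONTROL, VariantClass.MISSENSE): config.missense_rate_control,
    }

    variants: list[VariantRecord] = []
    cohorts = [
        (Phenotype.CASE, "case", config.n_cases),
        (Phenotype.CONTROL, "ctrl", config.n_controls),
    ]
    for phenotype, prefix, n_samples in cohorts:
        for i in range(n_samples):
            sample = f"{prefix}{i:05d}"
            for vclass in (VariantClass.LGD, VariantClass.MISSENSE):
                count = rng.poisson(rates[(phenotype, vclass)])
                for _ in range(count):
                    routed = (
                        phenotype is Phenotype.CASE
                        and risk_list
                        and rng.random() < excess[vclass] * config.risk_gene_share
                    )
                    gene = (
                        risk_list[rng.integers(len(risk_list))]
                        if routed
                        else genes[rng.integers(config.n_genes)]
                    )
                    pathogenicity = None
                    if vclass is VariantClass.MISSENSE:
                        shifted = phenotype is Phenotype.CASE and gene in risk
                        pathogenicity = _pathogenicity(
                            shifted, config.pathogenicity_shift, rng
                        )
                    variants.append(
                        VariantRecord(
                            sample_id=sample,
                            phenotype=phenotype,
                            gene=gene,
                            variant_class=vclass,
                            pathogenicity=pathogenicity,
                        )
                    )
    return variants, scores, risk


def write_cohort(
    variants: Sequence[VariantRecord],
    scores: GeneScoreTable,
    out_dir: str | Path,
    risk_genes: set[str] | None = None,
) -> dict[str, Path]:
    """Emit variants.tsv, per-score TSVs, and truth.tsv under ``out_dir``.

    Files use the dialects expected by the readers, so a round trip
    through :func:`dnvrisk.io_features.read_variants` /
    :func:`~dnvrisk.io_features.read_gene_scores` reproduces the records
    and score values exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    variants_path = out_dir / "variants.tsv"
    with open(variants_path, "w") as handle:
        handle.write("SampleID\tPhenotype\tGene\tClass\tPrimateAI\n")
        for v in variants:
            score = "NA" if v.pathogenicity is None else repr(float(v.pathogenicity))
            handle.write(
                f"{v.sample_id}\t{v.phenotype.value}\t{v.gene}\t"
                f"{v.variant_class.value}\t{score}\n"
            )
    paths["variants"] = variants_path

    for name in SCORE_NAMES:
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as handle:
            handle.write("Gene\tScore\n")
            for gene in scores.genes:
                if not scores.is_missing(gene, name):
                    value = float(scores.table.at[gene, name])
                    handle.write(f"{gene}\t{value!r}\n")
        paths[name] = path

    if risk_genes is not None:
        truth_path = out_dir / "truth.tsv"
        with open(truth_path, "w") as handle:
            handle.write("Gene\tIsRiskGene\n")
            for gene in scores.genes:
                handle.write(f"{gene}\t{int(gene in risk_genes)}\n")
        paths["truth"] = truth_path
    return paths
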