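import numpy as np
import pytest

from dnvrisk import (
    CohortConfig,
    GeneScoreTable,
    Phenotype,
    VariantClass,
    VariantRecord,
    build_feature_matrix,
    simulate_cohort,
)


@pytest.fixture
def toy_variants_file(tmp_path):
    """2 LGD + 1 missense + 1 other row."""
    path = tmp_path / "variants.tsv"
    path.write_text(
        "SampleID\tPhenotype\tGene\tClass\tPrimateAI\n"
        "S1\tcase\tGENEA\tlgd\tNA\n"
        "S2\tcase\tGENEB\tlgd\tNA\n"
        "S3\tcontrol\tGENEA\tmissense\t0.7\n"
        "S4\tcontrol\tGENEC\tother\tNA\n"
    )
    return path


@pytest.fixture
def toy_scores():
    return GeneScoreTable.from_dict(
        {
            "GENEA": {"pli": 0.99, "loeuf": 0.2, "rvis": -1.5, "phastcons": 0.9},
            "GENEB": {"pli": 0.10, "loeuf": 1.4, "rvis": 0.8, "phastcons": 0.3},
            "GENEC": {"pli": 0.50, "loeuf": 0.9, "rvis": 0.0, "phastcons": 0.5},
        }
    )


def make_variant(sample, gene, vclass=VariantClass.LGD, case=True, score=None):
    return VariantRecord(
        sample_id=sample,
        phenotype=Phenotype.CASE if case else Phenotype.CONTROL,
        gene=gene,
        variant_class=vclass,
        pathogenicity=score,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by slower tests (session scope)."""
    config = CohortConfig(
        n_cases=300,
        n_controls=300,
        n_genes=60,
        n_risk_genes=10,
        risk_gene_share=0.9,
        seed=123,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_lgd_matrix(small_cohort):
    variants, scores, _ = small_cohort
    return build_feature_matrix(variants, scores, VariantClass.LGD, "full")


@pytest.fixture
def separable_matrix():
    """Cases all carry gene RISK, controls never do: linearly separable."""
    rng = np.random.default_rng(7)
    variants = []
    for i in range(30):
        variants.append(make_variant(f"c{i}", "RISK", case=True))
        if rng.random() < 0.5:
            variants.append(make_variant(f"c{i}", f"BG{rng.integers(5)}", case=True))
    for i in range(30):
        variants.append(make_variant(f"u{i}", f"BG{rng.integers(5)}", case=False))
    scores = GeneScoreTable.from_dict(
        {
            g: {"pli": 0.5, "loeuf": 1.0, "rvis": 0.0, "phastcons": 0.5}
            for g in ["RISK"] + [f"BG{k}" for k in range(5)]
        }
    )
    return build_feature_matrix(variants, scores, VariantClass.LGD, "full")
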