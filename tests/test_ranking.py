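import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from dnvrisk import (
    GeneScoreTable,
    SNNHyperparams,
    VariantClass,
    build_feature_matrix,
    correlate_with_constraint,
    enrichment_diff,
    make_artificial_samples,
    rank_genes,
    snn_fit,
)
from dnvrisk.errors import ValidationError
from dnvrisk.ranking import GeneRanking

from conftest import make_variant


def constant_probability_model(value):
    return lambda fm: np.full(fm.n_samples, value)


def table_model(mapping, default=0.1):
    """Model returning a fixed probability per gene (sample id)."""
    return lambda fm: np.array([mapping.get(s, default) for s in fm.sample_ids])


@pytest.fixture
def simple_ranking():
    table = pd.DataFrame(
        {
            "Gene": ["A", "B", "C", "D"],
            "MeanProbability": [0.9, 0.7, 0.4, 0.1],
            "CI_low": [0.85, 0.6, 0.3, 0.05],
            "CI_high": [0.95, 0.8, 0.5, 0.15],
            "Rank": [1, 2, 3, 4],
            "E_diff": [np.nan] * 4,
            "Extrapolated": [False] * 4,
        }
    )
    return GeneRanking(table=table, n_iter=1)


class TestArtificialSamples:
    def test_lgd_rows_single_indicator(self, toy_scores):
        schema = ["GENEA", "GENEB", "GENEC", "pli", "loeuf", "rvis", "phastcons"]
        art = make_artificial_samples(
            ["GENEA", "GENEB", "GENEC"], VariantClass.LGD, toy_scores, schema
        )
        assert art.matrix.gene_part.sum(axis=1).tolist() == [1.0, 1.0, 1.0]
        assert art.excluded == []

    def test_gene_outside_schema_excluded(self, toy_scores):
        art = make_artificial_samples(
            ["GENEA", "NOVEL"], VariantClass.LGD, toy_scores, ["GENEA"]
        )
        assert art.genes == ["GENEA"]
        assert art.excluded == ["NOVEL"]

    def test_extrapolate_uses_score_features(self, toy_scores):
        schema = ["GENEA", "pli", "loeuf", "rvis", "phastcons"]
        art = make_artificial_samples(
            ["GENEA", "GENEC"], VariantClass.LGD, toy_scores, schema, extrapolate=True
        )
        assert art.genes == ["GENEA", "GENEC"]
        assert art.extrapolated == [False, True]
        np.testing.assert_allclose(art.matrix.values[1], [0.0, 0.5, 0.9, 0.0, 0.5])

    def test_row_matches_real_single_variant_sample(self, toy_scores):
        real = build_feature_matrix(
            [make_variant("S1", "GENEA")], toy_scores, VariantClass.LGD
        )
        art = make_artificial_samples(
            ["GENEA"], VariantClass.LGD, toy_scores, real.feature_names
        )
        assert np.array_equal(art.matrix.values[0], real.values[0])

    def test_missense_pathogenicity_cell(self, toy_scores):
        art = make_artificial_samples(
            ["GENEA"], VariantClass.MISSENSE, toy_scores, ["GENEA", "GENEB"],
            pathogenicity=0.75,
        )
        np.testing.assert_allclose(art.matrix.values[0], [0.75, 0.0])

    def test_empty_gene_list_error(self, toy_scores):
        with pytest.raises(ValidationError):
            make_artificial_samples([], VariantClass.LGD, toy_scores, ["GENEA"])


class TestRankGenes:
    def test_two_genes_ordered(self, toy_scores):
        art = make_artificial_samples(
            ["GENEA", "GENEB"], VariantClass.LGD, toy_scores,
            ["GENEA", "GENEB"],
        )
        model = table_model({"GENEA": 0.1, "GENEB": 0.9})
        ranking = rank_genes([model], art)
        assert ranking.table["Gene"].tolist() == ["GENEB", "GENEA"]
        assert ranking.table["Rank"].tolist() == [1, 2]

    def test_identical_iterations_zero_ci_width(self, toy_scores):
        art = make_artificial_samples(
            ["GENEA"], VariantClass.LGD, toy_scores, ["GENEA"]
        )
        models = [constant_probability_model(0.42)] * 5
        ranking = rank_genes(models, art)
        row = ranking.table.iloc[0]
        assert row["CI_high"] - row["CI_low"] == 0.0
        assert row["MeanProbability"] == pytest.approx(0.42)

    def test_tie_broken_lexicographically(self, toy_scores):
        art = make_artificial_samples(
            ["GENEB", "GENEA"], VariantClass.LGD, toy_scores, ["GENEA", "GENEB"]
        )
        ranking = rank_genes([constant_probability_model(0.5)], art)
        assert ranking.table["Gene"].tolist() == ["GENEA", "GENEB"]

    def test_input_order_invariance(self, toy_scores):
        schema = ["GENEA", "GENEB", "GENEC", "pli", "loeuf", "rvis", "phastcons"]
        model = table_model({"GENEA": 0.3, "GENEB": 0.8, "GENEC": 0.5})
        orderings = [
            ["GENEA", "GENEB", "GENEC"],
            ["GENEC", "GENEA", "GENEB"],
        ]
        tables = []
        for genes in orderings:
            art = make_artificial_samples(genes, VariantClass.LGD, toy_scores, schema)
            tables.append(rank_genes([model], art).table.reset_index(drop=True))
        pd.testing.assert_frame_equal(tables[0], tables[1])

    def test_no_models_error(self, toy_scores):
        art = make_artificial_samples(["GENEA"], VariantClass.LGD, toy_scores, ["GENEA"])
        with pytest.raises(ValidationError):
            rank_genes([], art)


class TestEnrichmentDiff:
    def test_substitution(self, simple_ranking):
        variants = (
            [make_variant(f"S{i}", "A") for i in range(2)]
            + [make_variant(f"S{i+2}", "B") for i in range(8)]
            + [make_variant(f"U{i}", "B", case=False) for i in range(5)]
        )
        ranking, _ = enrichment_diff(simple_ranking, variants, VariantClass.LGD)
        table = ranking.table.set_index("Gene")
        assert table.at["A", "E_diff"] == pytest.approx(0.2)

    def test_equal_distribution_zero(self, simple_ranking):
        variants = []
        for gene in ("A", "B"):
            variants.append(make_variant(f"c{gene}", gene, case=True))
            variants.append(make_variant(f"u{gene}", gene, case=False))
        ranking, _ = enrichment_diff(simple_ranking, variants, VariantClass.LGD)
        assert (ranking.table["E_diff"].dropna().abs() < 1e-12).all()

    def test_mass_conservation(self, simple_ranking):
        rng = np.random.default_rng(17)
        variants = []
        for i in range(60):
            variants.append(
                make_variant(
                    f"S{i}", rng.choice(["A", "B", "C", "D"]), case=bool(i % 2)
                )
            )
        ranking, _ = enrichment_diff(simple_ranking, variants, VariantClass.LGD)
        assert ranking.table["E_diff"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_binned_curve_columns(self, simple_ranking):
        variants = [
            make_variant("S1", "A"),
            make_variant("U1", "B", case=False),
        ]
        _, curve = enrichment_diff(simple_ranking, variants, VariantClass.LGD)
        assert list(curve.columns) == ["bin_low", "bin_high", "mean_e_diff", "n_genes"]
        assert curve["n_genes"].sum() == 4

    def test_missing_class_errors(self, simple_ranking):
        cases_only = [make_variant("S1", "A")]
        with pytest.raises(ValidationError):
            enrichment_diff(simple_ranking, cases_only, VariantClass.LGD)

    def test_proxy_formula_recorded(self, simple_ranking):
        variants = [make_variant("S1", "A"), make_variant("U1", "B", case=False)]
        ranking, _ = enrichment_diff(simple_ranking, variants, VariantClass.LGD)
        assert "e_diff_formula" in ranking.metadata


class TestConstraintCorrelation:
    def test_perfect_monotone_rho_one(self):
        genes = [f"G{i}" for i in range(10)]
        pli = np.linspace(0.05, 0.95, 10)
        scores = GeneScoreTable.from_dict(
            {g: {"pli": p, "loeuf": 2 - 2 * p, "rvis": -p, "phastcons": p}
             for g, p in zip(genes, pli)}
        )
        table = pd.DataFrame(
            {
                "Gene": genes,
                "MeanProbability": pli,  # probability strictly increases with pLI
                "CI_low": pli,
                "CI_high": pli,
                "Rank": rankdata(-pli).astype(int),
                "E_diff": np.nan,
                "Extrapolated": False,
            }
        )
        out = correlate_with_constraint(GeneRanking(table=table, n_iter=1), scores)
        assert out["pli"]["rho"] == pytest.approx(1.0)
        assert out["loeuf"]["rho"] == pytest.approx(-1.0)

    def test_matches_explicit_rank_oracle(self):
        rng = np.random.default_rng(18)
        genes = [f"G{i}" for i in range(30)]
        probs = rng.uniform(0, 1, 30)
        pli = rng.uniform(0, 1, 30)
        scores = GeneScoreTable.from_dict(
            {g: {"pli": p, "loeuf": 1.0 - 0.4 * p, "rvis": float(i % 7) - 3.0,
                 "phastcons": p * 0.9}
             for i, (g, p) in enumerate(zip(genes, pli))}
        )
        table = pd.DataFrame(
            {
                "Gene": genes,
                "MeanProbability": probs,
                "CI_low": probs,
                "CI_high": probs,
                "Rank": rankdata(-probs).astype(int),
                "E_diff": np.nan,
                "Extrapolated": False,
            }
        )
        out = correlate_with_constraint(GeneRanking(table=table, n_iter=1), scores)
        # brute-force Spearman: Pearson correlation of the rank vectors
        rp = rankdata(probs)
        rs = rankdata(pli)
        expected = np.corrcoef(rp, rs)[0, 1]
        assert out["pli"]["rho"] == pytest.approx(expected, abs=1e-12)

    def test_permutation_null_rarely_large(self):
        rng = np.random.default_rng(19)
        n = 50
        probs = rng.uniform(0, 1, n)
        base = rng.uniform(0, 1, n)
        large = 0
        for _ in range(200):
            perm = rng.permutation(base)
            rho = np.corrcoef(rankdata(probs), rankdata(perm))[0, 1]
            if abs(rho) >= 0.4:
                large += 1
        assert large <= 10  # >= 95% below |0.4|

    def test_constant_score_error(self):
        genes = ["A", "B", "C"]
        scores = GeneScoreTable.from_dict(
            {g: {"pli": 0.5, "loeuf": 1.0, "rvis": 0.0, "phastcons": 0.5} for g in genes}
        )
        table = pd.DataFrame(
            {
                "Gene": genes,
                "MeanProbability": [0.1, 0.5, 0.9],
                "CI_low": [0.1, 0.5, 0.9],
                "CI_high": [0.1, 0.5, 0.9],
                "Rank": [3, 2, 1],
                "E_diff": np.nan,
                "Extrapolated": False,
            }
        )
        with pytest.raises(ValidationError):
            correlate_with_constraint(GeneRanking(table=table, n_iter=1), scores)


def test_score_features_beat_trivial_on_planted_cohort(small_cohort):
    # models trained with gene-score features separate planted risk genes
    # better (rank-sum) than trivially trained models on the same cohort
    from scipy.stats import mannwhitneyu

    variants, scores, risk = small_cohort
    hp = SNNHyperparams(lambda1=2.0, hidden_units=8, epochs=150, seed=0)
    separations = {}
    for mode in ("full", "trivial"):
        fm = build_feature_matrix(variants, scores, VariantClass.LGD, mode)
        model = snn_fit(fm, hp)
        art = make_artificial_samples(
            scores.genes, VariantClass.LGD, scores, model.feature_schema,
            extrapolate=(mode == "full"),
        )
        ranking = rank_genes([model], art)
        table = ranking.table
        is_risk = table["Gene"].isin(risk)
        stat = mannwhitneyu(
            table.loc[is_risk, "Rank"], table.loc[~is_risk, "Rank"],
            alternative="less",
        )
        separations[mode] = stat.pvalue
    assert separations["full"] <= separations["trivial"]
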