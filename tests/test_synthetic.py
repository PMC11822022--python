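"""Latent Gaussian-copula cohort generator: margins, dependence, IO."""

import numpy as np
import pytest
from scipy import stats

from cohortnet._matrix import PSDRepairError, is_valid_correlation, nearest_psd_correlation
from cohortnet.association import build_network
from cohortnet.synthetic import (
    CohortTable,
    SyntheticSpec,
    VariableSchema,
    default_spec,
    effect_block_from_variables,
    generate_cohorts,
    plant_effect,
    read_table,
    write_table,
)

from conftest import small_corr, small_schema


class TestVariableSchema:
    def test_binary_requires_one_cutpoint(self):
        with pytest.raises(ValueError, match="exactly 1 cutpoint"):
            VariableSchema("x", "binary", (0.0, 1.0))

    def test_cutpoints_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            VariableSchema("x", "ordinal", (0.5, 0.5))

    def test_continuous_takes_no_cutpoints(self):
        with pytest.raises(ValueError, match="no cutpoints"):
            VariableSchema("x", "continuous", (0.0,))

    def test_unknown_vtype(self):
        with pytest.raises(ValueError, match="unknown vtype"):
            VariableSchema("x", "categorical")

    def test_n_levels(self):
        assert VariableSchema("x", "ordinal", (-1.0, 0.0, 1.0)).n_levels == 4
        assert VariableSchema("x", "binary", (0.0,)).n_levels == 2
        assert VariableSchema("x", "continuous").n_levels is None


class TestSpecValidation:
    def test_invalid_corr_rejected(self):
        corr = small_corr()
        corr[0, 1] = 0.9  # asymmetric
        with pytest.raises(ValueError, match="correlation"):
            SyntheticSpec(schema=small_schema(), latent_corr=corr, seed=0)

    def test_disconnected_effect_block_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            SyntheticSpec(
                schema=small_schema(),
                latent_corr=small_corr(),
                effect_block={(0, 1), (3, 4)},
                effect_delta=0.1,
                seed=0,
            )

    def test_missing_rate_range(self):
        with pytest.raises(ValueError, match="missing_rate"):
            SyntheticSpec(schema=small_schema(), latent_corr=small_corr(), missing_rate=1.0)


class TestGenerateCohorts:
    def test_binary_prevalence_matches_cutpoint(self):
        """Cutpoint 0 gives prevalence 1/2 within 3 binomial SEs at n=10,000."""
        schema = (VariableSchema("b", "binary", (0.0,)), VariableSchema("c", "continuous"))
        spec = SyntheticSpec(schema=schema, latent_corr=np.eye(2), n_pain=5000, n_nopain=5000, seed=3)
        table = generate_cohorts(spec)
        prev = table.data["b"].mean()
        assert abs(prev - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_independence_gives_null_edges(self):
        """Identity latent correlation: observed associations all near 0."""
        spec = SyntheticSpec(
            schema=small_schema(), latent_corr=np.eye(6), n_pain=2500, n_nopain=2500, seed=4
        )
        net = build_network(generate_cohorts(spec))
        off = net.weights[np.triu_indices(6, 1)]
        # 3.9 sigma bound per edge at n=5000 with 15 edges: ~1% family-wise
        assert np.max(np.abs(off)) < 3.9 / np.sqrt(5000)

    def test_copula_spearman_closed_form(self):
        """Two Gaussians at latent rho=0.5: Spearman = (6/pi) arcsin(rho/2)."""
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        schema = (VariableSchema("u", "continuous"), VariableSchema("v", "continuous"))
        spec = SyntheticSpec(schema=schema, latent_corr=corr, n_pain=25_000, n_nopain=25_000, seed=5)
        table = generate_cohorts(spec)
        rho_s = stats.spearmanr(table.data["u"], table.data["v"]).statistic
        expected = (6 / np.pi) * np.arcsin(0.5 / 2)
        assert rho_s == pytest.approx(expected, abs=0.015)

    def test_discrete_margins_match_normal_increments(self):
        """Ordinal category frequencies converge to Phi-increments (n=50,000)."""
        cuts = (-0.5, 0.3, 1.0)
        schema = (VariableSchema("o", "ordinal", cuts), VariableSchema("c", "continuous"))
        spec = SyntheticSpec(schema=schema, latent_corr=np.eye(2), n_pain=25_000, n_nopain=25_000, seed=6)
        table = generate_cohorts(spec)
        freq = table.data["o"].value_counts(normalize=True).sort_index().to_numpy()
        edges = np.concatenate([[-np.inf], cuts, [np.inf]])
        expected = np.diff(stats.norm.cdf(edges))
        assert np.abs(freq - expected).max() < 0.01

    def test_copula_monotone_invariance(self, small_spec):
        """Monotone transforms of continuous margins leave Spearman edges fixed."""
        table = generate_cohorts(small_spec.replace(n_pain=400, n_nopain=400))
        net_before = build_network(table)
        transformed = table.data.copy()
        transformed["fitness"] = np.exp(transformed["fitness"])
        transformed["income"] = transformed["income"] ** 3
        table2 = CohortTable(data=transformed, cohort=table.cohort, schema=table.schema)
        net_after = build_network(table2)
        spearman_mask = net_before.methods == "spearman"
        np.testing.assert_allclose(
            net_before.weights[spearman_mask], net_after.weights[spearman_mask], atol=1e-12
        )

    def test_seeded_determinism(self, small_spec):
        a = generate_cohorts(small_spec)
        b = generate_cohorts(small_spec)
        assert a.equals(b)
        c = generate_cohorts(small_spec.replace(seed=small_spec.seed + 1))
        assert not a.equals(c)

    def test_missingness_rate(self):
        spec = default_spec(n_pain=500, n_nopain=500, missing_rate=0.2, seed=8)
        table = generate_cohorts(spec)
        rate = table.data.isna().to_numpy().mean()
        assert rate == pytest.approx(0.2, abs=0.01)


class TestPlantEffect:
    def test_zero_delta_identity(self):
        spec = default_spec(n_pain=100, n_nopain=100, effect_delta=0.0, seed=0)
        np.testing.assert_array_equal(plant_effect(spec), spec.latent_corr)

    def test_planted_block_raises_pain_correlations(self):
        """Monte-Carlo: pain-cohort empirical correlations on the planted
        block exceed nopain's on average at n=5,000 per cohort."""
        spec = default_spec(n_pain=5000, n_nopain=5000, effect_delta=0.15, seed=9)
        table = generate_cohorts(spec)
        net_p = build_network(table, "pain")
        net_n = build_network(table, "nopain")
        diffs = [net_p.weights[i, j] - net_n.weights[i, j] for i, j in spec.effect_block]
        assert np.mean(diffs) > 0.05

    def test_planted_matrix_is_valid(self):
        spec = default_spec(n_pain=100, n_nopain=100, effect_delta=0.15, seed=0)
        assert is_valid_correlation(plant_effect(spec))

    def test_delta_overflow_never_out_of_range(self):
        """A delta pushing entries past 1 must repair or reject, never emit
        an out-of-range correlation."""
        spec = SyntheticSpec(
            schema=small_schema(),
            latent_corr=small_corr(0.5),
            effect_block=effect_block_from_variables([0, 1, 2]),
            effect_delta=0.7,
            seed=0,
        )
        try:
            planted = plant_effect(spec)
        except PSDRepairError:
            return
        assert is_valid_correlation(planted)


class TestNearestPSD:
    def test_projection_repairs_indefinite(self, rng):
        corr = small_corr(0.3)
        corr[0, 1] = corr[1, 0] = 0.99
        corr[0, 2] = corr[2, 0] = -0.99
        repaired = nearest_psd_correlation(corr)
        assert is_valid_correlation(repaired)

    def test_valid_matrix_unchanged(self):
        corr = small_corr(0.4)
        np.testing.assert_allclose(nearest_psd_correlation(corr), corr, atol=1e-12)


class TestTableIO:
    def test_round_trip_identity(self, small_spec, tmp_path):
        table = generate_cohorts(small_spec.replace(missing_rate=0.1))
        path = tmp_path / "cohorts.csv"
        write_table(table, path)
        back = read_table(path)
        assert back.equals(table)

    def test_heavy_missing_column_preserved(self, small_spec, tmp_path):
        table = generate_cohorts(small_spec)
        data = table.data.copy()
        mask = np.random.default_rng(0).random(len(data)) < 0.3
        data.loc[mask, "mood"] = np.nan
        table = CohortTable(data=data, cohort=table.cohort, schema=table.schema)
        path = tmp_path / "t.csv"
        write_table(table, path)
        back = read_table(path)
        assert back.data["mood"].isna().sum() == int(mask.sum())
        assert back.equals(table)

    def test_unknown_vtype_token_rejected(self, small_spec, tmp_path):
        table = generate_cohorts(small_spec)
        path = tmp_path / "t.csv"
        write_table(table, path)
        schema_path = path.with_suffix(".schema.yaml")
        schema_path.write_text(schema_path.read_text().replace("binary", "bolean"))
        with pytest.raises(ValueError, match="unknown vtype"):
            read_table(path)

    def test_schema_column_mismatch_lists_names(self, small_spec, tmp_path):
        table = generate_cohorts(small_spec)
        path = tmp_path / "t.csv"
        write_table(table, path)
        schema_path = path.with_suffix(".schema.yaml")
        schema_path.write_text(schema_path.read_text().replace("smoker", "smoker_renamed"))
        with pytest.raises(ValueError, match="smoker"):
            read_table(path)
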