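"""Estimator dispatch and mixed-type network construction."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohortnet.association import (
    NetworkBuilder,
    build_network,
    network_from_weights,
    phi_coefficient,
    point_biserial,
    read_graphml,
    select_method,
    spearman,
    write_edge_csv,
    write_graphml,
)
from cohortnet.synthetic import CohortTable, VariableSchema, generate_cohorts


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("binary", "binary", "phi"),
        ("ordinal", "binary", "pointbiserial"),
        ("binary", "ordinal", "pointbiserial"),
        ("binary", "continuous", "pointbiserial"),
        ("continuous", "ordinal", "spearman"),
        ("ordinal", "ordinal", "spearman"),
        ("continuous", "continuous", "spearman"),
    ],
)
def test_select_method_dispatch(a, b, expected):
    assert select_method(a, b) == expected
    assert select_method(b, a) == expected


def test_select_method_unknown_vtype():
    with pytest.raises(ValueError, match="unknown vtype"):
        select_method("binary", "nominal")


class TestEstimators:
    def test_phi_identity_and_independence(self):
        x = np.array([0, 0, 1, 1, 0, 1])
        assert phi_coefficient(x, x) == pytest.approx(1.0)
        # 2x2 table [[2,2],[2,2]]
        a = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        assert phi_coefficient(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_phi_from_2x2_table(self):
        # table [[3,1],[1,3]]: phi = (3*3-1*1)/sqrt(4^4) = 0.5
        x = np.array([0] * 4 + [1] * 4)
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        assert phi_coefficient(x, y) == pytest.approx(0.5)
        assert phi_coefficient(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_point_biserial_against_pearson(self):
        g = np.array([0, 0, 1, 1])
        y = np.array([1.0, 3.0, 5.0, 7.0])
        assert point_biserial(g, y) == pytest.approx(np.corrcoef(g, y)[0, 1])
        assert point_biserial(g, y) == pytest.approx(0.894427, abs=1e-6)

    def test_point_biserial_no_separation(self):
        g = np.array([0, 0, 1, 1])
        y = np.array([2.0, 4.0, 4.0, 2.0])
        assert point_biserial(g, y) == pytest.approx(0.0, abs=1e-12)
        assert point_biserial(g, g.astype(float)) == pytest.approx(1.0)

    def test_spearman_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, x**3) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_spearman_ties_midrank_oracle(self):
        from scipy import stats

        x = np.array([1, 2, 2, 3, 3, 3, 4], dtype=float)
        y = np.array([2, 1, 3, 3, 5, 4, 4], dtype=float)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert spearman(x, y) == pytest.approx(oracle)
        assert spearman(x, y) == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_constant_input_signals_undefined(self):
        const = np.ones(5)
        varying = np.array([0, 1, 0, 1, 0], dtype=float)
        assert np.isnan(phi_coefficient(const, varying))
        assert np.isnan(point_biserial(varying, const))
        assert np.isnan(spearman(const, const))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_phi_and_pointbiserial_equal_pearson(self, data):
        """Coded-data Pearson is the oracle for both binary estimators."""
        n = data.draw(st.integers(5, 30))
        g = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)), dtype=float)
        y = np.array(
            data.draw(
                st.lists(st.floats(-50, 50, allow_nan=False), min_size=n, max_size=n)
            )
        )
        if g.std() == 0 or y.std() == 0:
            assert np.isnan(point_biserial(g, y))
            return
        oracle = np.corrcoef(g, y)[0, 1]
        assert point_biserial(g, y) == pytest.approx(oracle, abs=1e-10)
        yb = (y > np.median(y)).astype(float)
        if yb.std() > 0:
            assert phi_coefficient(g, yb) == pytest.approx(np.corrcoef(g, yb)[0, 1], abs=1e-10)


def _mixed_table(values, cohorts=None):
    schema = (
        VariableSchema("b", "binary", (0.0,)),
        VariableSchema("o", "ordinal", (-0.5, 0.5)),
        VariableSchema("c", "continuous"),
    )
    n = len(values)
    if cohorts is None:
        cohorts = ["pain"] * (n // 2) + ["nopain"] * (n - n // 2)
    return CohortTable(
        data=pd.DataFrame(values, columns=["b", "o", "c"]),
        cohort=pd.Series(cohorts),
        schema=schema,
    )


class TestBuildNetwork:
    def test_dispatch_one_of_each_vtype(self):
        values = np.array(
            [
                [0, 0, 0.1],
                [1, 1, -0.4],
                [0, 2, 1.2],
                [1, 0, 0.5],
                [0, 1, -1.0],
                [1, 2, 0.3],
            ],
            dtype=float,
        )
        net = build_network(_mixed_table(values))
        assert net.methods[0, 1] == "pointbiserial"
        assert net.methods[0, 2] == "pointbiserial"
        assert net.methods[1, 2] == "spearman"
        assert net.n_effective[0, 1] == 6

    def test_duplicate_continuous_column_edge_is_one(self, rng):
        x = rng.standard_normal(40)
        schema = (VariableSchema("c1", "continuous"), VariableSchema("c2", "continuous"))
        table = CohortTable(
            data=pd.DataFrame({"c1": x, "c2": x.copy()}),
            cohort=pd.Series(["pain"] * 20 + ["nopain"] * 20),
            schema=schema,
        )
        assert build_network(table).weights[0, 1] == pytest.approx(1.0)

    def test_participant_order_invariance(self, small_table, rng):
        net = build_network(small_table)
        perm = rng.permutation(small_table.n_participants)
        net_shuffled = build_network(small_table.subset(perm))
        np.testing.assert_allclose(net.weights, net_shuffled.weights, atol=1e-12)

    def test_subset_filter_equals_extracted_table(self, small_table):
        via_filter = build_network(small_table, "pain")
        extracted = small_table.subset(small_table.cohort_index("pain"))
        via_table = build_network(extracted)
        np.testing.assert_allclose(via_filter.weights, via_table.weights, atol=1e-12)
        np.testing.assert_array_equal(via_filter.n_effective, via_table.n_effective)

    def test_constant_column_zeroed_and_flagged(self):
        values = np.array(
            [[1, 0, 0.1], [1, 1, -0.4], [1, 2, 1.2], [1, 0, 0.5]], dtype=float
        )
        with pytest.warns(UserWarning, match="b"):
            net = build_network(_mixed_table(values))
        assert net.weights[0, 1] == 0.0
        assert net.weights[0, 2] == 0.0
        assert net.undefined[0, 1] and net.undefined[0, 2]
        assert not net.undefined[1, 2]

    def test_pairwise_path_matches_dense_when_complete(self, small_table):
        builder = NetworkBuilder(small_table)
        dense = builder._build_dense(small_table.values)
        pairwise = builder._build_pairwise(small_table.values)
        np.testing.assert_allclose(dense.weights, pairwise.weights, atol=1e-10)
        np.testing.assert_array_equal(dense.n_effective, pairwise.n_effective)

    def test_missing_data_pairwise_complete(self):
        values = np.array(
            [
                [0, 0, 0.1],
                [1, np.nan, -0.4],
                [0, 2, 1.2],
                [1, 0, np.nan],
                [0, 1, -1.0],
                [1, 2, 0.3],
                [1, 1, 0.9],
                [0, 2, -0.2],
            ]
        )
        net = build_network(_mixed_table(values))
        assert net.n_effective[0, 1] == 7
        assert net.n_effective[0, 2] == 7
        assert net.n_effective[1, 2] == 6
        m = np.isfinite(values[:, 0]) & np.isfinite(values[:, 1])
        oracle = np.corrcoef(values[m, 0], values[m, 1])[0, 1]
        assert net.weights[0, 1] == pytest.approx(oracle)

    def test_independent_data_gives_small_weights(self):
        spec_vars = (
            VariableSchema("b", "binary", (0.0,)),
            VariableSchema("c", "continuous"),
        )
        from cohortnet.synthetic import SyntheticSpec

        spec = SyntheticSpec(
            schema=spec_vars, latent_corr=np.eye(2), n_pain=2500, n_nopain=2500, seed=11
        )
        net = build_network(generate_cohorts(spec))
        assert abs(net.weights[0, 1]) < 3.9 / np.sqrt(5000)

    def test_too_few_participants(self, small_table):
        with pytest.raises(ValueError, match="2 participants"):
            build_network(small_table, np.array([0]))


class TestNetworkIO:
    def test_graphml_round_trip(self, small_table, tmp_path):
        net = build_network(small_table)
        path = tmp_path / "net.graphml"
        write_graphml(net, path)
        g = read_graphml(path)
        assert set(g.nodes) == set(net.node_names)
        i, j = 0, 1
        edge = g.edges[net.node_names[i], net.node_names[j]]
        assert edge["weight"] == pytest.approx(net.weights[i, j])
        assert edge["method"] == net.methods[i, j]
        assert edge["n_effective"] == net.n_effective[i, j]

    def test_edge_csv_shape(self, small_table, tmp_path):
        net = build_network(small_table)
        path = tmp_path / "edges.csv"
        write_edge_csv(net, path)
        df = pd.read_csv(path)
        assert len(df) == 15
        assert list(df.columns) == ["node_a", "node_b", "weight", "method", "n_effective"]

    def test_network_from_weights_validates(self):
        with pytest.raises(ValueError, match="symmetric"):
            network_from_weights(np.array([[0.0, 0.5], [0.4, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            network_from_weights(np.array([[0.1, 0.5], [0.5, 0.0]]))
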