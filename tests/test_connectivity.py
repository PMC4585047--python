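"""Correlation networks, connectivity sums, edges, and the permutation null."""

import numpy as np
import pandas as pd
import pytest

from conftest import pearson_oracle
from fosnet.connectivity import (
    CorrelationMatrix,
    connectivity_profile,
    correlation_matrix,
    edge_list,
    permutation_null,
    to_graph,
)
from fosnet.errors import DegenerateDataError, InsufficientDataError


def _one_group(data: dict) -> pd.DataFrame:
    n = len(next(iter(data.values())))
    return pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(n)],
            "treatment": ["MA"] * n,
            "phase": ["light"] * n,
            **data,
        }
    )


def _matrix(values, regions=("A", "B", "C")) -> CorrelationMatrix:
    df = pd.DataFrame(np.asarray(values, float), index=list(regions), columns=list(regions))
    return CorrelationMatrix(values=df, method="pearson", n_pairs=df * 0 + 10)


THREE_REGION = _matrix(
    [[1.0, 0.5, -0.3], [0.5, 1.0, 0.2], [-0.3, 0.2, 1.0]]
)


class TestCorrelationMatrix:
    def test_identical_columns_correlate_at_one(self):
        x = [3.0, 7.0, 1.0, 9.0, 5.0]
        corr = correlation_matrix(_one_group({"A": x, "B": list(x)}))
        assert corr.values.loc["A", "B"] == pytest.approx(1.0)

    def test_negated_column_correlates_at_minus_one(self):
        x = np.array([3.0, 7.0, 1.0, 9.0, 5.0])
        neg = 2 * x.mean() - x  # reflection about the mean
        corr = correlation_matrix(_one_group({"A": x, "B": neg}))
        assert corr.values.loc["A", "B"] == pytest.approx(-1.0)

    def test_matches_hand_coded_product_moment_formula(self, toy_table_5x3):
        corr = correlation_matrix(toy_table_5x3)
        for a in "ABC":
            for b in "ABC":
                want = pearson_oracle(list(toy_table_5x3[a]), list(toy_table_5x3[b]))
                assert corr.values.loc[a, b] == pytest.approx(want, abs=1e-12)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_spearman_is_rank_pearson(self, toy_table_5x3):
        corr = correlation_matrix(toy_table_5x3, method="spearman")
        ranks = toy_table_5x3[["A", "B", "C"]].rank()
        want = pearson_oracle(list(ranks["A"]), list(ranks["B"]))
        assert corr.values.loc["A", "B"] == pytest.approx(want, abs=1e-12)

    def test_too_few_complete_pairs_names_the_pair(self):
        table = _one_group(
            {"A": [1.0, 2.0, 3.0, 4.0, 5.0], "B": [1.0, np.nan, np.nan, np.nan, 2.0]}
        )
        with pytest.raises(InsufficientDataError, match="'A'.*'B'"):
            correlation_matrix(table)

    def test_constant_region_names_the_region(self):
        table = _one_group({"A": [1.0, 2.0, 3.0, 4.0], "B": [5.0, 5.0, 5.0, 5.0]})
        with pytest.raises(DegenerateDataError, match="B"):
            correlation_matrix(table)


class TestConnectivityProfile:
    def test_three_region_arithmetic(self):
        prof = connectivity_profile(THREE_REGION)
        assert prof.connectivity["A"] == pytest.approx(0.8)
        assert prof.connectivity["B"] == pytest.approx(0.7)
        assert prof.connectivity["C"] == pytest.approx(0.5)

    def test_bounds_identity_and_saturated(self):
        r = 6
        eye = _matrix(np.eye(r), regions=[f"r{i}" for i in range(r)])
        assert (connectivity_profile(eye).connectivity == 0.0).all()
        ones = _matrix(np.ones((r, r)), regions=[f"r{i}" for i in range(r)])
        assert (connectivity_profile(ones).connectivity == r - 1).all()

    def test_bounds_hold_for_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(-1, 1, size=(5, 5))
            c = np.clip((a + a.T) / 2, -1, 1)
            np.fill_diagonal(c, 1.0)
            k = connectivity_profile(_matrix(c, regions=list("abcde"))).connectivity
            assert ((k >= 0) & (k <= 4)).all()


class TestEdgeList:
    def test_zero_threshold_gives_complete_graph(self):
        edges = edge_list(THREE_REGION, 0.0)
        assert len(edges) == 3  # R(R-1)/2

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            edge_list(THREE_REGION, 1.01)

    def test_threshold_filters_by_magnitude_keeping_sign(self):
        edges = edge_list(THREE_REGION, 0.25)
        assert len(edges) == 2
        assert sorted(edges["r"]) == [pytest.approx(-0.3), pytest.approx(0.5)]

    def test_graph_export_carries_signs(self):
        g = to_graph(THREE_REGION, 0.25)
        assert g.number_of_edges() == 2
        signs = {g.edges[e]["sign"] for e in g.edges}
        assert signs == {"positive", "negative"}


class TestPermutationNull:
    @staticmethod
    def _noise_table(n=12, r=4, seed=0):
        rng = np.random.default_rng(seed)
        return _one_group({f"r{i}": rng.normal(50, 10, n) for i in range(r)})

    def test_identical_seed_identical_result(self):
        table = self._noise_table()
        a = permutation_null(table, n_perm=200, seed=5)
        b = permutation_null(table, n_perm=200, seed=5)
        c = permutation_null(table, n_perm=200, seed=6)
        pd.testing.assert_series_equal(a.z, b.z)
        assert not a.z.equals(c.z)

    def test_duplicated_columns_saturate_connectivity_and_z(self):
        rng = np.random.default_rng(1)
        x = rng.normal(50, 10, 12)
        table = _one_group({f"r{i}": x.copy() for i in range(5)})
        res = permutation_null(table, n_perm=2000, seed=2)
        assert np.allclose(res.observed, 4.0)  # R - 1, the upper bound
        assert (res.z > 2).all()
        # observed exceeds every value the shuffled null produced
        assert (res.observed.to_numpy() > res.null_mean + 6 * res.null_sd).all()

    def test_z_exactly_invariant_to_column_shifts(self):
        table = self._noise_table(seed=3)
        shifted = table.copy()
        shifted["r0"] = shifted["r0"] + 1000.0
        a = permutation_null(table, n_perm=300, seed=7)
        b = permutation_null(shifted, n_perm=300, seed=7)
        pd.testing.assert_series_equal(a.z, b.z)

    def test_z_equivariant_under_region_relabeling(self):
        # shuffling streams attach to column positions, so equivariance is
        # distributional; with many replicates the Z's agree closely
        table = self._noise_table(n=15, r=4, seed=4)
        perm = ["r2", "r0", "r3", "r1"]
        relabeled = table[["animal_id", "treatment", "phase", *perm]]
        a = permutation_null(table, n_perm=8000, seed=8)
        b = permutation_null(relabeled, n_perm=8000, seed=9)
        assert np.abs(a.z[perm].to_numpy() - b.z[perm].to_numpy()).max() < 0.2

    def test_independent_noise_z_centered_near_zero(self):
        zs = []
        for seed in range(10):
            table = self._noise_table(n=20, r=8, seed=100 + seed)
            zs.append(permutation_null(table, n_perm=400, seed=seed).z.to_numpy())
        assert np.abs(np.concatenate(zs)).mean() < 1.0

    def test_constant_column_rejected_by_name(self):
        table = _one_group({"A": [1.0, 2.0, 3.0, 4.0], "B": [7.0] * 4})
        with pytest.raises(DegenerateDataError, match="B"):
            permutation_null(table, n_perm=100, seed=0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(self._noise_table(), n_perm=50, seed=0)


class TestPropertyBounds:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0.0, 200.0, allow_nan=False), min_size=4, max_size=4),
            min_size=5,
            max_size=12,
        )
    )
    def test_connectivity_within_bounds_for_arbitrary_tables(rows):
        """0 <= k_r <= R-1 holds for every non-degenerate table."""
        import hypothesis

        x = np.asarray(rows)
        hypothesis.assume(all(len(set(col)) > 1 for col in x.T))
        table = _one_group({f"r{i}": x[:, i] for i in range(4)})
        corr = correlation_matrix(table)
        k = connectivity_profile(corr).connectivity
        assert ((k >= 0) & (k <= 3 + 1e-12)).all()
        assert np.allclose(corr.values, corr.values.T)
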