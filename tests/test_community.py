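import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from rknet import (
    AbundanceTable, bray_curtis, pcoa, permanova_sequential, regime_permanova,
    spearman_dissimilarity, to_relative, trajectory_table,
)


def table_from(X, kind="absolute"):
    n, m = X.shape
    return AbundanceTable(X, [f"s{i}" for i in range(n)],
                          [f"o{j}" for j in range(m)], kind)


class TestBrayCurtis:
    def test_hand_computed_values(self):
        t = table_from(np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0],
                                 [1.0, 1.0]]))
        d = bray_curtis(t)
        assert d["s0", "s1"] == pytest.approx(1.0)      # disjoint
        assert d["s2", "s3"] == pytest.approx(1 / 3)    # 2/6
        assert d["s0", "s0"] == 0.0

    def test_range_and_symmetry(self, small_experiment):
        d = bray_curtis(to_relative(small_experiment[0])).data
        assert ((d >= 0) & (d <= 1 + 1e-12)).all()
        np.testing.assert_allclose(d, d.T)

    def test_all_zero_sample_rejected(self):
        t = table_from(np.array([[1.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="all zero"):
            bray_curtis(t)


class TestPcoa:
    def test_equilateral_simplex_has_two_equal_axes(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(d, ids=list("abc"))
        assert res.eigenvalues.size == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        D = squareform(pdist(X))
        res = pcoa(D, ids=[str(i) for i in range(10)])
        coords = res.coordinates.to_numpy()
        np.testing.assert_allclose(squareform(pdist(coords)), D, atol=1e-8)

    def test_collinear_points_on_first_axis(self):
        pts = np.array([0.0, 1.0, 3.0, 6.0])[:, None]
        D = squareform(pdist(pts))
        res = pcoa(D, ids=list("abcd"))
        axis1 = res.coordinates["PC1"].to_numpy()
        gaps = np.abs(np.diff(axis1))
        np.testing.assert_allclose(gaps, [1.0, 2.0, 3.0], atol=1e-8)

    def test_two_samples_single_axis(self):
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        res = pcoa(D, ids=["a", "b"])
        assert res.coordinates.shape[1] == 1
        sep = abs(res.coordinates.iloc[0, 0] - res.coordinates.iloc[1, 0])
        assert sep == pytest.approx(0.7)

    def test_non_euclidean_warns_and_drops_axes(self):
        # Bray-Curtis on sparse data is typically non-Euclidean
        rng = np.random.default_rng(1)
        X = rng.random((12, 4)) * (rng.random((12, 4)) > 0.5)
        X += 0.01
        with pytest.warns(UserWarning, match="non-Euclidean"):
            res = pcoa(bray_curtis(table_from(X)))
        assert (res.eigenvalues > 0).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [0.5, 0.0]]), ids=["a", "b"])

    def test_matches_skbio_on_euclidean_input(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 3))
        D = squareform(pdist(X))
        mine = pcoa(D, ids=[str(i) for i in range(8)])
        ref = skbio_pcoa(DistanceMatrix(D), method="eigh",
                         number_of_dimensions=0)
        ref_eig = ref.eigvals.to_numpy()
        np.testing.assert_allclose(mine.eigenvalues,
                                   np.sort(ref_eig[ref_eig > 1e-10])[::-1],
                                   atol=1e-8)
        n_axes = mine.eigenvalues.size
        np.testing.assert_allclose(np.abs(mine.coordinates.to_numpy()),
                                   np.abs(ref.samples.to_numpy()[:, :n_axes]),
                                   atol=1e-8)


class TestSpearmanDissimilarity:
    def test_diagonal_and_reversal(self):
        t = table_from(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        d = spearman_dissimilarity(t)
        assert d.loc["s0", "s0"] == 0.0
        assert d.loc["s0", "s1"] == pytest.approx(2.0)  # rank-reversed

    def test_invariant_under_common_monotone_transform(self, small_experiment):
        rel = to_relative(small_experiment[0])
        warped = AbundanceTable(np.sqrt(rel.values), rel.sample_ids,
                                rel.otu_ids, "absolute")
        np.testing.assert_allclose(spearman_dissimilarity(rel).to_numpy(),
                                   spearman_dissimilarity(warped).to_numpy(),
                                   atol=1e-12)

    def test_constant_profile_flagged(self):
        t = table_from(np.array([[1.0, 1.0], [1.0, 2.0]]))
        with pytest.warns(UserWarning, match="constant"):
            d = spearman_dissimilarity(t)
        assert np.isnan(d.loc["s0", "s1"])


class TestPermanova:
    def example(self, seed=0, n=24, effect=1.0):
        rng = np.random.default_rng(seed)
        g = np.repeat(["a", "b"], n // 2)
        X = rng.normal(size=(n, 5)) + effect * (g == "b")[:, None]
        D = squareform(pdist(X))
        return D, pd.DataFrame({"g": g}, index=[str(i) for i in range(n)])

    def test_single_factor_matches_skbio(self):
        D, factors = self.example(effect=0.8)
        mine = permanova_sequential(D, factors, permutations=99, seed=1)
        ref = skbio_permanova(DistanceMatrix(D, ids=list(factors.index)),
                              factors["g"].to_numpy(), permutations=99)
        assert mine["g"]["F"] == pytest.approx(ref["test statistic"], rel=1e-10)
        assert mine["g"]["df"] == 1

    def test_r2_partition_sums_to_one(self, small_experiment):
        counts, meta, _, _ = small_experiment
        res = regime_permanova(to_relative(counts), meta, permutations=99,
                               seed=2)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0)
        assert res.table.loc["Total", "R2"] == pytest.approx(1.0)

    def test_current_regime_dominates_selection_group(self, small_experiment):
        counts, meta, _, _ = small_experiment
        res = regime_permanova(to_relative(counts), meta, days=(28, 50),
                               permutations=199, seed=3)
        assert res["current_regime"]["R2"] > res["selection_group"]["R2"]
        assert res["current_regime"]["p"] <= 0.05

    def test_reproducible_under_seed(self):
        D, factors = self.example(effect=0.5)
        a = permanova_sequential(D, factors, permutations=199, seed=7)
        b = permanova_sequential(D, factors, permutations=199, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_single_level_factor_rejected(self):
        D, factors = self.example()
        factors["g"] = "same"
        with pytest.raises(ValueError, match="two levels"):
            permanova_sequential(D, factors, permutations=49)

    def test_null_p_not_extreme(self):
        D, factors = self.example(seed=5, effect=0.0)
        res = permanova_sequential(D, factors, permutations=199, seed=8)
        assert res["g"]["p"] > 0.05


class TestTrajectoryTable:
    def test_facets_and_ordering(self, small_experiment):
        counts, meta, _, _ = small_experiment
        res = pcoa(bray_curtis(to_relative(counts)))
        traj = trajectory_table(res, meta)
        assert {"PC1", "PC2", "current_regime", "resource_supply"} <= \
            set(traj.columns)
        for _, grp in traj.groupby("microcosm_id"):
            assert grp["day"].is_monotonic_increasing
        switch = traj[traj["selection_group"] == "RK"]
        assert set(switch.loc[switch["day"] <= 28, "current_regime"]) == {"r"}
        assert set(switch.loc[switch["day"] > 28, "current_regime"]) == {"K"}
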