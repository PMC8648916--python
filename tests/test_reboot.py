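import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from rknet import (
    AbundanceTable, SimilaritySpec, adjust_q, noisy_similarity, reboot,
    similarity, zscore_test,
)
from rknet.reboot import NOISE_LEVELS, results_to_frame


def brute_force_by(pvalues):
    """Independent step-up Benjamini-Yekutieli oracle."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    c = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, c * m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def table_from(X, kind="absolute"):
    n, m = X.shape
    return AbundanceTable(X, [f"s{i}" for i in range(n)],
                          [f"o{j}" for j in range(m)], kind)


class TestSimilarity:
    def test_pearson_perfect_linearity(self):
        assert similarity([1, 2, 3], [2, 4, 6], "pearson") == pytest.approx(1.0)

    def test_spearman_hand_computed(self):
        # 1 - 6 * sum(d^2) / (n(n^2-1)) with d = (ranks differ by 6 total)
        assert similarity([1, 2, 3], [3, 1, 2], "spearman") == pytest.approx(-0.5)

    def test_spearman_ties_use_average_ranks(self):
        assert similarity([1, 1, 2, 3], [1, 1, 2, 3], "spearman") == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        assert np.isnan(similarity([1, 1, 1], [1, 2, 3], "pearson"))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=20,
                    unique=True))
    def test_spearman_invariant_under_monotone_transform(self, xs):
        x = np.array(xs, dtype=float)
        y = np.exp(x / 1000)  # strictly increasing transform
        assert similarity(x, y, "spearman") == pytest.approx(1.0)


class TestNoisySimilarity:
    def test_zero_magnitude_is_bitwise_identical(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(10), rng.random(10)
        spec = SimilaritySpec("spearman", 0.0)
        assert noisy_similarity(x, y, spec, rng) == similarity(x, y, "spearman")

    def test_gamma_is_magnitude_times_xmin(self):
        spec = SimilaritySpec("pearson", 10.0, x_min=2e-5)
        assert spec.gamma == pytest.approx(2e-4)
        assert SimilaritySpec("pearson", 0.0).gamma == 0.0

    def test_named_noise_levels(self):
        assert NOISE_LEVELS == {"none": 0.0, "low": 1.0, "medium": 10.0,
                                "high": 100.0}
        t = table_from(np.array([[0.0, 2e-5], [1e-3, 0.0], [2e-3, 1e-4]]),
                       "relative")
        spec = SimilaritySpec.for_table(t, "pearson", "low")
        assert spec.gamma == pytest.approx(2e-5)

    def test_double_zero_pairs_decorrelate(self):
        # two all-zero vectors correlate perfectly without noise; injected
        # noise must restore a null-centred similarity
        rng = np.random.default_rng(1)
        x = np.zeros(20)
        spec = SimilaritySpec("spearman", 1.0, x_min=1e-4)
        draws = [noisy_similarity(x, x, spec, rng) for _ in range(1000)]
        assert abs(np.mean(draws)) < 0.1


class TestAdjustQ:
    def test_hand_computed_triple(self):
        # c(3) = 11/6; all three step-up minima coincide at 0.055
        np.testing.assert_allclose(adjust_q([0.01, 0.02, 0.03]),
                                   [0.055, 0.055, 0.055])

    def test_single_p_uses_c1(self):
        np.testing.assert_allclose(adjust_q([0.2]), [0.2])
        np.testing.assert_allclose(adjust_q([0.9]), [0.9])

    def test_empty_list(self):
        assert adjust_q([]).size == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(adjust_q(p), brute_force_by(p),
                                       atol=1e-12)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.random(30)
            q = adjust_q(p)
            assert (q <= 1.0).all()
            assert (np.diff(q[np.argsort(p, kind="stable")]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_q([0.5, 1.5])


class TestZscoreTest:
    def test_pooled_closed_form(self):
        z, p = zscore_test(0.8, 0.1, 0.0, 0.1, variant="pooled")
        assert z == pytest.approx(0.8 / (0.1 * np.sqrt(2)), rel=1e-6)
        assert z == pytest.approx(5.657, abs=1e-3)
        assert p == pytest.approx(2 * norm.sf(z), rel=1e-9)
        assert p == pytest.approx(1.54e-8, rel=5e-3)

    def test_identical_distributions(self):
        z, p = zscore_test(0.3, 0.1, 0.3, 0.1)
        assert z == 0.0 and p == 1.0

    def test_sign_follows_mean_difference(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            bm, pm = rng.normal(size=2)
            z, _ = zscore_test(bm, 0.2, pm, 0.2)
            assert np.sign(z) == np.sign(bm - pm)

    def test_zero_denominator_flagged(self):
        z, p = zscore_test(0.5, 0.0, 0.0, 0.0)
        assert np.isnan(z) and np.isnan(p)


class TestReboot:
    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        t = table_from(rng.random((20, 5)))
        a = results_to_frame(reboot(t, SimilaritySpec("spearman", 0.0),
                                    iterations=100, seed=9))
        b = results_to_frame(reboot(t, SimilaritySpec("spearman", 0.0),
                                    iterations=100, seed=9))
        assert a.equals(b)

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=50)
        X = np.exp(np.column_stack([base + 0.05 * rng.normal(size=50),
                                    base + 0.05 * rng.normal(size=50),
                                    rng.normal(size=50)]))
        res = reboot(table_from(X), SimilaritySpec("spearman", 0.0),
                     iterations=1000, seed=10)
        pair = {frozenset((r.otu_a, r.otu_b)): r for r in res}
        hit = pair[frozenset(("o0", "o1"))]
        assert hit.similarity > 0.9
        assert hit.z > 0
        assert hit.q < 1e-3

    def test_permutation_null_centred(self):
        rng = np.random.default_rng(7)
        res = reboot(table_from(rng.random((30, 6))),
                     SimilaritySpec("pearson", 0.0), iterations=400, seed=11)
        for r in res:
            assert abs(r.perm_mean) < 4 * r.perm_sd / np.sqrt(400) + 0.01

    def test_bootstrap_mean_tracks_point_similarity(self):
        rng = np.random.default_rng(8)
        gaps = []
        for n in (20, 200):
            base = rng.normal(size=n)
            X = np.column_stack([base + rng.normal(size=n),
                                 base + rng.normal(size=n)])
            res = reboot(table_from(np.exp(X)), SimilaritySpec("pearson", 0.0),
                         iterations=400, seed=12)[0]
            gaps.append(abs(res.boot_mean - res.similarity))
        assert gaps[1] < gaps[0]

    def test_constant_otu_pairs_excluded(self):
        rng = np.random.default_rng(13)
        X = rng.random((15, 3))
        X[:, 2] = 1.0
        res = reboot(table_from(X), SimilaritySpec("pearson", 0.0),
                     iterations=100, seed=1)
        pairs = {frozenset((r.otu_a, r.otu_b)) for r in res}
        assert pairs == {frozenset(("o0", "o1"))}

    def test_renormalize_requires_relative(self):
        rng = np.random.default_rng(14)
        t = table_from(rng.random((10, 3)), "absolute")
        with pytest.raises(ValueError, match="relative"):
            reboot(t, SimilaritySpec("pearson", 0.0), iterations=100,
                   renormalize=True, seed=0)

    def test_renormalized_permutations_run(self):
        rng = np.random.default_rng(15)
        X = rng.random((12, 3))
        X = X / (2 * X.sum(axis=1, keepdims=True))  # rows sum to 0.5
        import pandas as pd
        residual = pd.Series(0.5, index=[f"s{i}" for i in range(12)])
        res = reboot(table_from(X, "relative"), SimilaritySpec("spearman", 0.0),
                     iterations=100, renormalize=True, residual_pool=residual,
                     seed=2)
        assert len(res) == 3
        assert all(np.isfinite(r.q) for r in res)
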