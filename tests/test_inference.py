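import numpy as np
import pytest

from stylemorph.inference import (
    make_grouping,
    pairwise_size_position_tests,
    permanova,
)

from helpers import brute_force_permanova_f


class TestPermanova:
    def test_pseudo_f_matches_brute_force(self, rng):
        X = rng.normal(size=(18, 3))
        labels = ["a"] * 6 + ["b"] * 7 + ["c"] * 5
        res = permanova(X, labels, n_permutations=99, seed=0)
        assert res.pseudo_F == pytest.approx(brute_force_permanova_f(X, labels), rel=1e-10)

    def test_pseudo_f_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        X = rng.normal(size=(20, 3))
        labels = ["a"] * 10 + ["b"] * 10
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        ref = skbio_permanova(DistanceMatrix(D), labels, permutations=99)
        res = permanova(X, labels, n_permutations=99, seed=0)
        assert res.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_exact_enumeration_small_n(self, rng):
        X = rng.normal(size=(4, 2))
        labels = ["A", "A", "B", "B"]
        res = permanova(X, labels, n_permutations=9999, seed=0)
        assert res.exact
        assert res.n_permutations == 6  # 4!/(2!2!) distinct relabelings
        # independent check: enumerate all relabelings by brute force
        from itertools import permutations

        fs = {
            perm: brute_force_permanova_f(X, perm)
            for perm in set(permutations(labels))
        }
        F_obs = brute_force_permanova_f(X, labels)
        p_expected = np.mean([f >= F_obs - 1e-12 for f in fs.values()])
        assert res.p_value == pytest.approx(p_expected)

    def test_p_value_never_zero(self, rng):
        # two clearly separated groups: p bounded below by 1/(1+n_perm)
        X = np.vstack([rng.normal(size=(10, 2)), rng.normal(size=(10, 2)) + 50.0])
        labels = ["a"] * 10 + ["b"] * 10
        res = permanova(X, labels, n_permutations=199, seed=1)
        assert res.p_value >= 1.0 / 200.0
        assert res.p_value <= 0.01

    def test_f_invariant_to_rotation(self, rng):
        X = rng.normal(size=(16, 3))
        labels = ["a"] * 8 + ["b"] * 8
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = permanova(X, labels, n_permutations=49, seed=0)
        b = permanova(X @ Q, labels, n_permutations=49, seed=0)
        assert a.pseudo_F == pytest.approx(b.pseudo_F, rel=1e-9)
        np.testing.assert_allclose(a.permutation_Fs, b.permutation_Fs, rtol=1e-9)

    def test_power_increases_with_separation(self, rng):
        base = rng.normal(size=(30, 2))
        labels = ["a"] * 15 + ["b"] * 15
        Fs = []
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            X = base.copy()
            X[15:, 0] += delta
            Fs.append(permanova(X, labels, n_permutations=9, seed=0).pseudo_F)
        assert np.all(np.diff(Fs) > 0)

    def test_reproducible_from_seed(self, rng):
        X = rng.normal(size=(30, 2))
        labels = ["a"] * 15 + ["b"] * 15
        a = permanova(X, labels, n_permutations=199, seed=5)
        b = permanova(X, labels, n_permutations=199, seed=5)
        np.testing.assert_array_equal(a.permutation_Fs, b.permutation_Fs)

    def test_tiny_group_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(X, ["a", "a", "a", "a", "b"], 99)


class TestPairwiseTests:
    def test_null_calibration_on_identical_groups(self):
        ps = []
        for rep in range(40):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(60, 3))
            labels = ["a"] * 30 + ["b"] * 30
            res = pairwise_size_position_tests(X, labels, "sum_of_variances",
                                               n_resamples=199, seed=rep)
            ps.append(res[0].p_raw)
        assert 0.3 < np.median(ps) < 0.7

    def test_single_comparison_no_correction(self, rng):
        X = rng.normal(size=(40, 2))
        labels = ["a"] * 20 + ["b"] * 20
        (res,) = pairwise_size_position_tests(X, labels, "sum_of_variances",
                                              n_resamples=99, seed=0)
        assert res.p_bonferroni == res.p_raw

    def test_bonferroni_monotone_over_slices(self, rng):
        X = rng.normal(size=(40, 2))
        labels = ["a"] * 15 + ["b"] * 15 + ["c"] * 10
        results = pairwise_size_position_tests(X, labels, "average_displacement",
                                               n_resamples=99, seed=0)
        assert len(results) == 3
        for r in results:
            assert r.p_bonferroni >= r.p_raw
            assert r.p_bonferroni <= 1.0
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 3))

    def test_small_group_reported_untestable(self, rng):
        X = rng.normal(size=(25, 2))
        labels = ["big"] * 20 + ["mid"] * 3 + ["tiny"] * 2
        results = pairwise_size_position_tests(X, labels, "sum_of_variances",
                                               n_resamples=99, seed=0)
        by_pair = {r.pair: r for r in results}
        assert not by_pair[("big", "tiny")].testable
        assert "below minimum size" in by_pair[("big", "tiny")].note
        assert not by_pair[("mid", "tiny")].testable
        assert by_pair[("big", "mid")].testable
        # correction counts only the single testable pair
        assert by_pair[("big", "mid")].p_bonferroni == by_pair[("big", "mid")].p_raw

    def test_clear_size_difference_detected(self, rng):
        X = np.vstack([rng.normal(size=(100, 2)) * 3.0, rng.normal(size=(50, 2))])
        labels = ["wide"] * 100 + ["narrow"] * 50
        (res,) = pairwise_size_position_tests(X, labels, "sum_of_variances",
                                              n_resamples=999, seed=0)
        assert res.p_raw < 0.01

    def test_reproducible_from_seed(self, rng):
        X = rng.normal(size=(30, 2))
        labels = ["a"] * 15 + ["b"] * 15
        a = pairwise_size_position_tests(X, labels, "sum_of_variances", 199, seed=3)
        b = pairwise_size_position_tests(X, labels, "sum_of_variances", 199, seed=3)
        np.testing.assert_array_equal(a[0].null_values, b[0].null_values)


class TestGrouping:
    def test_coarse_pools_fossil_slices(self):
        labels = ["extant", "Cretaceous", "Miocene", "Eocene", "extant"]
        assert make_grouping(labels, "coarse") == [
            "extant", "fossil", "fossil", "fossil", "extant"
        ]

    def test_slices_identity(self):
        labels = ["extant", "Cretaceous"]
        assert make_grouping(labels, "slices") == labels

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown grouping"):
            make_grouping(["a"], "fine")
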