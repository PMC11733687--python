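"""Permutation inference: cluster tests, RM F-test, paired t, effect sizes."""

import itertools

import numpy as np
import pytest
from scipy import stats

from speechrsa.permstats import (
    bonferroni_alpha,
    cluster_test_1d,
    cluster_test_2d,
    cohens_d_paired,
    perm_paired_t,
    perm_rm_anova,
)


def exhaustive_cluster_oracle_1d(data, mu0, cluster_alpha):
    """Brute-force enumeration of all sign flips with scipy t-tests and a
    hand-rolled run finder; returns (observed max size, null max sizes)."""
    n, T = data.shape
    tcrit = stats.t.ppf(1 - cluster_alpha, n - 1)

    def max_run(mask):
        best = cur = 0
        for m in mask:
            cur = cur + 1 if m else 0
            best = max(best, cur)
        return best

    null = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        flipped = np.asarray(signs)[:, None] * (data - mu0)
        t = stats.ttest_1samp(flipped, 0.0, axis=0).statistic
        t = np.nan_to_num(t)
        null.append(max_run(t > tcrit))
    t_obs = np.nan_to_num(stats.ttest_1samp(data - mu0, 0.0, axis=0).statistic)
    return max_run(t_obs > tcrit), np.array(null)


def flood_fill_components(mask):
    """BFS flood fill with 4-connectivity; independent of scipy.ndimage."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack, cells = [(i, j)], []
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    cells.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        x, y = a + da, b + db
                        if (
                            0 <= x < mask.shape[0]
                            and 0 <= y < mask.shape[1]
                            and mask[x, y]
                            and not seen[x, y]
                        ):
                            seen[x, y] = True
                            stack.append((x, y))
                comps.append(sorted(cells))
    return comps


class TestCluster1D:
    def test_data_at_mu0_gives_no_clusters(self):
        data = np.full((8, 50), 0.5)
        res = cluster_test_1d(data, mu0=0.5)
        assert res.clusters == []

    def test_strong_uniform_effect_matches_exhaustive_oracle(self, rng):
        # ten subjects, +10 SD constant effect: the implementation must
        # reproduce the exhaustive-enumeration null exactly
        data = 0.5 + 10.0 + 0.01 * rng.standard_normal((10, 12))
        res = cluster_test_1d(data, mu0=0.5, cluster_alpha=0.05)
        assert res.exhaustive and res.n_permutations == 1024
        obs, null = exhaustive_cluster_oracle_1d(data, 0.5, 0.05)
        assert len(res.clusters) == 1
        assert res.clusters[0].size == obs == 12
        np.testing.assert_array_equal(
            np.sort(res.null_max_sizes), np.sort(null)
        )
        assert res.clusters[0].p_value == pytest.approx(
            np.mean(null >= obs)
        )

    def test_only_identity_flip_survives_a_strict_threshold(self, rng):
        # with a cluster-forming threshold above t = 4 (the t-value any
        # single sign flip of a huge constant effect produces in n = 10),
        # only the unflipped assignment reaches the maximum: p = 1/1024
        data = 0.5 + 10.0 + 0.01 * rng.standard_normal((10, 12))
        res = cluster_test_1d(data, mu0=0.5, cluster_alpha=0.001)
        assert res.clusters[0].size == 12
        assert res.clusters[0].p_value == pytest.approx(1.0 / 1024.0)

    def test_sampled_mode_close_to_exhaustive(self, rng):
        data = 0.4 * rng.standard_normal((10, 30)) + 0.15
        exh = cluster_test_1d(data, mu0=0.0)
        smp = cluster_test_1d(data, mu0=0.0, n_perm=4000, seed=5,
                              exhaustive=False)
        assert exh.exhaustive and not smp.exhaustive
        for ce, cs in zip(exh.clusters, smp.clusters):
            assert cs.p_value == pytest.approx(ce.p_value, abs=0.02)

    def test_subject_order_invariance(self, rng):
        data = rng.standard_normal((9, 40)) + 0.3
        r1 = cluster_test_1d(data, mu0=0.0)
        r2 = cluster_test_1d(data[rng.permutation(9)], mu0=0.0)
        assert [c.size for c in r1.clusters] == [c.size for c in r2.clusters]
        assert [c.p_value for c in r1.clusters] == [
            c.p_value for c in r2.clusters
        ]

    def test_zero_variance_columns_not_supra_threshold(self):
        data = np.ones((6, 20)) * 0.5
        data[:, 5:10] = 0.9  # zero variance, positive offset
        res = cluster_test_1d(data, mu0=0.5)
        assert res.clusters == []


class TestCluster2D:
    def test_null_data_gives_no_clusters(self):
        data = np.zeros((6, 8, 8))
        res = cluster_test_2d(data, mu0=0.0)
        assert res.clusters == []

    def test_block_effect_is_one_cluster_of_25(self, rng):
        # zero background (t = 0 by the zero-variance guard) so the
        # supra-threshold set is exactly the stimulated block
        data = np.zeros((8, 12, 12))
        data[:, 3:8, 4:9] += 5.0 + 0.01 * rng.standard_normal((8, 5, 5))
        res = cluster_test_2d(data, mu0=0.0)
        sig = [c for c in res.clusters if c.significant]
        assert len(sig) == 1
        assert sig[0].size == 25

    def test_corner_touching_blocks_are_two_clusters(self, rng):
        # two blocks meeting only at a corner: 4-connectivity keeps them
        # separate; verified against an independent flood-fill oracle
        data = np.zeros((8, 10, 10))
        data[:, 2:5, 2:5] += 5.0 + 0.01 * rng.standard_normal((8, 3, 3))
        data[:, 5:8, 5:8] += 5.0 + 0.01 * rng.standard_normal((8, 3, 3))
        res = cluster_test_2d(data, mu0=0.0)
        t_obs = stats.ttest_1samp(data, 0.0, axis=0).statistic
        comps = flood_fill_components(t_obs > res.t_threshold)
        assert len(comps) == 2
        assert sorted(c.size for c in res.clusters) == sorted(
            len(c) for c in comps
        )
        assert sorted(sorted(c.indices) for c in res.clusters) == sorted(comps)

    def test_random_masks_match_flood_fill(self, rng):
        # connectivity bookkeeping on arbitrary patterns
        for _ in range(10):
            data = rng.standard_normal((6, 9, 9)) + 0.8
            res = cluster_test_2d(data, mu0=0.0, n_perm=50, seed=0,
                                  exhaustive=False)
            t_obs = stats.ttest_1samp(data, 0.0, axis=0).statistic
            comps = flood_fill_components(t_obs > res.t_threshold)
            assert sorted(len(c) for c in comps) == sorted(
                c.size for c in res.clusters
            )


class TestPermRMANOVA:
    def test_constant_sessions_give_f_zero_p_one(self):
        data = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        with pytest.warns(UserWarning, match="zero residual variance"):
            res = perm_rm_anova(data, n_perm=200, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_sessions_f_equals_squared_paired_t(self, rng):
        data = rng.standard_normal((6, 2))
        res = perm_rm_anova(data, n_perm=10, seed=0)
        t = stats.ttest_rel(data[:, 0], data[:, 1]).statistic
        assert res.statistic == pytest.approx(t**2, rel=1e-10)

    def test_hand_computed_table(self):
        # 3 subjects x 2 sessions, differences (1, 1, 4): t = 2 -> F = 4
        data = np.array([[3.0, 2.0], [5.0, 4.0], [10.0, 6.0]])
        res = perm_rm_anova(data, n_perm=10, seed=0)
        assert res.statistic == pytest.approx(4.0, rel=1e-12)

    def test_strong_session_shift_detected(self, rng):
        detected = 0
        for rep in range(20):
            data = rng.standard_normal((10, 3))
            data[:, 2] += 5.0
            res = perm_rm_anova(data, n_perm=300, seed=rep)
            detected += res.p_value < 0.05
        assert detected >= 19

    def test_incomplete_data_errors(self):
        data = np.ones((3, 3))
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            perm_rm_anova(data)


class TestPermPairedT:
    def test_equal_vectors(self):
        x = np.arange(5.0)
        res = perm_paired_t(x, x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_all_positive_differences_exhaustive_p(self, rng):
        x = rng.uniform(1.0, 2.0, 10)
        y = x - rng.uniform(0.5, 1.0, 10)  # strictly positive differences
        res = perm_paired_t(x, y)
        assert res.exhaustive and res.n_permutations == 1024
        assert res.p_value == pytest.approx(2.0 / 1024.0)

    def test_sampled_p_within_mc_error_of_exhaustive(self, rng):
        x = rng.standard_normal(10) + 0.6
        y = rng.standard_normal(10)
        exh = perm_paired_t(x, y)
        smp = perm_paired_t(np.concatenate([x, [0.1, -0.2, 0.3]]),
                            np.concatenate([y, [0.0, 0.0, 0.0]]),
                            n_perm=10000, seed=3)
        assert not smp.exhaustive
        # n = 13 > 12 -> sampled; compare against full enumeration by brute force
        d = np.concatenate([x - y, [0.1, -0.2, 0.3]])
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        count = 0
        for signs in itertools.product([1.0, -1.0], repeat=13):
            dd = np.asarray(signs) * d
            t = dd.mean() / (dd.std(ddof=1) / np.sqrt(len(dd)))
            count += abs(t) >= abs(t_obs) - 1e-12
        p_true = count / 2**13
        assert smp.p_value == pytest.approx(p_true, abs=0.01)

    def test_p_is_valid(self, rng):
        x = rng.standard_normal(8) + 50.0
        y = rng.standard_normal(8)
        res = perm_paired_t(x, y)
        assert res.p_value >= 1.0 / res.n_permutations


class TestEffectSizes:
    def test_equal_vectors_give_zero(self):
        x = np.arange(4.0)
        assert cohens_d_paired(x, x) == 0.0

    def test_arithmetic_example(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d_paired(x + x[::-1] * 0, np.zeros(3)) == pytest.approx(
            2.0
        )

    def test_antisymmetry(self, rng):
        x, y = rng.standard_normal(6), rng.standard_normal(6)
        assert cohens_d_paired(x, y) == pytest.approx(-cohens_d_paired(y, x))

    def test_constant_nonzero_difference_is_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(cohens_d_paired(np.ones(3) * 2, np.ones(3)))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 6, 0.05 / 6), (0.05, 3, 0.05 / 3), (0.01, 1, 0.01)],
    )
    def test_adjustment(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_printed_rounding(self):
        assert round(bonferroni_alpha(0.05, 6), 4) == 0.0083
        assert round(bonferroni_alpha(0.05, 3), 4) == 0.0167

    def test_invalid_m_errors(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
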