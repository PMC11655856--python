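"""Time-series feature battery vs. brute-force oracles and invariance laws."""

import numpy as np
import pytest

from ndcvae.features import (
    FEATURE_NAMES,
    basic_stats,
    build_feature_matrix,
    cluster_features,
    dynamic_variability,
    kernel_entropy,
    pp_meanstat,
    std_nth_der,
    trev3_denom,
    var_ratio_stat,
    visibility_degrees,
    visibility_expnlogL,
    walker_distdiff,
)

RNG = np.random.default_rng(20240901)


class TestBasicStats:
    def test_hand_examples(self):
        assert basic_stats([1, 1, 1]) == (1.0, 0.0)
        m, s = basic_stats([0, 2])
        assert m == 1.0 and np.isclose(s, np.sqrt(2))

    def test_zscored_series(self):
        x = RNG.normal(size=200)
        z = (x - x.mean()) / x.std(ddof=1)
        m, s = basic_stats(z)
        assert abs(m) < 1e-12 and np.isclose(s, 1.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            basic_stats([1.0])


class TestKernelEntropy:
    def test_gaussian_limit(self):
        x = np.random.default_rng(1).normal(size=10_000)
        h = kernel_entropy(x)
        assert abs(h - 0.5 * np.log(2 * np.pi * np.e)) < 0.05

    def test_scaling_adds_log_c(self):
        x = np.random.default_rng(2).normal(size=2000)
        c = 3.7
        assert abs(kernel_entropy(c * x) - kernel_entropy(x) - np.log(c)) < 0.02

    def test_gaussian_maximizes_entropy_at_equal_variance(self):
        # the Gaussian is the max-entropy distribution at fixed variance, so
        # an equal-variance bimodal mixture must come out lower
        rng = np.random.default_rng(3)
        uni = rng.normal(size=4000)
        bim = np.concatenate([rng.normal(-2, 0.5, 2000), rng.normal(2, 0.5, 2000)])
        bim = bim / bim.std()  # equal variance
        assert kernel_entropy(bim) < kernel_entropy(uni)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            kernel_entropy(np.ones(50))


class TestTrev3Denom:
    def test_hand_arithmetic(self):
        assert trev3_denom([0, 1, 2, 3, 4, 5]) == 27.0  # d=(3,3,3), 9^{3/2}
        assert trev3_denom(np.ones(10)) == 0.0

    def test_degree_three_homogeneity(self):
        x = RNG.normal(size=50)
        c = -2.5
        assert np.isclose(trev3_denom(c * x), abs(c) ** 3 * trev3_denom(x))

    def test_full_ratio_variant(self):
        x = RNG.normal(size=100)
        d = x[3:] - x[:-3]
        expected = np.mean(d**3) / np.mean(d**2) ** 1.5
        assert np.isclose(trev3_denom(x, full_ratio=True), expected)


class TestStdNthDer:
    def test_cubic_annihilated(self):
        t = np.arange(20.0)
        assert std_nth_der(2 * t**3 - t**2 + 5, n=4) == 0.0

    def test_hand_differencing(self):
        assert np.isclose(std_nth_der([1, 2, 4, 8, 16, 32], n=4), np.sqrt(0.5))

    def test_level_invariance(self):
        x = RNG.normal(size=40)
        assert np.isclose(std_nth_der(x + 123.4), std_nth_der(x))


class TestPhillipsPerron:
    @staticmethod
    def df_t_ratio(x):
        """Plain Dickey–Fuller t-ratio oracle (no long-run correction)."""
        y, ylag = x[1:], x[:-1]
        n = y.size
        d = np.column_stack([np.ones(n), ylag])
        coef, *_ = np.linalg.lstsq(d, y, rcond=None)
        resid = y - d @ coef
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(d.T @ d)[1, 1])
        return (coef[1] - 1) / se

    def test_lag_zero_equals_dickey_fuller(self):
        from ndcvae.features import _pp_ztau

        x = np.cumsum(np.random.default_rng(4).normal(size=300))
        assert np.isclose(_pp_ztau(x, 0), self.df_t_ratio(x), atol=1e-10)

    def test_mean_reverting_series_strongly_negative(self):
        rng = np.random.default_rng(5)
        x = np.empty(500)
        x[0] = 0
        for t in range(1, 500):
            x[t] = 0.2 * x[t - 1] + rng.normal()
        assert pp_meanstat(x) < -5

    def test_random_walk_small_magnitude(self):
        x = np.cumsum(np.random.default_rng(6).normal(size=500))
        assert pp_meanstat(x) > -3.0  # does not reject a unit root


class TestWalker:
    def test_constant_series_zero(self):
        assert walker_distdiff(np.full(30, 2.0)) == 0.0

    def test_alpha_one_equals_lagged_ks_oracle(self):
        x = RNG.normal(size=80)
        w = np.concatenate([[x[0]], x[:-1]])  # α=1: walker is one-step lag
        from scipy.stats import ks_2samp

        expected = ks_2samp(w, x, method="asymp").statistic
        assert np.isclose(walker_distdiff(x, alpha=1.0), expected)

    def test_statistic_in_unit_interval(self):
        for _ in range(5):
            v = walker_distdiff(RNG.normal(size=60))
            assert 0 <= v <= 1


def brute_visibility_degrees(x):
    """O(n³) reference: check every chord against every interior point."""
    n = x.size
    adj = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            visible = True
            for c in range(a + 1, b):
                chord = x[b] + (x[a] - x[b]) * (b - c) / (b - a)
                if x[c] >= chord:
                    visible = False
                    break
            if visible:
                adj[a, b] = adj[b, a] = True
    return adj.sum(axis=1)


class TestVisibility:
    def test_three_point_exhaustive(self):
        for x2 in (-1.0, 0.0, 0.49, 0.51, 2.0):
            x = np.array([0.0, x2, 1.0])
            deg = visibility_degrees(x)
            # neighbors always see each other; ends see each other iff the
            # middle point is below the chord (here: x2 < 0.5)
            expect_13 = x2 < 0.5
            assert deg[1] == 2
            assert deg[0] == (2 if expect_13 else 1)
            assert deg[2] == (2 if expect_13 else 1)

    def test_convex_increasing_is_complete(self):
        x = np.exp(np.linspace(0, 2, 12))  # strictly convex
        deg = visibility_degrees(x)
        assert np.all(deg == 11)

    @pytest.mark.parametrize("n", [6, 20, 57])
    def test_degrees_match_cubic_oracle(self, n):
        for seed in range(3):
            x = np.random.default_rng(seed + n).normal(size=n)
            assert np.array_equal(visibility_degrees(x), brute_visibility_degrees(x))

    def test_expnlogl_matches_direct_formula(self):
        x = RNG.normal(size=50)
        z = (x - x.mean()) / x.std()
        k = brute_visibility_degrees(z)
        ks = k - k.min()
        lam = 1.0 / ks.mean()
        expected = -np.mean(np.log(lam) - lam * ks)
        assert np.isclose(visibility_expnlogL(x), expected)


class TestVarianceRatio:
    def test_antipersistent_series_negative(self):
        # increments are first differences of white noise (lag-1
        # autocorrelation −1/2), so VR(q) < 1 and z is strongly negative
        noise = np.random.default_rng(7).normal(size=1001)
        x = np.concatenate([[0.0], np.cumsum(np.diff(noise))])
        assert var_ratio_stat(x, q=4) < -3

    def test_trending_series_positive(self):
        rng = np.random.default_rng(8)
        # positively autocorrelated increments inflate VR
        inc = np.convolve(rng.normal(size=600), np.ones(5) / 5, mode="valid")
        assert var_ratio_stat(np.cumsum(inc), q=4) > 3

    def test_zero_variance_guard(self):
        with pytest.raises(ValueError):
            var_ratio_stat(np.arange(100.0), q=4)  # equal increments

    def test_matches_direct_formula(self):
        x = np.cumsum(RNG.normal(size=200))
        q = 4
        n = x.size - 1
        mu = (x[-1] - x[0]) / n
        d1 = np.diff(x) - mu
        var1 = d1 @ d1 / (n - 1)
        dq = x[q:] - x[:-q] - q * mu
        varq = dq @ dq / (q * (n - q + 1) * (1 - q / n))
        z = (varq / var1 - 1) / np.sqrt(2 * (2 * q - 1) * (q - 1) / (3 * q * n))
        assert np.isclose(var_ratio_stat(x, q=4), z)


class TestDynamicVariability:
    def test_reference_window_count(self):
        # 225 samples, window 20, step 4 → 52 left-aligned windows
        assert (225 - 20) // 4 + 1 == 52
        states = np.random.default_rng(9).normal(size=(3, 225))
        v = dynamic_variability(states, window=20, step=4)
        assert v.shape == (3,) and np.all(np.isfinite(v))

    def test_periodic_states_give_zero_variability(self):
        # period equal to the step: every window sees identical content
        base = np.array([0.0, 1.0, 0.0, -1.0])
        states = np.vstack(
            [np.tile(np.roll(base, k), 20) for k in range(3)]
        )
        v = dynamic_variability(states, window=20, step=4)
        assert np.allclose(v[np.isfinite(v)], 0.0, atol=1e-12)

    def test_matches_manual_recomputation(self):
        states = np.random.default_rng(10).normal(size=(5, 60))
        window, step = 20, 4
        n_win = (60 - window) // step + 1
        f = np.empty((n_win, 5, 4))
        for i in range(n_win):
            corr = np.corrcoef(states[:, i * step : i * step + window])
            for k in range(5):
                f[i, k] = np.delete(corr[k], k)
        expected = np.empty(5)
        for k in range(5):
            cc = np.corrcoef(f[:, k])
            iu = np.triu_indices(n_win, 1)
            expected[k] = 1 - cc[iu].mean()
        assert np.allclose(dynamic_variability(states, window, step), expected)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            dynamic_variability(np.ones((2, 60)))


class TestClusterFeatures:
    def test_identity_matrix_all_singletons(self):
        clusters, reps = cluster_features(np.eye(5))
        assert sorted(reps) == [0, 1, 2, 3, 4]
        assert all(len(c) == 1 for c in clusters)

    def test_block_plus_singleton(self):
        c = np.eye(4)
        block = [0, 1, 2]
        for i in block:
            for j in block:
                if i != j:
                    c[i, j] = 0.9
        c[0, 1] = c[1, 0] = 0.95  # feature 0 and 1 better connected
        clusters, reps = cluster_features(c)
        assert len(clusters) == 2
        big = next(cl for cl in clusters if len(cl) == 3)
        sums = {i: sum(abs(c[i, j]) for j in big if j != i) for i in big}
        assert reps[clusters.index(big)] == max(sums, key=lambda i: (sums[i], -i))

    def test_representative_count_bounded(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(-1, 1, size=(8, 8))
        c = (a + a.T) / 2
        np.fill_diagonal(c, 1.0)
        clusters, reps = cluster_features(c)
        assert len(reps) <= 8

    def test_asymmetric_rejected(self):
        c = np.eye(3)
        c[0, 1] = 0.7
        with pytest.raises(ValueError):
            cluster_features(c)


class TestFeatureMatrix:
    def test_column_count_and_names(self):
        rng = np.random.default_rng(12)
        n_sub, n_reg, n_t, n_st = 2, 5, 64, 2
        states = rng.normal(size=(n_sub, n_reg, n_t, n_st)).cumsum(axis=2) * 0.2 + \
            rng.normal(size=(n_sub, n_reg, n_t, n_st))
        fm = build_feature_matrix(
            states, rng.normal(size=(n_sub, n_reg, 2)), rng.normal(size=(n_sub, 2)),
            window=20, step=4,
        )
        assert fm.shape == (2, 10 * n_reg * n_st + 2 * n_reg + 2)  # 112
        assert fm.columns.is_unique
        assert fm.columns[0].startswith("mean_state0_region0")
        assert fm.columns[-1] == "theta_s1"

    def test_reference_width_arithmetic(self):
        # 100 regions, 2 states, 10 features, 2 region + 2 subject params
        assert 10 * 100 * 2 + 2 * 100 + 2 == 2202
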