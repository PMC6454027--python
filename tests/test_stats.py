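"""Sign-permutation inference, cluster correction, bootstrap latencies,
trimming and counting — checked against exhaustive and analytic oracles."""

import itertools

import numpy as np
import pytest

import wavemeg as wm
from wavemeg import stats


def exhaustive_sign_p(values: np.ndarray) -> float:
    """Two-sided sign-flip p by enumerating all 2^n sign vectors."""
    n = len(values)
    obs = abs(values.mean())
    count = 0
    for signs in itertools.product((-1, 1), repeat=n):
        if abs(np.dot(signs, values) / n) >= obs - 1e-12:
            count += 1
    return count / 2**n


class TestSignPermutation:
    def test_all_zero_data_has_p_one(self):
        p = wm.sign_permutation_test(np.zeros((6, 20)), n_perm=200,
                                     rng=np.random.default_rng(0))
        np.testing.assert_array_equal(p, 1.0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            wm.sign_permutation_test(np.ones((1, 10)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monte_carlo_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal(10) + 0.6
        n_perm = 2000
        p_mc = wm.sign_permutation_test(vals[:, None], n_perm=n_perm,
                                        rng=np.random.default_rng(seed + 100))[0]
        p_ex = exhaustive_sign_p(vals)
        se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
        assert abs(p_mc - p_ex) <= 3 * se + 1.0 / (n_perm + 1)

    def test_unanimous_positive_signal_minimal_p(self):
        x = np.full((12, 1), 2.5)
        p = wm.sign_permutation_test(x, n_perm=4000, rng=np.random.default_rng(3))[0]
        p_ex = exhaustive_sign_p(x[:, 0])  # = 2 / 2^12
        assert p_ex == pytest.approx(2 / 4096)
        assert p <= 5 * p_ex + 3 / 4001

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((8, 300))
        p = wm.sign_permutation_test(x, n_perm=500, rng=rng)
        grid = np.sort(p)
        ks = np.abs(grid - (np.arange(1, 301) / 300)).max()
        assert ks < 0.1


class TestClusterCorrection:
    def test_no_subthreshold_points_empty_mask(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 50)) * 0.01
        p = np.full(50, 0.5)
        sm = wm.cluster_correct(p, x, n_perm=300, rng=rng)
        assert sm.count() == 0 and sm.clusters == []

    def test_recovers_contiguous_signal_window(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((12, 200)) * 0.3
        x[:, 80:130] += 2.0  # 50-timepoint signal at high SNR
        sm = wm.significance_mask(x, n_perm=500, rng=rng)
        assert len(sm.clusters) >= 1
        inside = sm.mask[80:130].sum()
        assert inside >= 0.8 * 50
        assert sm.mask[:60].sum() == 0

    def test_masked_points_lie_inside_listed_clusters(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 150)) * 0.4
        x[:, 40:70] += 1.5
        sm = wm.significance_mask(x, n_perm=400, rng=rng)
        rebuilt = np.zeros(150, dtype=bool)
        for start, stop, size in sm.clusters:
            assert size == stop - start + 1
            rebuilt[start : stop + 1] = True
        np.testing.assert_array_equal(rebuilt, sm.mask)


class TestBootstrapLatency:
    def test_shared_unique_maximum_degenerates(self):
        t = np.arange(0.0, 200.0, 5.0)
        curve = np.exp(-0.5 * ((t - 85.0) / 20.0) ** 2)
        x = np.tile(curve, (6, 1))
        est = wm.bootstrap_latency(x, t, (0, 200), n_boot=100, kind="peak",
                                   rng=np.random.default_rng(0))
        assert est.point == 85.0 and est.mean == 85.0
        assert est.sem == 0.0 and est.ci95 == (85.0, 85.0)

    def test_peak_recovery_under_noise(self):
        rng = np.random.default_rng(1)
        t = np.arange(-50.0, 300.0, 5.0)
        curve = np.exp(-0.5 * ((t - 120.0) / 30.0) ** 2)
        x = curve + rng.standard_normal((10, t.size)) * 0.25
        est = wm.bootstrap_latency(x, t, (0, 300), n_boot=500, kind="peak",
                                   rng=rng)
        assert abs(est.mean - 120.0) <= 10.0
        assert est.ci95[0] <= est.point <= est.ci95[1]

    def test_two_seeds_agree_within_bootstrap_error(self):
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 300.0, 5.0)
        curve = np.exp(-0.5 * ((t - 140.0) / 25.0) ** 2)
        x = curve + rng.standard_normal((8, t.size)) * 0.3
        e1 = wm.bootstrap_latency(x, t, (0, 300), 400, "peak",
                                  np.random.default_rng(10))
        e2 = wm.bootstrap_latency(x, t, (0, 300), 400, "peak",
                                  np.random.default_rng(20))
        se = max(e1.sem, e2.sem) / np.sqrt(400) * np.sqrt(400)  # bootstrap sd
        assert abs(e1.mean - e2.mean) <= 2 * max(se, 1e-9)

    def test_onset_is_first_significant_timepoint_after_zero(self):
        rng = np.random.default_rng(3)
        t = np.arange(-50.0, 250.0, 5.0)
        x = rng.standard_normal((12, t.size)) * 0.2
        x[:, (t >= 100) & (t <= 200)] += 2.0
        est = wm.bootstrap_latency(x, t, (0, 250), n_boot=50, kind="onset",
                                   rng=rng, n_perm_onset=200)
        assert 85.0 <= est.point <= 115.0
        assert est.missing_fraction <= 0.1

    def test_onset_missing_draws_reported(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((6, 60)) * 0.05  # pure null: no clusters
        t = np.arange(0.0, 300.0, 5.0)
        est = wm.bootstrap_latency(x, t, (0, 300), n_boot=30, kind="onset",
                                   rng=rng, n_perm_onset=150)
        assert est.missing_fraction > 0.5


class TestTrimAndFilter:
    def test_hundred_distinct_values_keep_ninety(self):
        out = wm.trim_outliers(np.arange(1.0, 101.0), pct=5)
        assert out.size == 90
        assert out.min() == 6.0 and out.max() == 95.0

    def test_equal_values_all_retained(self):
        out = wm.trim_outliers(np.full(50, 3.0), pct=5)
        assert out.size == 50

    def test_linear_interpolation_percentile_bounds(self):
        out = wm.trim_outliers(np.arange(1.0, 1001.0), pct=5)
        assert out.min() == 51.0 and out.max() == 950.0

    def test_small_sample_returned_unchanged(self):
        vals = np.arange(10.0)
        out = wm.trim_outliers(vals, pct=5)
        np.testing.assert_array_equal(out, vals)

    def test_latency_cutoff_boundary_inclusive(self):
        np.testing.assert_array_equal(
            wm.latency_histogram_filter(np.array([108.0, 151.0])), [108.0])
        np.testing.assert_array_equal(
            wm.latency_histogram_filter(np.array([150.0])), [150.0])
        assert wm.latency_histogram_filter(np.array([])).size == 0


class TestCounting:
    @staticmethod
    def mask_of(spans, n=60):
        m = np.zeros(n, dtype=bool)
        clusters = []
        for a, b in spans:
            m[a : b + 1] = True
            clusters.append((a, b, b - a + 1))
        return stats.SignificanceMask(mask=m, clusters=clusters, cdt=0.05,
                                      alpha=0.05, n_permutations=100)

    def test_empty_masks_count_zero(self):
        masks = {"W2": self.mask_of([]), "W3": self.mask_of([])}
        meta = {"W2": (1, "H"), "W3": (1, "V")}
        table, sums = wm.count_significant(masks, meta)
        assert table["n_significant"].sum() == 0
        assert sums == {"H": 0, "V": 0, "D": 0}

    def test_run_lengths_summed(self):
        masks = {"W2": self.mask_of([(10, 19), (40, 44)])}
        table, sums = wm.count_significant(masks, {"W2": (1, "H")})
        assert table.loc[0, "n_significant"] == 15
        assert sums["H"] == 15

    def test_orientation_sums_pool_levels(self):
        masks = {
            "W2": self.mask_of([(0, 9)]),   # level 1 H: 10
            "W7": self.mask_of([(0, 4)]),   # level 2 H: 5
            "W4": self.mask_of([(0, 1)]),   # level 1 D: 2
            "W1": self.mask_of([(0, 29)]),  # level 1 A: ignored in sums
        }
        meta = {"W2": (1, "H"), "W7": (2, "H"), "W4": (1, "D"), "W1": (1, "A")}
        table, sums = wm.count_significant(masks, meta)
        assert sums == {"H": 15, "V": 0, "D": 2}
        assert set(table.columns) == {"descriptor", "level", "band", "n_significant"}
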