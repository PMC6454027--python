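"""Pseudo-trial averaging and pairwise SVM decoding: partition contracts,
chance and ceiling behaviour, engine agreement, and determinism."""

import numpy as np
import pytest

import wavemeg as wm
from wavemeg import mvpa


class TestPseudotrials:
    def test_forty_trials_give_four_groups_of_ten(self):
        trials = np.random.default_rng(0).standard_normal((40, 6))
        ps = wm.make_pseudotrials(trials, K=4, group_size=10,
                                  rng=np.random.default_rng(1))
        assert ps.patterns.shape == (4, 6)
        assert ps.K == 4 and ps.group_size == 10
        used = np.concatenate(ps.provenance)
        assert len(used) == 40 and len(set(used)) == 40  # disjoint partition

    def test_identical_trials_average_to_same_pattern(self):
        p = np.arange(5.0)
        trials = np.tile(p, (12, 1))
        ps = wm.make_pseudotrials(trials, K=4, group_size=3,
                                  rng=np.random.default_rng(2))
        np.testing.assert_allclose(ps.patterns, np.tile(p, (4, 1)))

    def test_group_averaging_shrinks_variance(self):
        # pseudo-trial variance of i.i.d. noise ~ sigma^2 / group_size
        rng = np.random.default_rng(3)
        g = 5
        vals = []
        for _ in range(1000):
            trials = rng.standard_normal((4 * g, 1))
            vals.append(wm.make_pseudotrials(trials, K=4, group_size=g,
                                             rng=rng).patterns.ravel())
        var = np.var(np.concatenate(vals))
        assert var == pytest.approx(1.0 / g, rel=0.2)

    def test_shortfall_policy_shrinks_group(self):
        assert mvpa.resolve_group_size(12, 4, 10) == 3
        assert mvpa.resolve_group_size(5, 4, 10) == 1
        assert mvpa.resolve_group_size(3, 4, 10) == 0

    def test_fewer_than_k_trials_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            wm.make_pseudotrials(np.zeros((3, 4)), K=4,
                                 rng=np.random.default_rng(0))


class TestDecodePair:
    def separated(self, gap, rng, n=12, f=8):
        a = rng.standard_normal((n, f))
        b = rng.standard_normal((n, f)) + gap
        return a, b

    def test_disjoint_noiseless_patterns_decode_perfectly(self):
        rng = np.random.default_rng(0)
        a, b = self.separated(50.0, rng)
        acc = wm.decode_pair_timepoint(a, b, K=4, group_size=3, n_reps=10, rng=rng)
        assert acc == 1.0

    def test_same_distribution_is_chance_level(self):
        rng = np.random.default_rng(1)
        a, b = self.separated(0.0, rng, n=20)
        acc = wm.decode_pair_timepoint(a, b, K=4, group_size=5, n_reps=100, rng=rng)
        assert 0.4 <= acc <= 0.6

    def test_identical_classes_tie_break_near_half(self):
        # every trial of both classes is the same pattern: all pseudo-trials
        # coincide, the classifier sees zero margin, ties resolve one way
        rng = np.random.default_rng(2)
        p = rng.standard_normal(8)
        a = np.tile(p, (12, 1))
        acc = wm.decode_pair_timepoint(a, a.copy(), K=4, group_size=3,
                                       n_reps=20, rng=rng)
        assert acc == pytest.approx(0.5, abs=1e-12)

    def test_label_swap_flips_predictions_exactly(self):
        # decision-function sign symmetry: negating the labels negates
        # every prediction (no exact-zero ties in generic float data)
        rng = np.random.default_rng(3)
        train = rng.standard_normal((20, 6, 9))
        test = rng.standard_normal((20, 2, 9))
        y = np.array([-1, -1, -1, 1, 1, 1])
        p = mvpa._batched_svm_predict(train, y, test)
        p_swapped = mvpa._batched_svm_predict(train, -y, test)
        np.testing.assert_array_equal(p_swapped, -p)

    def test_label_swap_changes_accuracy_little(self):
        rng = np.random.default_rng(3)
        a, b = self.separated(0.6, rng, n=16)
        acc_ab = wm.decode_pair_timepoint(a, b, K=4, group_size=4, n_reps=600,
                                          rng=np.random.default_rng(10))
        acc_ba = wm.decode_pair_timepoint(b, a, K=4, group_size=4, n_reps=600,
                                          rng=np.random.default_rng(10))
        assert abs(acc_ab - acc_ba) < 0.02

    def test_batched_engine_matches_sklearn(self):
        # same rng stream -> identical partitions -> accuracies must agree
        rng = np.random.default_rng(4)
        a = rng.standard_normal((12, 6, 10))
        b = rng.standard_normal((12, 6, 10)) + 0.8
        acc_fast = wm.decode_pair_timecourse(a, b, K=4, group_size=3, n_reps=5,
                                             rng=np.random.default_rng(5),
                                             engine="batched")
        acc_ref = wm.decode_pair_timecourse(a, b, K=4, group_size=3, n_reps=5,
                                            rng=np.random.default_rng(5),
                                            engine="sklearn")
        assert np.abs(acc_fast - acc_ref).max() <= 0.05
        assert np.abs(acc_fast - acc_ref).mean() <= 0.01

    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError, match="engine"):
            wm.decode_pair_timepoint(np.zeros((8, 3)), np.zeros((8, 3)),
                                     engine="quantum")

    def test_accuracy_nondecreasing_with_snr(self):
        rng = np.random.default_rng(6)
        pa = rng.standard_normal(12)
        pb = rng.standard_normal(12)
        accs = []
        for noise in (3.0, 1.0, 0.3):
            r = np.random.default_rng(7)
            a = pa + r.normal(0, noise, (24, 12))
            b = pb + r.normal(0, noise, (24, 12))
            accs.append(wm.decode_pair_timepoint(a, b, K=4, group_size=6,
                                                 n_reps=30, rng=r))
        se = 0.5 / np.sqrt(30 * 4)  # one Monte-Carlo s.e. of a fold mean
        assert accs[1] >= accs[0] - se
        assert accs[2] >= accs[1] - se


class TestRDMSeries:
    def test_series_shape_symmetry_and_nan_diagonal(self, decoded_series):
        series, _ = decoded_series
        ns, nt, nc, _ = series.data.shape
        assert (ns, nc) == (4, 8)
        np.testing.assert_array_equal(series.data, series.data.transpose(0, 1, 3, 2))
        assert np.isnan(series.data[:, :, range(nc), range(nc)]).all()
        off = series.data[:, :, 0, 1]
        assert (off >= 0).all() and (off <= 1).all()

    def test_peak_of_grand_average_matches_injected_latency(self, decoded_series):
        series, truth = decoded_series
        iu = np.triu_indices(series.n_conditions, 1)
        acc = series.grand_average()[:, iu[0], iu[1]].mean(axis=1)
        t_peak = series.times[np.argmax(acc)]
        assert abs(t_peak - truth.signal_peak_ms) <= 10.0

    def test_same_seed_reproduces_bit_identical_series(self, signal_epochs):
        epochs, _ = signal_epochs
        small = epochs.with_data(epochs.data[:1, :3, :, :, :5])
        a = wm.decoding_rdm_series(small, K=4, group_size=3, n_reps=2, seed=42)
        b = wm.decoding_rdm_series(small, K=4, group_size=3, n_reps=2, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_pair_cells_match_standalone_decode(self, signal_epochs):
        # per-pair seeding makes each cell reproducible in isolation
        epochs, _ = signal_epochs
        small = epochs.with_data(epochs.data[:1, :3, :, :, :5])
        series = wm.decoding_rdm_series(small, K=4, group_size=3, n_reps=2, seed=9)
        rng = np.random.default_rng(np.random.SeedSequence([9, 0, 0, 2]))
        acc = wm.decode_pair_timecourse(small.data[0, 0], small.data[0, 2],
                                        K=4, group_size=3, n_reps=2, rng=rng)
        np.testing.assert_allclose(series.data[0, :, 0, 2], acc)

    def test_condition_with_too_few_trials_is_nan(self, signal_epochs):
        epochs, _ = signal_epochs
        small = epochs.with_data(epochs.data[:1, :3, :, :, :5])
        small.valid[0, 1, :] = False
        small.valid[0, 1, 0] = True  # 1 < K trials left
        series = wm.decoding_rdm_series(small, K=4, group_size=3, n_reps=2, seed=1)
        assert np.isnan(series.data[0, :, 1, :]).all()
        assert np.isfinite(series.data[0, :, 0, 2]).all()
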