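"""Preprocessing against brute-force oracles and distributional checks."""

import numpy as np
import pytest

from socialca1 import preprocess, synthgen
from socialca1.task import TaskSpec


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------
def naive_condition(F, median_order=3, drift_window=900, percentile=0.05):
    """Two-loop reference: per-trial edge-replicating median filter, trial
    concatenation, truncated centered-window running percentile."""
    n_neurons, n_frames, n_trials = F.shape
    half = median_order // 2
    out = np.empty((n_neurons, n_frames * n_trials))
    for n in range(n_neurons):
        concat = []
        for t in range(n_trials):
            x = F[n, :, t]
            for i in range(n_frames):
                lo, hi = max(0, i - half), min(n_frames, i + half + 1)
                window = list(x[lo:hi])
                window = [x[0]] * (half - (i - lo)) + window + [x[-1]] * (half - (hi - 1 - i))
                concat.append(np.median(window))
        concat = np.asarray(concat)
        total = len(concat)
        w = min(drift_window, total)
        for i in range(total):
            lo, hi = max(0, i - w // 2), min(total, i + (w + 1) // 2)
            out[n, i] = concat[i] - np.percentile(concat[lo:hi], percentile * 100)
    return out


def naive_threshold(pre_values, mode="median+3iqr"):
    q1, q3 = np.percentile(pre_values, 25), np.percentile(pre_values, 75)
    med = np.percentile(pre_values, 50)
    iqr = q3 - q1
    return {"median+3iqr": med + 3 * iqr, "3iqr": 3 * iqr, "q3+3iqr": q3 + 3 * iqr}[mode]


class TestConditioning:
    def test_constant_trace_maps_to_zero(self):
        F = np.full((2, 30, 4), 7.5)
        out = preprocess.condition_trace(F, drift_window=20)
        assert np.allclose(out, 0.0)

    def test_three_frame_plateau_survives_median_filter(self):
        F = np.zeros((1, 30, 1))
        F[0, 10:13, 0] = 5.0  # plateau wide enough for an order-3 median
        F[0, 20, 0] = 5.0  # single-frame spike is removed
        filt = preprocess.condition_trace(F, drift_window=30)
        rel = filt[0] - filt[0, 0]
        assert rel[11] == pytest.approx(5.0)
        assert rel[20] == pytest.approx(0.0)

    @pytest.mark.parametrize("shape,window", [((2, 20, 3), 15), ((1, 37, 2), 74),
                                              ((3, 10, 5), 7)])
    def test_matches_naive_two_loop_oracle(self, shape, window):
        rng = np.random.default_rng(3)
        F = rng.normal(10, 2, size=shape) + np.linspace(0, 5, shape[1])[None, :, None]
        got = preprocess.condition_trace(F, drift_window=window)
        want = naive_condition(F, drift_window=window)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_overlong_window_clipped_with_warning(self):
        F = np.random.default_rng(0).normal(size=(1, 10, 2)) + 10
        with pytest.warns(UserWarning):
            a = preprocess.condition_trace(F, drift_window=100)
        b = preprocess.condition_trace(F, drift_window=20)
        assert np.allclose(a, b)

    def test_even_median_order_rejected(self):
        with pytest.raises(ValueError):
            preprocess.condition_trace(np.ones((1, 10, 1)), median_order=4)


class TestBaseline:
    def test_identical_trace_returns_that_value(self):
        assert preprocess.estimate_baseline(np.full(100, 5.0)) == 5.0

    def test_bimodal_mode_sits_at_major_component(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(1.0, 0.05, 900), rng.normal(10.0, 0.05, 100)])
        assert preprocess.estimate_baseline(x) == pytest.approx(1.0, abs=0.1)

    def test_mode_robust_to_positive_skew(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(2.0, 0.1, 5000), rng.exponential(5.0, 500) + 2])
        f0 = preprocess.estimate_baseline(x)
        assert f0 < x.mean()
        assert f0 == pytest.approx(2.0, abs=0.15)

    def test_nonfinite_trace_rejected(self):
        with pytest.raises(ValueError):
            preprocess.estimate_baseline(np.array([1.0, np.nan]))


class TestDff:
    def test_identity_and_doubling(self):
        assert np.allclose(preprocess.compute_dff(np.array([3.0]), 3.0), 0.0)
        assert np.allclose(preprocess.compute_dff(np.array([6.0]), 3.0), 1.0)

    def test_hand_arithmetic(self):
        trace = np.array([2.0, 4.0, 1.0])
        assert np.allclose(preprocess.compute_dff(trace, 2.0), [0.0, 1.0, -0.5])

    def test_nonpositive_baseline_names_neuron(self):
        with pytest.raises(ValueError, match="neuron 7"):
            preprocess.compute_dff(np.ones(3), 0.0, neuron=7)


class TestEventDetection:
    def test_threshold_of_standard_normal_near_three_iqr(self):
        # pooled pre-open dff ~ N(0,1): median + 3*IQR = 3 * 1.349 ~ 4.05
        rng = np.random.default_rng(4)
        dff = rng.standard_normal((40, 400))
        events, thr, excluded, fallback = preprocess.detect_events(dff, 20)
        assert not fallback
        assert thr == pytest.approx(3 * 1.349, abs=0.3)
        # exclusion pass removes only extreme-noise trials
        assert len(excluded) < 40

    def test_subthreshold_trace_yields_no_events(self):
        dff = np.zeros((30, 10))
        dff[5, 2] = 0.1
        events, thr, *_ = preprocess.detect_events(dff + 0.0, 10)
        assert np.all(events[dff <= thr] == 0)

    def test_single_planted_transient_is_one_contiguous_event(self):
        rng = np.random.default_rng(5)
        dff = 0.05 * rng.standard_normal((60, 30))
        dff[30:35, 7] += 10.0
        events, thr, *_ = preprocess.detect_events(dff, 20)
        flat = events.T.ravel()
        assert preprocess.count_excursions(flat, 0.0) == 1
        assert (events[:, 7] > 0).sum() == 5

    def test_two_pass_exclusion_tightens_threshold(self):
        rng = np.random.default_rng(6)
        dff = 0.1 * rng.standard_normal((30, 20))
        contaminated = dff.copy()
        contaminated[5, 3] = 50.0  # pre-open transient in one trial
        _, thr_c, excluded, _ = preprocess.detect_events(contaminated, 15)
        _, thr_clean, *_ = preprocess.detect_events(dff, 15)
        assert 3 in excluded
        assert thr_c < 1.0  # the contaminant did not inflate the final threshold
        assert thr_c == pytest.approx(thr_clean, rel=0.3)

    def test_all_trials_excluded_falls_back_to_pass_one(self):
        dff = np.zeros((10, 4))
        dff[2, :] = 5.0  # every trial has a pre-open excursion
        _, thr, excluded, fallback = preprocess.detect_events(dff, 5)
        assert fallback and len(excluded) == 4

    @pytest.mark.parametrize("mode", preprocess.THRESHOLD_MODES)
    def test_threshold_modes_match_naive_formula(self, mode):
        rng = np.random.default_rng(7)
        pre = rng.normal(size=500)
        assert preprocess._iqr_threshold(pre, mode) == pytest.approx(
            naive_threshold(pre, mode), rel=1e-12
        )

    def test_empty_pre_open_rejected(self):
        with pytest.raises(ValueError):
            preprocess.detect_events(np.zeros((10, 2)), 0)


class TestFalsePositiveRatio:
    def test_symmetric_noise_ratio_near_one(self):
        rng = np.random.default_rng(8)
        dff = rng.standard_normal(200_000)
        r = preprocess.false_positive_ratio(dff, 2.0)
        assert r == pytest.approx(1.0, abs=0.15)

    def test_strong_transients_give_low_ratio(self, events):
        # synthetic population matched to the observed regime: mostly < 5%
        ok = np.isfinite(events.fp_ratio)
        assert np.median(events.fp_ratio[ok]) < 0.05

    def test_no_positive_events_reports_missing(self):
        assert np.isnan(preprocess.false_positive_ratio(np.zeros(100), 1.0))


class TestPipelineInvariants:
    def test_neuron_permutation_commutes(self, task):
        truth = synthgen.GroundTruth.build(2, 1, 1, 4, seed=3)
        sess = synthgen.generate_session(task, truth, n_trials=60, seed=13)
        ev = preprocess.preprocess_session(sess)
        perm = np.random.default_rng(0).permutation(sess.F.shape[0])
        sess_p = synthgen.SessionRecord(
            sess.trials, sess.F[perm], sess.frame_rate_hz, sess.epoch_frames
        )
        ev_p = preprocess.preprocess_session(sess_p)
        assert np.array_equal(ev_p.dff, ev.dff[perm])
        assert np.array_equal(ev_p.threshold, ev.threshold[perm])

    def test_positive_scaling_leaves_dff_invariant_without_drift(self, task):
        truth = synthgen.GroundTruth.build(1, 0, 0, 2, seed=4)
        noise = synthgen.NoiseSpec(drift_amplitude=0.0)
        sess = synthgen.generate_session(task, truth, n_trials=40, seed=14, noise=noise)
        ev = preprocess.preprocess_session(sess)
        scaled = synthgen.SessionRecord(
            sess.trials, 3.7 * sess.F, sess.frame_rate_hz, sess.epoch_frames
        )
        ev_s = preprocess.preprocess_session(scaled)
        assert np.allclose(ev_s.dff, ev.dff, rtol=1e-9, atol=1e-9)

    def test_event_trace_idempotent_under_rethresholding(self, events):
        n = 0
        ev, thr = events.events[n], events.threshold[n]
        again = np.where(ev > thr, ev, 0.0)
        assert np.array_equal(again, ev)

    def test_zero_noise_events_only_where_planted(self, task):
        truth = synthgen.GroundTruth(
            [synthgen.NeuronTruth("reward", "activated", 2.0, 2.0)]
        )
        noise = synthgen.NoiseSpec(
            drift_amplitude=0.0, white_sd=0.0, background_rate_hz=0.0
        )
        sess = synthgen.generate_session(task, truth, n_trials=80, seed=15, noise=noise)
        ev = preprocess.preprocess_session(sess)
        go = (sess.trials["category"] == "reward").to_numpy()
        assert not (ev.events[0][:, ~go] > 1e-9).any()
        assert ev.events[0][:, go].sum() > 0
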