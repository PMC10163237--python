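"""d-prime, permutation inference, and responsiveness classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialca1 import behavior, selectivity, synthgen
from socialca1.task import NO_REWARD, REWARD, TaskSpec


def naive_dprime(x1, x2):
    m1, m2 = np.mean(x1), np.mean(x2)
    s1 = np.sqrt(np.sum((np.asarray(x1) - m1) ** 2) / (len(x1) - 1))
    s2 = np.sqrt(np.sum((np.asarray(x2) - m2) ** 2) / (len(x2) - 1))
    return (m1 - m2) / np.sqrt(0.5 * (s1**2 + s2**2))


class TestDprime:
    def test_hand_evaluated_example(self):
        assert selectivity.dprime([1, 2, 3], [0, 1, 2]) == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        assert selectivity.dprime([4, 5, 6], [4, 5, 6]) == 0.0

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=12)
        assert selectivity.dprime(a, b) == pytest.approx(-selectivity.dprime(b, a))

    def test_zero_variance_undefined(self):
        assert np.isnan(selectivity.dprime([1, 1, 1], [2, 2, 2]))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            selectivity.dprime([1.0], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 30))
        b = rng.normal(size=rng.integers(2, 30))
        got = selectivity.dprime(a, b)
        want = naive_dprime(a, b)
        if np.isfinite(want):
            assert got == pytest.approx(want, rel=1e-12)


class TestPointwise:
    def test_shuffled_labels_fluctuate_around_zero(self):
        rng = np.random.default_rng(1)
        trace = rng.normal(size=(50, 100))
        labels = rng.random(100) < 0.5
        d = selectivity.pointwise_dprime(trace, labels)
        assert np.nanmean(np.abs(d)) < 0.5
        assert abs(np.nanmean(d)) < 0.1

    def test_constant_frame_is_missing(self):
        trace = np.ones((3, 20))
        trace[1] = np.random.default_rng(2).normal(size=20)
        labels = np.arange(20) < 10
        d = selectivity.pointwise_dprime(trace, labels)
        assert np.isnan(d[0]) and np.isnan(d[2]) and np.isfinite(d[1])

    def test_planted_neuron_dprime_rises_in_stimulus_epoch(
        self, session, events, analysis_mask
    ):
        # neuron 0 is a planted reward neuron in the shared session fixture
        ef = session.epoch_frames
        labels = (session.trials["category"] == REWARD).to_numpy()[analysis_mask]
        d = selectivity.pointwise_dprime(events.events[0][:, analysis_mask], labels)
        pre = np.nanmean(np.abs(d[: ef["open"]]))
        stim = np.nanmean(np.abs(d[ef["open_complete"] : ef["response"]]))
        assert stim > pre + 0.5


class TestPermutationTest:
    def test_null_rate_close_to_five_percent(self):
        rng = np.random.default_rng(10)
        labels = np.arange(120) < 60
        hits = 0
        n = 200
        for _ in range(n):
            amps = rng.normal(size=120)
            *_, lab = selectivity.permutation_test(amps, labels, 500, seed=rng)
            hits += lab != selectivity.NONE_LABEL
        assert 0.01 < hits / n < 0.10

    def test_large_effect_detected_with_correct_sign(self):
        rng = np.random.default_rng(11)
        labels = np.arange(200) < 100
        detected = 0
        for _ in range(20):
            amps = np.where(labels, rng.normal(2, 1, 200), rng.normal(0, 1, 200))
            d, p, lab = selectivity.permutation_test(amps, labels, 1000, seed=rng)
            detected += lab == selectivity.GO_PREFERRING and d > 0
        assert detected == 20

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(12)
        amps = rng.normal(size=60)
        labels = np.arange(60) < 30
        r1 = selectivity.permutation_test(amps, labels, 1000, seed=5)
        r2 = selectivity.permutation_test(amps, labels, 1000, seed=5)
        assert r1 == r2

    def test_degenerate_null_not_significant(self):
        amps = np.zeros(40)
        amps[:3] = 1.0
        labels = np.arange(40) < 20
        d, p, lab = selectivity.permutation_test(amps, labels, 200, seed=0)
        assert lab == selectivity.NONE_LABEL

    def test_bonferroni_tightens_the_tails(self):
        rng = np.random.default_rng(13)
        labels = np.arange(100) < 50
        hits_plain = hits_bonf = 0
        for _ in range(150):
            amps = rng.normal(size=100)
            *_, lab1 = selectivity.permutation_test(amps, labels, 400, 1, seed=rng)
            *_, lab6 = selectivity.permutation_test(amps, labels, 400, 6, seed=rng)
            hits_plain += lab1 != selectivity.NONE_LABEL
            hits_bonf += lab6 != selectivity.NONE_LABEL
        assert hits_bonf <= hits_plain


class TestResponsiveness:
    def _events_for(self, pre_level, stim_level, n_trials=40, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        ef = TaskSpec().epoch_frames()
        ev = np.abs(noise * rng.standard_normal((180, n_trials)))
        ev[: ef["open"]] += pre_level
        ev[ef["open_complete"] : ef["response"]] += stim_level
        return ev, ef

    def test_activated_inhibited_and_none_codes(self):
        ev, ef = self._events_for(0.1, 1.0)
        assert selectivity.classify_response(ev, np.ones(40, bool), ef)[0] == "activated"
        ev, ef = self._events_for(1.0, 0.1)
        assert selectivity.classify_response(ev, np.ones(40, bool), ef)[0] == "inhibited"
        ev = np.zeros((180, 40))
        assert selectivity.classify_response(ev, np.ones(40, bool), ef) == ("none", 1.0)

    def test_identical_areas_give_p_one(self):
        ev = np.zeros((180, 30))
        ef = TaskSpec().epoch_frames()
        # dyadic values make both per-trial areas exactly 1.0
        ev[:32] = 1.0 / 32
        ev[ef["open_complete"] : ef["open_complete"] + 16] = 1.0 / 16
        code, p = selectivity.classify_response(ev, np.ones(30, bool), ef)
        assert code == "none" and p == 1.0

    def test_planted_polarity_recovered_from_generated_population(self, task):
        truth = synthgen.GroundTruth(
            [
                synthgen.NeuronTruth(REWARD, "activated", 2.0, 3.0),
                synthgen.NeuronTruth(REWARD, "inhibited", 2.0, 4.0),
                synthgen.NeuronTruth(),
            ]
        )
        sess = synthgen.generate_session(task, truth, n_trials=300, seed=21)
        from socialca1 import preprocess

        ev = preprocess.preprocess_session(sess)
        mask = behavior.analysis_trial_mask(sess.trials)
        profiles = [
            selectivity.response_profile(ev.events[n], sess.trials, mask, sess.epoch_frames)
            for n in range(3)
        ]
        assert profiles[0].codes["Go"] == "activated"
        assert profiles[1].codes["Go"] == "inhibited"
        assert profiles[2].codes["Go"] == "none"

    def test_response_scores_follow_the_codebook(self):
        def prof(go, nogo):
            return selectivity.ResponseProfile({"Go": go, "NoGo": nogo}, {})

        assert selectivity.response_score(prof("activated", "none")) == 1
        assert selectivity.response_score(prof("activated", "activated")) == 2
        assert selectivity.response_score(prof("inhibited", "inhibited")) == -2
        assert selectivity.response_score(prof("none", "none")) == 0
        assert selectivity.response_score(prof("activated", "inhibited")) == 0


class TestPassivePairwise:
    FOUR = TaskSpec(
        stimuli=("E", "F", "G", "H"),
        category_map={s: NO_REWARD for s in "EFGH"},
    )

    def _passive_session(self, selective: bool, seed=30):
        truth = synthgen.GroundTruth(
            [
                synthgen.NeuronTruth(
                    "identity:E" if selective else "none",
                    "activated" if selective else "none",
                    2.0, 3.0,
                )
            ]
        )
        trials = synthgen.generate_trial_sequence(self.FOUR, 120, seed=seed)
        rec = synthgen.generate_population(
            trials, truth, synthgen.NoiseSpec(), self.FOUR, seed=seed
        )
        from socialca1 import preprocess

        ev = preprocess.preprocess_session(rec)
        return rec, ev

    def test_single_stimulus_neuron_is_significant_with_six_pairs(self):
        rec, ev = self._passive_session(True)
        out = selectivity.passive_pairwise_dprime(
            ev.events, rec.trials, np.ones(len(rec.trials), bool), rec.epoch_frames,
            n_shuffles=300, seed=0,
        )
        pair_cols = [c for c in out.columns if c.startswith("d_")]
        assert len(pair_cols) == 6
        assert bool(out["significant"].iloc[0])
        assert out["mean_abs_dprime"].iloc[0] > 0.3

    def test_nonselective_neuron_mean_dprime_near_zero(self):
        rec, ev = self._passive_session(False, seed=31)
        out = selectivity.passive_pairwise_dprime(
            ev.events, rec.trials, np.ones(len(rec.trials), bool), rec.epoch_frames,
            n_shuffles=300, seed=0,
        )
        assert abs(out["mean_dprime"].iloc[0]) < 0.3
        assert not bool(out["significant"].iloc[0])

    def test_sparse_stimulus_rejected(self):
        rec, ev = self._passive_session(False, seed=32)
        trials = rec.trials.copy()
        trials.loc[trials["stimulus"] == "E", "stimulus"] = "F"
        trials.loc[trials.index[:1], "stimulus"] = "E"
        with pytest.raises(ValueError):
            selectivity.passive_pairwise_dprime(
                ev.events, trials, np.ones(len(trials), bool), rec.epoch_frames, 10
            )
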