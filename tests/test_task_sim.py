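"""Race-model behavioral generator and EEG synthesizer."""

import dataclasses

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from sstdbs import (
    RaceParams,
    TaskConfig,
    TrialType,
    build_trial_sequence,
    default_templates,
    simulate_cohort,
    simulate_session,
    synthesize_eeg,
)
from sstdbs.behavior import summarize_session
from sstdbs.task_sim import (
    InvalidConfigError,
    default_channel_labels,
    simulate_stop_outcomes,
)


class TestTrialSequence:
    def test_go_fraction_at_1000_trials(self):
        """A 1000-trial block carries 52.6% plain go trials."""
        cfg = TaskConfig(n_blocks=1, trials_per_block=1000)
        seq = build_trial_sequence(cfg, seed=0)
        assert seq.count(TrialType.GO) == 526
        assert seq.count(TrialType.STOP) == 158

    def test_degenerate_all_go(self):
        cfg = TaskConfig(
            n_blocks=2,
            trials_per_block=50,
            proportions={TrialType.GO: 1.0, TrialType.STOP: 0.0,
                         TrialType.GO_FAST: 0.0, TrialType.GO_CERTAIN: 0.0},
        )
        assert set(build_trial_sequence(cfg, seed=3)) == {TrialType.GO}

    def test_seeded_determinism(self):
        cfg = TaskConfig()
        assert build_trial_sequence(cfg, seed=11) == build_trial_sequence(cfg, seed=11)

    @pytest.mark.parametrize("seed", range(5))
    def test_no_adjacent_stop_trials(self, seed):
        seq = build_trial_sequence(TaskConfig(), seed=seed)
        for a, b in zip(seq, seq[1:]):
            assert not (a is TrialType.STOP and b is TrialType.STOP)

    def test_block_counts_are_exact(self):
        cfg = TaskConfig(n_blocks=3, trials_per_block=100)
        seq = build_trial_sequence(cfg, seed=1)
        assert len(seq) == 300
        block = seq[:100]
        # largest-remainder allocation of the default mix at 100 trials
        assert block.count(TrialType.GO) == 52
        assert block.count(TrialType.STOP) == 16

    def test_invalid_proportions_raise(self):
        with pytest.raises(InvalidConfigError):
            TaskConfig(proportions={TrialType.GO: 0.9, TrialType.STOP: 0.2,
                                    TrialType.GO_FAST: 0.0, TrialType.GO_CERTAIN: 0.0})
        with pytest.raises(InvalidConfigError):
            TaskConfig(proportions={TrialType.GO: 0.6, TrialType.STOP: 0.4,
                                    TrialType.GO_FAST: 0.0, TrialType.GO_CERTAIN: 0.0})


class TestStaircase:
    def test_success_raises_next_ssd_by_step(self, default_params):
        """A successful inhibition at SSD d puts the next stop trial at d+50."""
        sess = simulate_session(TaskConfig(), default_params, seed=2)
        stops = sess.of_type(TrialType.STOP)
        same_block = [
            (a, b) for a, b in zip(stops, stops[1:]) if a.block == b.block
        ]
        assert same_block
        for a, b in same_block:
            expected = a.ssd + (50.0 if a.stop_success else -50.0)
            expected = min(max(expected, 50.0), 900.0)
            assert b.ssd == pytest.approx(expected)

    def test_trigger_failure_one_means_never_stopping(self):
        params = RaceParams(p_trigger_failure=1.0)
        sess = simulate_session(TaskConfig(), params, seed=4)
        stops = sess.of_type(TrialType.STOP)
        assert stops and all(t.responded and not t.stop_success for t in stops)

    def test_long_run_success_converges_to_half(self, default_params):
        """Over many tracked stop trials the symmetric staircase self-balances
        at 50% inhibition."""
        rates = []
        for seed in range(12):
            sess = simulate_session(TaskConfig(), default_params, seed=seed)
            stops = sess.of_type(TrialType.STOP)
            rates.append(np.mean([t.stop_success for t in stops]))
        assert abs(np.mean(rates) - 0.5) < 0.05

    def test_new_block_restarts_from_recent_staircase_level(self, default_params):
        sess = simulate_session(TaskConfig(n_blocks=2), default_params, seed=9)
        stops = sess.of_type(TrialType.STOP)
        last4 = [t.ssd for t in stops if t.block == 0][-4:]
        first_b1 = next(t for t in stops if t.block == 1)
        assert first_b1.ssd == pytest.approx(np.mean(last4))


class TestRace:
    def test_race_consistency_with_exgaussian_cdf(self):
        """P(respond | SSD) equals the ex-Gaussian go CDF at SSD + SSRT when
        the stop latency is deterministic."""
        params = RaceParams(ssrt_sd=0.0, p_trigger_failure=0.0)
        rng = np.random.default_rng(123)
        K = params.go_tau / params.go_sigma
        for ssd in (250.0, 400.0, 550.0):
            responded = simulate_stop_outcomes(params, ssd, 5000, rng)
            p_emp = responded.mean()
            p_true = scipy.stats.exponnorm.cdf(
                ssd + params.ssrt_true, K, loc=params.go_mu, scale=params.go_sigma
            )
            se = np.sqrt(p_true * (1 - p_true) / 5000)
            assert abs(p_emp - p_true) < 4 * se

    def test_signal_respond_rt_faster_than_go_rt(self, default_params):
        """The race censors slow go finishes on stop trials: USRT < GORT."""
        cfg = TaskConfig(n_blocks=7, trials_per_block=100)
        summ = summarize_session(simulate_session(cfg, default_params, seed=21))
        assert summ.usrt < summ.gort

    def test_session_determinism(self, default_params):
        cfg = TaskConfig()
        a = simulate_session(cfg, default_params, seed=33)
        b = simulate_session(cfg, default_params, seed=33)
        assert a.trials == b.trials


class TestCohort:
    def test_pair_count(self, default_params):
        pairs = simulate_cohort(12, TaskConfig(n_blocks=1), default_params,
                                {"rt_shift": 0.0, "ssrt_shift": 0.0}, seed=0)
        assert len(pairs) == 12
        assert sum(len(p) for p in pairs) == 24
        assert all(on.condition == "ON" and off.condition == "OFF" for on, off in pairs)

    def test_too_small_cohort_rejected(self, default_params):
        with pytest.raises(InvalidConfigError):
            simulate_cohort(1, TaskConfig(), default_params, {}, seed=0)

    def test_condition_effects_recovered_in_group_means(self, default_params):
        """Injected ON effects (go speeding, SSRT lengthening) reappear in
        the behavior-module group means."""
        pairs = simulate_cohort(
            12, TaskConfig(), default_params,
            {"rt_shift": 50.0, "ssrt_shift": 53.0}, seed=7,
        )
        d_gort, d_ssrt = [], []
        for on, off in pairs:
            s_on, s_off = summarize_session(on), summarize_session(off)
            d_gort.append(s_off.gort - s_on.gort)
            d_ssrt.append(s_on.ssrt - s_off.ssrt)
        assert np.mean(d_gort) == pytest.approx(50.0, abs=25.0)
        assert np.mean(d_ssrt) == pytest.approx(53.0, abs=30.0)


class TestEEGSynthesis:
    def test_epoch_geometry(self, low_noise_eeg):
        """(-200, 500) ms at 250 Hz with inclusive endpoints is 176 samples."""
        for key in ("GO", "STOP"):
            ep = low_noise_eeg[key]
            assert ep.data.shape[1] == 96
            assert ep.data.shape[2] == 176
            assert ep.times[0] == -200.0 and ep.times[-1] == 500.0
            assert ep.times[ep.time0] == 0.0

    def test_montage_exposes_f4(self, low_noise_eeg):
        assert "F4" in low_noise_eeg["STOP"].channel_labels
        assert len(default_channel_labels(96)) == 96

    def test_noiseless_epochs_equal_ground_truth_plus_go_overlap(
        self, small_session, templates
    ):
        eeg = synthesize_eeg(small_session, templates, noise_sd=0.0, seed=1)
        go = eeg["GO"]
        np.testing.assert_array_equal(go.data, go.ground_truth)
        stop = eeg["STOP"]
        # the stop epoch is the stored inhibition part plus go-locked overlap;
        # on a trial with the go bump far outside the window they coincide
        assert np.all(np.isfinite(stop.data))
        resid = stop.data - stop.ground_truth
        # residual must be purely go-locked: proportional to the motor topography
        motor = next(c for c in templates.components if c.name == "GO_MOTOR")
        for tr in range(stop.data.shape[0]):
            r = resid[tr]
            tc = r[np.argmax(np.abs(motor.topography))]
            np.testing.assert_allclose(r, np.outer(motor.topography, tc / motor.topography.max()), atol=1e-9)

    def test_synthesis_determinism(self, small_session, templates):
        a = synthesize_eeg(small_session, templates, noise_sd=1.0, seed=5)
        b = synthesize_eeg(small_session, templates, noise_sd=1.0, seed=5)
        np.testing.assert_array_equal(a["STOP"].data, b["STOP"].data)

    def test_us_trials_attenuate_inhibition_components(self, small_session, templates):
        eeg = synthesize_eeg(small_session, templates, noise_sd=0.0, seed=1)
        stop = eeg["STOP"]
        ss = [i for i, t in enumerate(stop.trial_meta) if t.stop_success]
        us = [i for i, t in enumerate(stop.trial_meta) if not t.stop_success]
        if ss and us:
            gt = stop.ground_truth
            amp_ss = np.abs(gt[ss]).max(axis=(1, 2)).mean()
            amp_us = np.abs(gt[us]).max(axis=(1, 2)).mean()
            assert amp_us < amp_ss


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    step=st.floats(10.0, 100.0),
    ssrt=st.floats(120.0, 300.0),
    seed=st.integers(0, 2**20),
)
def test_staircase_tracks_half_for_any_reasonable_params(step, ssrt, seed):
    """One-up/one-down tracking self-balances near 50% for any race with
    non-degenerate go/stop overlap."""
    cfg = TaskConfig(staircase_step=step)
    params = RaceParams(ssrt_true=ssrt)
    sess = simulate_session(cfg, params, seed=seed)
    stops = sess.of_type(TrialType.STOP)
    rate = np.mean([t.stop_success for t in stops[10:]])
    assert abs(rate - 0.5) < 0.25  # single short session, generous band
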