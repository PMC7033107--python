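"""Synthetic trial generator: beep trains, waveform family, trials, cohorts."""

import numpy as np
import pytest

from coordstab.errors import ParameterError
from coordstab.preprocess import SampledSignal
from coordstab.spectral import coordination_pattern_index, power_spectrum
from coordstab.synthetic import (
    LagModel,
    PatternParams,
    make_beep_train,
    simulate_cohort,
    simulate_hand_cycle,
    simulate_tempo_conditions,
    simulate_trial,
)


class TestBeepTrain:
    def test_fixed_tempo_gives_65_constant_intervals(self):
        bt = make_beep_train("fixed", 500)
        assert len(bt) == 65
        assert np.allclose(bt.intervals_ms, 500.0)

    def test_fixed_1000ms_first_two_onsets(self):
        bt = make_beep_train("fixed", 1000)
        assert bt.onsets[0] == 0.0 and bt.onsets[1] == 1.0

    def test_up_ramp_600_to_303_in_3ms_steps(self):
        bt = make_beep_train("up_ramp")
        iv = bt.intervals_ms
        assert len(bt) == 101
        assert iv[0] == pytest.approx(600.0)
        assert iv[-1] == pytest.approx(303.0)
        assert np.allclose(np.diff(iv), -3.0)

    def test_down_ramp_is_exact_reverse_of_up(self):
        up = make_beep_train("up_ramp").intervals_ms
        down = make_beep_train("down_ramp").intervals_ms
        assert np.allclose(down, up[::-1])

    @pytest.mark.parametrize("bad", [None, 50, 5000, -200])
    def test_invalid_fixed_interval_rejected(self, bad):
        with pytest.raises(ParameterError):
            make_beep_train("fixed", bad)

    def test_none_condition_is_empty(self):
        assert len(make_beep_train("none")) == 0


class TestHandCycle:
    def test_rhythmic_waveform_is_sinusoid_with_peak_at_quarter_cycle(self):
        p = PatternParams(cycle_duration=1.0, dwell_fraction=0.0, amplitude=80.0)
        assert simulate_hand_cycle(p, 0.25) == pytest.approx(80.0)
        # pure sinusoid: A*(1 - cos(2 pi t/T)) everywhere
        t = np.linspace(0, 0.999, 200)
        expected = 80.0 * (1 - np.cos(2 * np.pi * t))
        assert np.allclose(simulate_hand_cycle(p, t), expected)

    def test_dwell_half_rests_exactly(self):
        p = PatternParams(cycle_duration=1.0, dwell_fraction=0.5, amplitude=80.0)
        t_dwell = np.linspace(0.5, 0.999, 50)
        assert np.all(simulate_hand_cycle(p, t_dwell) == 0.0)

    @pytest.mark.parametrize("d", [0.2, 0.5, 0.8])
    def test_peak_to_peak_is_2A_for_all_dwell_fractions(self, d):
        p = PatternParams(cycle_duration=1.0, dwell_fraction=d, amplitude=80.0)
        y = simulate_hand_cycle(p, np.linspace(0, 0.9999, 5000))
        assert np.ptp(y) == pytest.approx(160.0, rel=1e-4)

    def test_dwell_reduces_fundamental_power_fraction(self):
        # numeric periodogram comparison of velocity waveforms, d=0.5 vs d=0
        t = np.arange(0, 25, 0.01) % 1.0
        out = {}
        for d in (0.0, 0.5):
            p = PatternParams(cycle_duration=1.0, dwell_fraction=d, noise_sd=0.0)
            v = np.gradient(simulate_hand_cycle(p, t), 0.01)
            spec = power_spectrum(SampledSignal(v, rate=100.0))
            out[d] = coordination_pattern_index(spec, 1.0).cpi
        assert out[0.5] < out[0.0]

    def test_cpi_monotone_decreasing_in_dwell_on_noiseless_grid(self):
        t = np.arange(0, 25, 0.01) % 1.0
        cpis = []
        for d in np.linspace(0.0, 0.8, 9):
            p = PatternParams(cycle_duration=1.0, dwell_fraction=d, noise_sd=0.0)
            v = np.gradient(simulate_hand_cycle(p, t), 0.01)
            spec = power_spectrum(SampledSignal(v, rate=100.0))
            cpis.append(coordination_pattern_index(spec, 1.0).cpi)
        assert np.all(np.diff(cpis) < 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            PatternParams(cycle_duration=0.0)
        with pytest.raises(ParameterError):
            PatternParams(cycle_duration=1.0, dwell_fraction=1.2)
        with pytest.raises(ParameterError):
            PatternParams(cycle_duration=1.0, noise_sd=-1.0)


class TestTrial:
    def test_degenerate_lag_model_catches_on_beeps(self):
        p = PatternParams(cycle_duration=1.0, noise_sd=0.0)
        trial = simulate_trial(p, make_beep_train("fixed", 500), LagModel(0.0, 0.0), seed=0)
        assert np.allclose(np.sort(trial.events.merged_catches), trial.beeps.onsets)

    def test_one_catch_per_beep_alternating_hands(self):
        p = PatternParams(cycle_duration=1.0)
        trial = simulate_trial(p, make_beep_train("fixed", 500), seed=0)
        ev = trial.events
        assert ev.catch_left.size == 33 and ev.catch_right.size == 32
        merged = np.sort(np.concatenate([ev.catch_left, ev.catch_right]))
        # left first, then strict alternation
        assert np.all(np.isin(merged[0::2], ev.catch_left))
        assert np.all(np.isin(merged[1::2], ev.catch_right))

    def test_same_seed_is_bit_identical(self):
        p = PatternParams(cycle_duration=1.0)
        a = simulate_trial(p, make_beep_train("fixed", 500), seed=7)
        b = simulate_trial(p, make_beep_train("fixed", 500), seed=7)
        assert np.array_equal(a.wrist_left.xyz, b.wrist_left.xyz)
        assert np.array_equal(a.head.xyz, b.head.xyz)
        assert np.array_equal(a.events.catch_right, b.events.catch_right)

    def test_fixed_trial_waveform_is_periodic_at_cycle_duration(self):
        p = PatternParams(cycle_duration=1.0, dwell_fraction=0.3, noise_sd=0.0)
        trial = simulate_trial(p, make_beep_train("fixed", 500), LagModel(0.0, 0.0), seed=0)
        y = trial.wrist_left.axis("SI")
        seg = y[200:3000]
        # autocorrelation peak at one cycle (100 frames), tolerance 1 sample
        ac = np.correlate(seg - seg.mean(), seg - seg.mean(), "full")[seg.size - 1 :]
        lag = 50 + int(np.argmax(ac[50:150]))
        assert abs(lag - 100) <= 1

    def test_negative_lag_sigma_rejected(self):
        with pytest.raises(ParameterError):
            LagModel(0.0, -0.1)


class TestCohort:
    def test_coupling_off_shares_lag_distribution(self):
        cohort = simulate_cohort(3, [0.0, 0.3, 0.6], adaptability_coupling=0.0,
                                 seed=1, n_trials=1, conditions=("up_ramp",))
        sigmas = {p.trials["up_ramp"][0].metadata["lag_sigma"] for p in cohort}
        assert len(sigmas) == 1

    def test_low_dwell_participant_has_larger_expected_asynchrony(self):
        from coordstab.adaptation import pair_catches_to_beeps, percent_asynchrony

        means = {0.0: [], 0.6: []}
        for seed in range(12):
            cohort = simulate_cohort(2, [0.0, 0.6], adaptability_coupling=0.04,
                                     seed=seed, n_trials=1, conditions=("up_ramp",))
            for part in cohort:
                t = part.trials["up_ramp"][0]
                res = percent_asynchrony(pair_catches_to_beeps(t.events, t.beeps))
                means[part.dwell_fraction].append(res.percent_asynchrony)
        assert np.mean(means[0.0]) > np.mean(means[0.6])

    def test_preferred_condition_has_no_beeps_and_30s(self):
        cohort = simulate_cohort(2, [0.1, 0.5], seed=0, n_trials=1,
                                 conditions=("preferred",))
        trial = cohort[0].trials["preferred"][0]
        assert len(trial.beeps) == 0
        assert len(trial.head) / trial.sampling_rate >= 30.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            simulate_cohort(3, [0.0, 0.5], seed=0)

    def test_expert_cohort_shape(self):
        cohort = simulate_tempo_conditions(n_participants=2, seed=0)
        assert len(cohort) == 2
        assert len(cohort[0].trials) == 10
        t260 = cohort[0].trials["fixed_260"][0]
        assert t260.beeps.interval_ms == 260.0
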