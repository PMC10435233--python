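"""Beat detection, relative frequency, arrest metrics, AV delay."""

import numpy as np
import pytest

from optophysio import (
    ArrestResult,
    BeatSeries,
    HeartSimParams,
    TimeSeries,
    arrest_time_ratio,
    av_delay,
    cardiac_arrest_rate,
    detect_arrest,
    detect_beats,
    relative_hb_frequency,
    simulate_heart_trial,
)

FPS = 67.0
FRAME = 1.0 / FPS


class TestDetectBeats:
    def test_noiseless_train_recovered_within_one_frame(self, plain_heart_trial):
        atr, _, truth = plain_heart_trial
        beats = detect_beats(atr)
        assert len(beats) == len(truth.beat_times_s)
        assert np.max(np.abs(beats.beat_times_s - truth.beat_times_s)) <= FRAME

    def test_noisy_count_within_one(self, dark_photostate):
        for seed in range(20):
            hp = HeartSimParams(noise_sd=0.1)  # 10% of beat amplitude
            atr, _, truth = simulate_heart_trial(hp, dark_photostate, 30.0, seed)
            beats = detect_beats(atr)
            assert abs(len(beats) - len(truth.beat_times_s)) <= 1

    def test_constant_trace_gives_no_beats(self):
        t = np.arange(0, 10, FRAME)
        beats = detect_beats(TimeSeries(t, np.full_like(t, 2.0)))
        assert len(beats) == 0

    def test_short_trace_rejected(self):
        t = np.arange(0, 1.0, FRAME)
        with pytest.raises(ValueError, match="2 s"):
            detect_beats(TimeSeries(t, np.zeros_like(t)))

    def test_nonpositive_min_ibi_rejected(self, plain_heart_trial):
        with pytest.raises(ValueError, match="min_ibi"):
            detect_beats(plain_heart_trial[0], min_ibi_s=0.0)


def _regular_beats(start, stop, ibi, t_end=None):
    bt = np.arange(start, stop, ibi)
    return BeatSeries(bt, t_start=0.0, t_end=t_end or stop)


class TestRelativeFrequency:
    def test_constant_train_normalizes_to_one(self):
        beats = _regular_beats(0.05, 30.0, 0.4)
        ft = relative_hb_frequency(beats, (0.0, 5.0))
        quant = (1.0 / (2 * ft.window_halfwidth_s)) / ft.baseline_freq_hz
        valid = ~np.isnan(ft.rel_freq)
        assert np.all(np.abs(ft.rel_freq[valid] - 1.0) <= quant + 1e-9)

    def test_arrest_interior_is_exactly_zero(self):
        bt = np.concatenate([np.arange(0.05, 10.0, 0.4),
                             np.arange(20.0, 30.0, 0.4)])
        beats = BeatSeries(bt, t_start=0.0, t_end=30.0)
        ft = relative_hb_frequency(beats, (0.0, 5.0))
        interior = (ft.t > 10.5) & (ft.t < 19.4)
        assert np.all(ft.rel_freq[interior] == 0.0)

    def test_half_rate_step_plateaus_at_half(self):
        bt = np.concatenate([np.arange(0.05, 10.0, 0.4),
                             np.arange(10.05, 30.0, 0.8)])
        beats = BeatSeries(bt, t_start=0.0, t_end=30.0)
        ft = relative_hb_frequency(beats, (0.0, 5.0))
        quant = (1.0 / (2 * ft.window_halfwidth_s)) / ft.baseline_freq_hz
        plateau = (ft.t > 12.0) & (ft.t < 28.0)
        assert np.all(np.abs(ft.rel_freq[plateau] - 0.5) <= quant + 1e-9)

    def test_window_halfwidth_configurable(self):
        beats = _regular_beats(0.05, 30.0, 0.4)
        ft = relative_hb_frequency(beats, (0.0, 5.0), window_halfwidth_s=1.0)
        assert ft.window_halfwidth_s == 1.0

    def test_nan_outside_record(self):
        beats = _regular_beats(0.05, 30.0, 0.4)
        ft = relative_hb_frequency(beats, (0.0, 5.0))
        assert np.isnan(ft.rel_freq[0])
        assert np.isnan(ft.rel_freq[-1])

    def test_empty_baseline_rejected(self):
        beats = _regular_beats(10.0, 30.0, 0.4, t_end=30.0)
        with pytest.raises(ValueError, match="baseline"):
            relative_hb_frequency(beats, (0.0, 5.0))


class TestDetectArrest:
    def test_recovery_noiseless_within_one_frame(self, mosopn3_photostate,
                                                 mosopn3_schedule):
        for seed in range(20):
            hp = HeartSimParams(noise_sd=0.0)
            atr, _, truth = simulate_heart_trial(hp, mosopn3_photostate, 30.0,
                                                 seed, stim_onset_s=5.0)
            res = detect_arrest(detect_beats(atr), mosopn3_schedule)
            assert res.arrested
            assert abs(res.latency_to_arrest_s - truth.latency_to_arrest_s) <= FRAME
            assert abs(res.time_to_resumption_s - truth.time_to_resumption_s) <= FRAME

    def test_recovery_noisy_within_50ms(self, mosopn3_photostate,
                                        mosopn3_schedule):
        for seed in range(20):
            hp = HeartSimParams(noise_sd=0.1)
            atr, _, truth = simulate_heart_trial(hp, mosopn3_photostate, 30.0,
                                                 seed, stim_onset_s=5.0)
            res = detect_arrest(detect_beats(atr), mosopn3_schedule)
            assert res.arrested
            assert abs(res.latency_to_arrest_s - truth.latency_to_arrest_s) <= 0.05
            assert abs(res.time_to_resumption_s - truth.time_to_resumption_s) <= 0.05

    def test_no_rate_change_not_arrested(self, plain_heart_trial,
                                         mosopn3_schedule):
        atr, _, _ = plain_heart_trial
        res = detect_arrest(detect_beats(atr), mosopn3_schedule)
        assert not res.arrested

    def test_no_pre_stimulus_beats_rejected(self, mosopn3_schedule):
        beats = BeatSeries(np.arange(10.0, 20.0, 0.4), t_start=0.0, t_end=20.0)
        with pytest.raises(ValueError, match="pre-stimulus"):
            detect_arrest(beats, mosopn3_schedule)


class TestArrestRatio:
    def test_ratio_sequence(self):
        res = [ArrestResult(True, 0.5, 10.0, 10.0),
               ArrestResult(True, 0.5, 5.0, 5.0),
               ArrestResult(False)]
        assert arrest_time_ratio(res) == [1.0, 0.5, 0.0]

    def test_equal_durations_all_one(self):
        res = [ArrestResult(True, 0.5, 7.0, 7.0)] * 4
        assert arrest_time_ratio(res) == [1.0, 1.0, 1.0, 1.0]

    def test_trial_one_not_arrested_rejected(self):
        with pytest.raises(ValueError, match="trial 1"):
            arrest_time_ratio([ArrestResult(False), ArrestResult(True, 1, 1, 1)])


class TestAvDelay:
    def test_hand_enumerated_exclusion(self):
        atr = BeatSeries(np.array([1.0, 2.0, 3.0]), t_start=0.0, t_end=5.0)
        ven = BeatSeries(np.array([1.1, 2.1, 3.6]), t_start=0.0, t_end=5.0)
        av = av_delay(atr, ven)
        assert np.allclose(av.delays_s, [0.1, 0.1])
        assert av.n_excluded == 1

    def test_planted_delay_recovered_per_pair(self, plain_heart_trial):
        atr, ven, truth = plain_heart_trial
        av = av_delay(detect_beats(atr), detect_beats(ven))
        assert len(av) > 50
        assert np.max(np.abs(av.delays_s - truth.av_delay_s)) <= FRAME
        assert av.n_excluded == 0

    def test_no_matches_gives_empty_result(self):
        atr = BeatSeries(np.array([1.0, 2.0]), t_start=0.0, t_end=5.0)
        ven = BeatSeries(np.array([0.5]), t_start=0.0, t_end=5.0)
        av = av_delay(atr, ven)
        assert len(av) == 0

    def test_retained_delays_never_exceed_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = np.sort(rng.uniform(0, 20, rng.integers(2, 15)))
            a = a[np.diff(np.concatenate([[-1], a])) > 0.05]
            v = np.sort(a + rng.uniform(0.01, 1.0, len(a)))
            if len(a) < 1 or len(v) < 1 or np.any(np.diff(v) <= 0):
                continue
            av = av_delay(BeatSeries(a, t_start=0, t_end=25),
                          BeatSeries(v, t_start=0, t_end=25))
            assert np.all(av.delays_s <= 0.5 + 1e-12)
            # non-crossing: retained pairs ordered in both coordinates
            assert np.all(np.diff(av.atrial_peaks_s) > 0)
            assert np.all(np.diff(av.ventricular_peaks_s) > 0)

    def test_empty_series_rejected(self):
        a = BeatSeries(np.array([1.0]), t_start=0, t_end=2)
        with pytest.raises(ValueError, match="nonempty"):
            av_delay(a, BeatSeries(np.array([]), t_start=0, t_end=2))


class TestArrestRate:
    def test_all_and_none(self):
        arrested = [ArrestResult(True, 1, 1, 1)] * 6
        quiet = [ArrestResult(False)] * 6
        assert cardiac_arrest_rate(arrested) == 1.0
        assert cardiac_arrest_rate(quiet) == 0.0

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            cardiac_arrest_rate([])
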