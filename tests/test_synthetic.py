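"""Generator correctness: photostate ODE, planted beats, bouts, calcium,
frame rendering, and reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optophysio import (
    GaussianSpectrum,
    HeartSimParams,
    LightSchedule,
    PhotostateParams,
    TailSimParams,
    TimeSeries,
    photostate_equilibrium,
    render_heart_frames,
    simulate_gcamp_trial,
    simulate_heart_trial,
    simulate_photostate,
    simulate_tail_trial,
)

FPS = 67.0


def _params(k_act=2.0, k_rev=0.0, k_adapt=0.0, act_c=520.0, rev_c=480.0):
    return PhotostateParams(k_act=k_act, k_rev=k_rev,
                            sigma_act=GaussianSpectrum(act_c, 40.0),
                            sigma_rev=GaussianSpectrum(rev_c, 20.0),
                            k_adapt=k_adapt)


class TestPhotostate:
    def test_darkness_stays_inactive(self):
        a = simulate_photostate(_params(), LightSchedule(), 10.0, 1 / FPS)
        assert np.all(a.v == 0.0)

    def test_closed_form_pure_activation(self):
        # constant light, no reversal, no adaptation: a = 1 - exp(-k I t)
        p = _params(k_act=2.0)
        sch = LightSchedule(((0.0, 10.0, 520.0, 0.5),))
        a = simulate_photostate(p, sch, 10.0, 1 / FPS)
        exact = 1.0 - np.exp(-2.0 * 0.5 * a.t)
        rel = np.abs(a.v - exact) / np.maximum(exact, 1e-12)
        assert np.max(rel[1:]) < 1e-6

    def test_converges_to_analytic_equilibrium(self):
        p = _params(k_act=2.0, k_rev=1.0, k_adapt=0.1)
        sch = LightSchedule(((0.0, 60.0, 500.0, 0.5),))
        a = simulate_photostate(p, sch, 60.0, 1 / FPS)
        eq = photostate_equilibrium(p, 500.0, 0.5)
        assert a.v[-1] == pytest.approx(eq, rel=1e-6)

    def test_violet_pulse_then_blue_reversal_switches_off(self):
        # lamprey-parapinopsin-like: violet activates, sustained blue reverts
        p = PhotostateParams(k_act=1.9, k_rev=3.0,
                             sigma_act=GaussianSpectrum(405.0, 25.0),
                             sigma_rev=GaussianSpectrum(495.0, 40.0),
                             k_adapt=0.06)
        sch = LightSchedule(((1.0, 2.0, 405.0, 0.5), (3.0, 20.0, 480.0, 0.5)))
        a = simulate_photostate(p, sch, 20.0, 1 / FPS)
        peak = a.v[(a.t >= 2.0) & (a.t <= 3.0)].max()
        assert a.v[-1] < 0.1 * peak

    def test_schedule_beyond_duration_rejected(self):
        sch = LightSchedule(((0.0, 20.0, 520.0, 0.5),))
        with pytest.raises(ValueError, match="beyond duration"):
            simulate_photostate(_params(), sch, 10.0, 1 / FPS)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            simulate_photostate(_params(), LightSchedule(), 10.0, 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(k_act=st.floats(0.0, 10.0), k_rev=st.floats(0.0, 10.0),
           k_adapt=st.floats(0.0, 1.0), irr=st.floats(0.0, 2.0),
           wl=st.floats(380.0, 650.0))
    def test_active_fraction_bounded(self, k_act, k_rev, k_adapt, irr, wl):
        p = _params(k_act=k_act, k_rev=k_rev, k_adapt=k_adapt)
        sch = LightSchedule(((0.5, 3.0, wl, irr), (4.0, 6.0, 480.0, irr)))
        a = simulate_photostate(p, sch, 8.0, 0.02)
        assert np.all(a.v >= 0.0) and np.all(a.v <= 1.0)

    def test_photoreversal_monotone_in_reversal_irradiance(self):
        # with spectrally separated bands, terminal a decreases as reversal
        # irradiance rises, below the darkness (adaptation-only) level
        p = PhotostateParams(k_act=2.0, k_rev=0.3,
                             sigma_act=GaussianSpectrum(405.0, 15.0),
                             sigma_rev=GaussianSpectrum(495.0, 40.0),
                             k_adapt=0.05)
        terminals = []
        for irr in (0.0, 0.25, 0.5, 1.0):
            segs = [(0.0, 1.0, 405.0, 0.5)]
            if irr > 0:
                segs.append((1.0, 15.0, 480.0, irr))
            a = simulate_photostate(p, LightSchedule(tuple(segs)), 15.0, 1 / FPS)
            terminals.append(a.v[-1])
        assert all(x > y for x, y in zip(terminals, terminals[1:]))


class TestHeartTrial:
    def test_unstimulated_beat_train_is_regular(self, dark_photostate):
        hp = HeartSimParams(noise_sd=0.0)
        _, _, truth = simulate_heart_trial(hp, dark_photostate, 20.0, seed=1)
        assert len(truth.beat_times_s) == 50  # 150 bpm over 20 s
        assert np.allclose(np.diff(truth.beat_times_s), 0.4, atol=1e-9)

    def test_ventricle_lags_atrium_by_av_delay(self, dark_photostate):
        hp = HeartSimParams(noise_sd=0.0, av_delay_s=0.08)
        atr, ven, truth = simulate_heart_trial(hp, dark_photostate, 20.0, seed=2)
        n = len(truth.ventricular_beat_times_s)
        lags = truth.ventricular_beat_times_s - truth.beat_times_s[:n]
        assert np.allclose(lags, 0.08, atol=1e-12)

    def test_default_scenario_plants_arrest_near_reported_values(
            self, mosopn3_photostate):
        lat, res = [], []
        for seed in range(20):
            hp = HeartSimParams(noise_sd=0.0)
            _, _, truth = simulate_heart_trial(hp, mosopn3_photostate, 30.0,
                                               seed, stim_onset_s=5.0)
            assert truth.arrested
            lat.append(truth.latency_to_arrest_s)
            res.append(truth.time_to_resumption_s)
        assert 0.5 < np.mean(lat) < 1.1   # reported 0.812 +- 0.198 s
        assert 5.0 < np.mean(res) < 13.0  # reported 8.83 +- 5.13 s

    def test_beat_count_matches_rate_integral(self, mosopn3_photostate):
        hp = HeartSimParams(noise_sd=0.0)
        _, _, truth = simulate_heart_trial(hp, mosopn3_photostate, 30.0, 7,
                                           stim_onset_s=5.0)
        rate_hz = truth.rate_profile.v / 60.0
        for lo, hi in ((0.0, 5.0), (5.0, 15.0), (0.0, 30.0)):
            sel = (truth.rate_profile.t >= lo) & (truth.rate_profile.t <= hi)
            expected = np.trapezoid(rate_hz[sel], truth.rate_profile.t[sel])
            count = np.sum((truth.beat_times_s >= lo) & (truth.beat_times_s < hi))
            assert abs(count - expected) <= 1.0

    def test_bit_reproducible_under_fixed_seed(self, mosopn3_photostate):
        hp = HeartSimParams(noise_sd=0.1)
        a1 = simulate_heart_trial(hp, mosopn3_photostate, 30.0, 11,
                                  stim_onset_s=5.0)
        a2 = simulate_heart_trial(hp, mosopn3_photostate, 30.0, 11,
                                  stim_onset_s=5.0)
        assert np.array_equal(a1[0].v, a2[0].v)
        assert np.array_equal(a1[1].v, a2[1].v)
        assert np.array_equal(a1[2].beat_times_s, a2[2].beat_times_s)

    def test_bad_threshold_rejected(self, dark_photostate):
        with pytest.raises(ValueError, match="arrest_threshold"):
            HeartSimParams(arrest_threshold=1.5)


class TestTailTrial:
    def test_noise_only_trace_stays_small(self):
        tp = TailSimParams(noise_sd=0.004)
        trace, truth = simulate_tail_trial(tp, 2.0, 10.0, seed=1)
        assert np.max(np.abs(trace.v)) <= 5 * tp.noise_sd
        assert not truth.pre_stimulus_active

    def test_single_bout_ground_truth(self):
        tp = TailSimParams((5.2,), (4.4,), (0.3,), noise_sd=0.0)
        trace, truth = simulate_tail_trial(tp, 2.0, 15.0, seed=1)
        assert truth.bout_onsets_s[0] == 5.2
        assert truth.bout_durations_s[0] == 4.4
        # flat-topped envelope attains the planted amplitude
        assert np.max(np.abs(trace.v)) == pytest.approx(0.3, rel=0.01)
        # silent outside the bout
        outside = (trace.t < 5.1) | (trace.t > 9.8)
        assert np.all(np.abs(trace.v[outside]) < 1e-12)

    def test_pre_stimulus_bout_flagged(self):
        tp = TailSimParams((1.0,), (0.5,), (0.2,), noise_sd=0.0)
        _, truth = simulate_tail_trial(tp, 2.0, 10.0, seed=1)
        assert truth.pre_stimulus_active

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TailSimParams((1.0, 1.5), (1.0, 1.0), (0.2, 0.2))


class TestGcampTrial:
    def test_quiet_heart_gives_flat_baseline(self, dark_photostate):
        hp = HeartSimParams()
        F, _ = simulate_gcamp_trial(100.0, 5.0, dark_photostate, hp, seed=1,
                                    duration_s=10.0, beats=[])
        assert np.allclose(F.v, 100.0)

    def test_single_beat_transient_peaks_at_coupling(self, dark_photostate):
        hp = HeartSimParams()
        F, _ = simulate_gcamp_trial(100.0, 5.0, dark_photostate, hp, seed=1,
                                    duration_s=10.0, beats=[3.0 - 1.0 / FPS * 0])
        # beat time on the sample grid: kernel max is exactly the coupling
        tb = F.t[np.argmax(F.v)]
        assert np.max(F.v) - 100.0 == pytest.approx(5.0, rel=1e-9)
        assert tb == pytest.approx(3.0, abs=1e-9)

    def test_arrest_dips_below_baseline(self, mosopn3_photostate):
        hp = HeartSimParams()
        F, truth = simulate_gcamp_trial(100.0, 2.0, mosopn3_photostate, hp,
                                        seed=2, duration_s=30.0)
        arrest = (F.t > 8.0) & (F.t < 12.0)
        assert F.v[arrest].mean() < 100.0
        assert np.all(F.v > 0)

    def test_nonpositive_baseline_rejected(self, dark_photostate):
        with pytest.raises(ValueError, match="baseline"):
            simulate_gcamp_trial(0.0, 5.0, dark_photostate, HeartSimParams(), 1)


class TestRenderFrames:
    def test_constant_traces_render_identical_frames(self):
        t = np.arange(0.0, 1.0, 1 / FPS)
        c = TimeSeries(t, np.full_like(t, 3.0))
        frames, _ = render_heart_frames(c, c)
        assert np.all(frames == frames[0])

    def test_round_trip_correlation(self, plain_heart_trial):
        from optophysio import FrameStack, Roi, extract_roi_luminosity
        atr, ven, _ = plain_heart_trial
        frames, rois = render_heart_frames(atr, ven)
        stack = FrameStack(frames, FPS)
        for lab, ref in (("atrium", atr), ("ventricle", ven)):
            rec = extract_roi_luminosity(stack, Roi(rois[lab], lab))
            r = np.corrcoef(rec.v, ref.v)[0, 1]
            assert r > 0.99

    def test_small_image_rejected(self, plain_heart_trial):
        atr, ven, _ = plain_heart_trial
        with pytest.raises(ValueError, match="32x32"):
            render_heart_frames(atr, ven, image_size=(16, 16))
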