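"""Synthetic physiological signals gated by a bistable-opsin photostate model.

The generator emulates the observables of an optogenetic cardio/locomotion
study in larval zebrafish:

* a two-state photopigment (dark/inactive vs photoproduct/active) whose
  active fraction ``a(t)`` follows a linear ODE driven by a light schedule —
  activation and photoreversal are both light-driven with wavelength-dependent
  efficiencies, plus a light-independent adaptation decay;
* heart-region luminosity oscillating at the beat rate, with cardiac arrest
  when ``a(t)`` exceeds a threshold and gradual first-order recovery;
* paired atrium/ventricle traces with a fixed atrio-ventricular lag;
* tail lateral-displacement traces with discrete movement bouts;
* GCaMP fluorescence with beat-coupled transients and an arrest-coupled dip;
* optionally, small rendered frame stacks with ROI masks, to exercise the
  image-extraction stage end to end.

Every generator takes an explicit seed and records the planted parameters in
a :class:`~optophysio.core.GroundTruth`, so each analysis stage has a
parameter-recovery oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import GroundTruth, LightSchedule, LightSegment, TimeSeries, Trial

__all__ = [
    "GaussianSpectrum",
    "PhotostateParams",
    "HeartSimParams",
    "TailSimParams",
    "simulate_photostate",
    "photostate_equilibrium",
    "simulate_heart_trial",
    "simulate_tail_trial",
    "simulate_gcamp_trial",
    "render_heart_frames",
    "opsin_presets",
    "pulse_schedule",
    "simulate_heart_cohort",
    "simulate_locomotion_cohort",
]

DEFAULT_FPS = 67.0  # infrared CMOS camera frame rate emulated throughout


# --------------------------------------------------------------------------
# photostate model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianSpectrum:
    """Unitless spectral efficiency in [0, 1]: a Gaussian bump over wavelength."""

    center_nm: float
    width_nm: float

    def __call__(self, wavelength_nm: float) -> float:
        x = (wavelength_nm - self.center_nm) / self.width_nm
        return float(np.exp(-0.5 * x * x))


@dataclass(frozen=True)
class PhotostateParams:
    """Kinetic constants of the two-state pigment.

    ``k_act`` and ``k_rev`` are rates per (mW/mm^2)/s at the peak of their
    respective spectra; ``k_adapt`` (1/s) is the light-independent decay of
    the active state (adaptation).
    """

    k_act: float
    k_rev: float
    sigma_act: GaussianSpectrum
    sigma_rev: GaussianSpectrum
    k_adapt: float = 0.0

    def __post_init__(self):
        if self.k_act < 0 or self.k_rev < 0 or self.k_adapt < 0:
            raise ValueError("all rates must be >= 0")

    def rates(self, wavelength_nm: float, irradiance: float) -> tuple[float, float]:
        """(alpha, beta): activation and deactivation rates under given light."""
        alpha = self.k_act * self.sigma_act(wavelength_nm) * irradiance
        beta = self.k_rev * self.sigma_rev(wavelength_nm) * irradiance + self.k_adapt
        return alpha, beta


def photostate_equilibrium(params: PhotostateParams, wavelength_nm: float,
                           irradiance: float) -> float:
    """Analytic equilibrium active fraction under constant illumination."""
    alpha, beta = params.rates(wavelength_nm, irradiance)
    if alpha + beta == 0.0:
        return 0.0
    return alpha / (alpha + beta)


def simulate_photostate(params: PhotostateParams, schedule: LightSchedule,
                        duration_s: float, dt_s: float,
                        a0: float = 0.0) -> TimeSeries:
    """Integrate da/dt = alpha(t) (1-a) - beta(t) a on a uniform grid.

    The coefficients are piecewise constant (one value per light segment,
    darkness elsewhere), so the update between samples is the exact
    exponential solution of the linear ODE; sample intervals straddling a
    segment boundary are split at the boundary. The result is exact up to
    floating-point rounding.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if schedule.end_s > duration_s + 1e-12:
        raise ValueError(
            f"schedule extends to {schedule.end_s} s beyond duration {duration_s} s"
        )
    if not 0.0 <= a0 <= 1.0:
        raise ValueError("a0 must lie in [0, 1]")

    n = int(round(duration_s / dt_s)) + 1
    t = np.arange(n) * dt_s
    a = np.empty(n)
    a[0] = a0

    breaks = schedule.breakpoints()

    def _advance(a_cur: float, t0: float, t1: float) -> float:
        seg = schedule.at(0.5 * (t0 + t1))
        if seg is None:
            alpha, beta = 0.0, params.k_adapt
        else:
            alpha, beta = params.rates(seg.wavelength_nm, seg.irradiance_mW_per_mm2)
        k = alpha + beta
        if k == 0.0:
            return a_cur
        a_eq = alpha / k
        return a_eq + (a_cur - a_eq) * math.exp(-k * (t1 - t0))

    cur = a0
    for i in range(1, n):
        t0, t1 = t[i - 1], t[i]
        # split the interval at any schedule breakpoints it contains
        inner = breaks[(breaks > t0 + 1e-15) & (breaks < t1 - 1e-15)]
        lo = t0
        for b in inner:
            cur = _advance(cur, lo, float(b))
            lo = float(b)
        cur = _advance(cur, lo, t1)
        # exact solution is bounded; clamp only rounding excursions
        cur = min(1.0, max(0.0, cur))
        a[i] = cur

    return TimeSeries(t, a)


# --------------------------------------------------------------------------
# heart trial
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HeartSimParams:
    """Parameters of the simulated cardiac trace.

    Beating is fully suppressed while the active fraction exceeds
    ``arrest_threshold``; below it the target rate scales with
    1 - (a/threshold)**gate_sharpness, and the realized rate relaxes toward
    the target with time constant ``recovery_tau_s`` (suppression itself is
    immediate). The default sharpness of 4 keeps the rate near baseline
    until the threshold is approached, reproducing the observed abrupt
    arrest while recovery stays graded; sharpness 1 recovers a purely
    linear gate.
    """

    base_rate_bpm: float = 150.0
    av_delay_s: float = 0.08
    arrest_threshold: float = 0.5
    gate_sharpness: float = 4.0
    recovery_tau_s: float = 2.0
    beat_waveform_amp: float = 1.0
    beat_width_s: float = 0.12
    noise_sd: float = 0.0
    fps: float = DEFAULT_FPS

    def __post_init__(self):
        if self.base_rate_bpm <= 0:
            raise ValueError("base_rate_bpm must be > 0")
        if self.av_delay_s < 0:
            raise ValueError("av_delay_s must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.recovery_tau_s <= 0:
            raise ValueError("recovery_tau_s must be > 0")
        if not 0.0 < self.arrest_threshold <= 1.0:
            raise ValueError("arrest_threshold must lie in (0, 1]")


def _raised_cosine_train(t: np.ndarray, beat_times: np.ndarray,
                         amp: float, width: float) -> np.ndarray:
    """Sum of raised-cosine pulses of the given width centred on beat times."""
    v = np.zeros_like(t)
    if len(t) < 2:
        return v
    dt = t[1] - t[0]
    half = width / 2.0
    for tb in beat_times:
        i0 = max(0, int(math.ceil((tb - half - t[0]) / dt)))
        i1 = min(len(t) - 1, int(math.floor((tb + half - t[0]) / dt)))
        if i1 < i0:
            continue
        x = t[i0:i1 + 1] - tb
        v[i0:i1 + 1] += amp * 0.5 * (1.0 + np.cos(np.pi * x / half))
    return v


def _plant_beats(a: np.ndarray, t: np.ndarray, hparams: HeartSimParams,
                 phase0: float) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the gated, relaxing beat rate; return (beat_times, rate_hz)."""
    base_hz = hparams.base_rate_bpm / 60.0
    thr = hparams.arrest_threshold
    gate = np.clip(1.0 - (np.minimum(a, thr) / thr) ** hparams.gate_sharpness,
                   0.0, 1.0)
    gate[a >= thr] = 0.0
    target = base_hz * gate
    n = len(t)
    dt = t[1] - t[0]
    rate = np.empty(n)
    r = target[0]
    rate[0] = r
    beats: list[float] = []
    phase = phase0
    next_k = 1.0
    for i in range(1, n):
        tgt = target[i]
        if tgt < r:
            r = tgt  # suppression is immediate
        else:
            r += (dt / hparams.recovery_tau_s) * (tgt - r)
        rate[i] = r
        dphi = 0.5 * (rate[i - 1] + r) * dt
        new_phase = phase + dphi
        while new_phase >= next_k and dphi > 0:
            frac = (next_k - phase) / dphi
            beats.append(float(t[i - 1] + frac * dt))
            next_k += 1.0
        phase = new_phase
    return np.asarray(beats), rate


def _arrest_truth_from_beats(beat_times: np.ndarray, stim_onset_s: float,
                             baseline_ibi_s: float, record_end_s: float,
                             gap_factor: float = 2.0,
                             search_window_s: float = 8.0) -> dict:
    """Arrest metrics from exact beat times by the missed-expected-beat rule.

    Arrest onset is the last beat preceding the first post-stimulus inter-beat
    gap exceeding ``gap_factor`` times the baseline IBI, plus one baseline IBI
    (the first missed expected beat). The same rule is applied by the
    detector to *detected* beats, so recovery error measures trace-level
    detection alone.
    """
    bt = np.asarray(beat_times, dtype=float)
    out = dict(arrested=False, arrest_onset_s=None, latency_to_arrest_s=None,
               time_to_resumption_s=None, arrest_duration_s=None)
    if len(bt) == 0:
        return out
    edges = np.concatenate([bt, [record_end_s]])
    for i in range(len(bt)):
        gap = edges[i + 1] - edges[i]
        if edges[i + 1] <= stim_onset_s:
            continue
        if gap > gap_factor * baseline_ibi_s:
            onset = edges[i] + baseline_ibi_s
            if onset > stim_onset_s + search_window_s:
                break
            out["arrested"] = True
            out["arrest_onset_s"] = onset
            out["latency_to_arrest_s"] = onset - stim_onset_s
            if i + 1 < len(bt):
                res = bt[i + 1] - onset
                out["time_to_resumption_s"] = res
                out["arrest_duration_s"] = res
            break
    return out


def simulate_heart_trial(hparams: HeartSimParams, a: TimeSeries,
                         duration_s: float, seed: int,
                         stim_onset_s: Optional[float] = None,
                         phase0: Optional[float] = None,
                         ) -> tuple[TimeSeries, TimeSeries, GroundTruth]:
    """Render atrial and ventricular luminosity traces driven by ``a(t)``.

    Beats are planted by a phase accumulator over the suppressed/relaxing
    instantaneous rate; each beat is drawn as a raised-cosine luminosity
    pulse; the ventricular train is the atrial train delayed by
    ``av_delay_s``. Additive Gaussian noise is applied per sample.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * hparams.fps)) + 1
    t = np.arange(n) / hparams.fps
    a_grid = np.interp(t, a.t, a.v)
    if phase0 is None:
        phase0 = float(rng.uniform(0.0, 1.0))

    beat_times, rate_hz = _plant_beats(a_grid, t, hparams, phase0)
    v_beats = beat_times + hparams.av_delay_s
    v_beats = v_beats[v_beats <= duration_s]

    atr = _raised_cosine_train(t, beat_times, hparams.beat_waveform_amp,
                               hparams.beat_width_s)
    ven = _raised_cosine_train(t, v_beats, hparams.beat_waveform_amp,
                               hparams.beat_width_s)
    if hparams.noise_sd > 0:
        atr = atr + rng.normal(0.0, hparams.noise_sd, n)
        ven = ven + rng.normal(0.0, hparams.noise_sd, n)

    truth = GroundTruth(
        seed=seed,
        beat_times_s=beat_times,
        ventricular_beat_times_s=v_beats,
        av_delay_s=hparams.av_delay_s,
        rate_profile=TimeSeries(t, rate_hz * 60.0),
        stim_onset_s=stim_onset_s,
    )
    if stim_onset_s is not None:
        arrest = _arrest_truth_from_beats(
            beat_times, stim_onset_s, 60.0 / hparams.base_rate_bpm, duration_s)
        truth.arrested = arrest["arrested"]
        truth.arrest_onset_s = arrest["arrest_onset_s"]
        truth.latency_to_arrest_s = arrest["latency_to_arrest_s"]
        truth.time_to_resumption_s = arrest["time_to_resumption_s"]
        truth.arrest_duration_s = arrest["arrest_duration_s"]
    return TimeSeries(t, atr), TimeSeries(t, ven), truth


# --------------------------------------------------------------------------
# tail trial
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TailSimParams:
    """Planted swim bouts on a lateral-displacement trace (body-length units)."""

    bout_onsets_s: tuple[float, ...] = ()
    bout_durations_s: tuple[float, ...] = ()
    bout_amplitudes: tuple[float, ...] = ()
    tail_beat_freq_hz: float = 20.0
    taper_s: float = 0.05
    noise_sd: float = 0.005
    fps: float = DEFAULT_FPS

    def __post_init__(self):
        on = tuple(float(x) for x in self.bout_onsets_s)
        du = tuple(float(x) for x in self.bout_durations_s)
        am = tuple(float(x) for x in self.bout_amplitudes)
        if not (len(on) == len(du) == len(am)):
            raise ValueError("bout lists must have equal length")
        if any(a < 0 for a in am):
            raise ValueError("amplitudes must be >= 0")
        if any(b <= a for a, b in zip(on, on[1:])):
            raise ValueError("onsets must be strictly increasing")
        for (o1, d1), o2 in zip(zip(on, du), on[1:]):
            if o1 + d1 > o2:
                raise ValueError("overlapping bouts rejected")
        object.__setattr__(self, "bout_onsets_s", on)
        object.__setattr__(self, "bout_durations_s", du)
        object.__setattr__(self, "bout_amplitudes", am)


def _tukey_envelope(x: np.ndarray, duration: float, taper: float) -> np.ndarray:
    """Flat-top envelope with cosine tapers of the given length at both ends."""
    taper = min(taper, duration / 2.0)
    env = np.ones_like(x)
    if taper > 0:
        rise = x < taper
        fall = x > duration - taper
        env[rise] = np.sin(0.5 * np.pi * x[rise] / taper) ** 2
        env[fall] = np.sin(0.5 * np.pi * (duration - x[fall]) / taper) ** 2
    env[(x < 0) | (x > duration)] = 0.0
    return env


def simulate_tail_trial(tparams: TailSimParams, stim_onset_s: float,
                        duration_s: float, seed: int
                        ) -> tuple[TimeSeries, GroundTruth]:
    """Tail displacement: zero-mean noise outside bouts, oscillation within.

    Within a bout the signal is amplitude x envelope x sin(2 pi f t'), with a
    flat-topped envelope so the planted amplitude is attained.
    """
    if any(o + d > duration_s for o, d in
           zip(tparams.bout_onsets_s, tparams.bout_durations_s)):
        raise ValueError("bouts must lie within the record duration")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * tparams.fps)) + 1
    t = np.arange(n) / tparams.fps
    v = rng.normal(0.0, tparams.noise_sd, n) if tparams.noise_sd > 0 else np.zeros(n)
    for onset, dur, amp in zip(tparams.bout_onsets_s, tparams.bout_durations_s,
                               tparams.bout_amplitudes):
        x = t - onset
        env = _tukey_envelope(x, dur, tparams.taper_s)
        v += amp * env * np.sin(2.0 * np.pi * tparams.tail_beat_freq_hz * x)
    truth = GroundTruth(
        seed=seed,
        bout_onsets_s=np.asarray(tparams.bout_onsets_s),
        bout_durations_s=np.asarray(tparams.bout_durations_s),
        bout_amplitudes=np.asarray(tparams.bout_amplitudes),
        pre_stimulus_active=any(o < stim_onset_s for o in tparams.bout_onsets_s),
        stim_onset_s=stim_onset_s,
    )
    return TimeSeries(t, v), truth


# --------------------------------------------------------------------------
# GCaMP trial
# --------------------------------------------------------------------------

def simulate_gcamp_trial(baseline_F: float, beat_coupling: float,
                         a: TimeSeries, hparams: HeartSimParams, seed: int,
                         duration_s: Optional[float] = None,
                         beats: Optional[Sequence[float]] = None,
                         dip_frac: float = 0.4, tau_decay_s: float = 0.25,
                         noise_sd: float = 0.0,
                         ) -> tuple[TimeSeries, GroundTruth]:
    """GCaMP fluorescence: baseline + per-beat transients - arrest-coupled dip.

    Each beat contributes an exponential-decay transient of peak amplitude
    ``beat_coupling``; during suppression the baseline dips by ``dip_frac``
    times the instantaneous suppression level (1 - rate/base rate).
    """
    if baseline_F <= 0:
        raise ValueError("baseline_F must be positive")
    if duration_s is None:
        duration_s = float(a.t[-1])
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * hparams.fps)) + 1
    t = np.arange(n) / hparams.fps
    a_grid = np.interp(t, a.t, a.v)
    if beats is None:
        phase0 = float(rng.uniform(0.0, 1.0))
        beat_times, rate_hz = _plant_beats(a_grid, t, hparams, phase0)
    else:
        beat_times = np.asarray(beats, dtype=float)
        _, rate_hz = _plant_beats(a_grid, t, hparams, 0.0)
    base_hz = hparams.base_rate_bpm / 60.0
    suppression = 1.0 - rate_hz / base_hz
    F = baseline_F * (1.0 - dip_frac * suppression)
    for tb in beat_times:
        m = t >= tb
        F[m] += beat_coupling * np.exp(-(t[m] - tb) / tau_decay_s)
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, n)
    F = np.maximum(F, 1e-9)
    truth = GroundTruth(seed=seed, beat_times_s=beat_times,
                        baseline_F=baseline_F, beat_coupling=beat_coupling,
                        rate_profile=TimeSeries(t, rate_hz * 60.0))
    return TimeSeries(t, F), truth


# --------------------------------------------------------------------------
# frame rendering
# --------------------------------------------------------------------------

def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = center
    ry, rx = radii
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def render_heart_frames(atrium: TimeSeries, ventricle: TimeSeries,
                        image_size: tuple[int, int] = (64, 96), seed: int = 0,
                        area_trace: Optional[TimeSeries] = None,
                        noise_sd: float = 0.0,
                        background: float = 10.0, lum_range: tuple[float, float] = (60.0, 200.0),
                        ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw two pulsating-ellipse chambers whose ROI means track the traces.

    Pixel intensity inside each chamber is an affine map of the corresponding
    trace into ``lum_range``; if ``area_trace`` is given, chamber semi-axes
    are scaled by sqrt(area ratio) per frame. Returns the float32 frame stack
    and the (static) ROI masks keyed by chamber label.
    """
    h, w = image_size
    if h < 32 or w < 32:
        raise ValueError("image_size must be at least 32x32")
    if len(atrium) != len(ventricle):
        raise ValueError("atrium and ventricle traces must share a grid")
    n = len(atrium)
    ry = rx = min(h, w) / 5.0
    centers = {"atrium": (h / 2.0, w * 0.27), "ventricle": (h / 2.0, w * 0.73)}
    pad = 1.2 if area_trace is None else 1.2 * math.sqrt(float(np.max(area_trace.v)))
    if abs(centers["atrium"][1] - centers["ventricle"][1]) <= 2 * rx * pad:
        raise ValueError("chamber regions overlap; enlarge image or reduce radii")

    def _affine(tr: TimeSeries) -> np.ndarray:
        lo, hi = float(np.min(tr.v)), float(np.max(tr.v))
        if hi - lo < 1e-12:
            return np.full(n, 0.5 * (lum_range[0] + lum_range[1]))
        return lum_range[0] + (tr.v - lo) / (hi - lo) * (lum_range[1] - lum_range[0])

    lum = {"atrium": _affine(atrium), "ventricle": _affine(ventricle)}
    rois = {lab: _ellipse_mask((h, w), c, (ry, rx)) for lab, c in centers.items()}

    rng = np.random.default_rng(seed)
    frames = np.full((n, h, w), background, dtype=np.float32)
    for i in range(n):
        if area_trace is None:
            masks = rois
        else:
            s = math.sqrt(float(np.interp(atrium.t[i], area_trace.t, area_trace.v)))
            masks = {lab: _ellipse_mask((h, w), c, (ry * s, rx * s))
                     for lab, c in centers.items()}
        for lab, m in masks.items():
            frames[i][m] = lum[lab][i]
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)
    return frames, rois


# --------------------------------------------------------------------------
# opsin presets and cohort scenarios
# --------------------------------------------------------------------------

def opsin_presets() -> dict[str, PhotostateParams]:
    """Qualitative kinetic presets for the three cardiac Gi/o-coupled pigments.

    The study reports no quantitative kinetic constants, so magnitudes are
    design choices tuned so that, with the default heart parameters and a
    1 s, 0.5 mW/mm^2 pulse at each pigment's peak wavelength, the emergent
    arrest latency centres near 0.8 s and resumption near 9 s. The ordering
    of adaptation rates (mosopn3 slowest) and the spectral separation of
    lampp's activation (violet) from its photoreversal (blue/green) follow
    the reported phenomenology.
    """
    return {
        "mosopn3": PhotostateParams(
            k_act=1.9, k_rev=0.15,
            sigma_act=GaussianSpectrum(520.0, 45.0),
            sigma_rev=GaussianSpectrum(480.0, 15.0),
            k_adapt=0.033,
        ),
        "puftmt": PhotostateParams(
            k_act=1.9, k_rev=0.3,
            sigma_act=GaussianSpectrum(470.0, 40.0),
            sigma_rev=GaussianSpectrum(480.0, 20.0),
            k_adapt=0.05,
        ),
        "lampp": PhotostateParams(
            k_act=1.9, k_rev=3.0,
            sigma_act=GaussianSpectrum(405.0, 25.0),
            sigma_rev=GaussianSpectrum(495.0, 40.0),
            k_adapt=0.06,
        ),
    }


#: peak stimulation wavelength used for each preset (nm)
STIM_WAVELENGTH = {"mosopn3": 520.0, "puftmt": 470.0, "lampp": 405.0}
#: blue/green band used for sustained photoreversal illumination (nm)
REVERSAL_WAVELENGTH = 480.0


def pulse_schedule(opsin: str, onset_s: float = 5.0, pulse_s: float = 1.0,
                   irradiance: float = 0.5,
                   reversal_from_s: Optional[float] = None,
                   reversal_until_s: Optional[float] = None,
                   reversal_irradiance: float = 0.5) -> LightSchedule:
    """1 s activation pulse at the opsin's peak wavelength, optionally followed
    by sustained blue/green reversal-band light."""
    segs = [LightSegment(onset_s, onset_s + pulse_s, STIM_WAVELENGTH[opsin], irradiance)]
    if reversal_from_s is not None:
        if reversal_until_s is None:
            raise ValueError("reversal_until_s required with reversal_from_s")
        segs.append(LightSegment(reversal_from_s, reversal_until_s,
                                 REVERSAL_WAVELENGTH, reversal_irradiance))
    return LightSchedule(tuple(segs))


def simulate_heart_cohort(opsin: str = "mosopn3", n_larvae: int = 4,
                          n_trials: int = 6, seed: int = 1,
                          duration_s: float = 25.0, stim_onset_s: float = 5.0,
                          irradiance: float = 0.5,
                          hparams: Optional[HeartSimParams] = None,
                          reversal: bool = False,
                          reversal_offset_s: float = 2.0,
                          reversal_duration_s: float = 20.0,
                          weak_from_trial: Optional[int] = None,
                          weak_irradiance: float = 0.002,
                          photostate: Optional[PhotostateParams] = None,
                          ) -> list[Trial]:
    """Simulate a cohort of heart trials for one opsin regime.

    ``reversal`` adds sustained blue/green light for ``reversal_duration_s``
    starting ``reversal_offset_s`` after stimulus onset (the switch-off
    experiment). ``weak_from_trial``
    drops the pulse irradiance from that 1-based trial index onward,
    emulating pharmacological blockade of the response.
    """
    if hparams is None:
        hparams = HeartSimParams(noise_sd=0.05)
    params = photostate if photostate is not None else opsin_presets()[opsin]
    ss = np.random.SeedSequence(seed)
    trials = []
    for larva in range(n_larvae):
        for k in range(1, n_trials + 1):
            child = ss.spawn(1)[0]
            trial_seed = int(child.generate_state(1)[0] % (2 ** 31))
            irr = irradiance
            if weak_from_trial is not None and k >= weak_from_trial:
                irr = weak_irradiance
            sched = pulse_schedule(
                opsin, stim_onset_s, 1.0, irr,
                reversal_from_s=stim_onset_s + reversal_offset_s if reversal else None,
                reversal_until_s=min(duration_s,
                                     stim_onset_s + reversal_offset_s
                                     + reversal_duration_s) if reversal else None)
            a = simulate_photostate(params, sched, duration_s, 1.0 / hparams.fps)
            atr, ven, truth = simulate_heart_trial(
                hparams, a, duration_s, trial_seed, stim_onset_s=stim_onset_s)
            trials.append(Trial(
                larva_id=f"{opsin}_L{larva + 1}", trial_index=k, tool=opsin,
                stim=sched, signals={"atrium": atr, "ventricle": ven},
                truth=truth))
    return trials


def simulate_locomotion_cohort(n_larvae: int = 12, n_trials: int = 6,
                               seed: int = 1, duration_s: float = 20.0,
                               stim_onset_s: float = 2.0,
                               induced_prob: float = 0.89,
                               pre_stim_prob: float = 0.05,
                               latency_mean_s: float = 3.2,
                               latency_sd_s: float = 1.1,
                               duration_mean_s: float = 4.4,
                               duration_sd_s: float = 2.0,
                               amplitude_mean: float = 0.3,
                               amplitude_sd: float = 0.08,
                               noise_sd: float = 0.005,
                               ) -> list[Trial]:
    """Trial-structured tail-displacement cohort with known bout parameters.

    Defaults mirror a strongly responsive Gq-coupled regime: ~89% of trials
    induced, latency ~3.2 s, bout duration ~4.4 s, strength ~0.3 body lengths.
    """
    ss = np.random.SeedSequence(seed)
    trials = []
    for larva in range(n_larvae):
        for k in range(1, n_trials + 1):
            child = ss.spawn(1)[0]
            trial_seed = int(child.generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(trial_seed)
            onsets, durs, amps = [], [], []
            if rng.uniform() < pre_stim_prob:
                onsets.append(max(0.2, stim_onset_s - rng.uniform(0.5, 1.5)))
                durs.append(rng.uniform(0.3, 0.8))
                amps.append(abs(rng.normal(amplitude_mean, amplitude_sd)))
            if rng.uniform() < induced_prob:
                lat = float(np.clip(rng.normal(latency_mean_s, latency_sd_s), 0.3, 7.5))
                dur = float(np.clip(rng.normal(duration_mean_s, duration_sd_s), 0.5, 8.0))
                onset = stim_onset_s + lat
                dur = min(dur, duration_s - onset - 0.2)
                if not onsets or onset > onsets[-1] + durs[-1] + 0.3:
                    onsets.append(onset)
                    durs.append(dur)
                    amps.append(float(np.clip(rng.normal(amplitude_mean, amplitude_sd),
                                              0.08, 1.0)))
            tp = TailSimParams(tuple(onsets), tuple(durs), tuple(amps),
                               noise_sd=noise_sd)
            trace, truth = simulate_tail_trial(tp, stim_onset_s, duration_s,
                                               trial_seed)
            sched = LightSchedule((LightSegment(stim_onset_s, stim_onset_s + 1.0,
                                                520.0, 0.4),))
            trials.append(Trial(larva_id=f"loco_L{larva + 1}", trial_index=k,
                                tool="gq_opsin", stim=sched,
                                signals={"tail": trace}, truth=truth))
    return trials
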