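"""Heartbeat detection and cardiac metrics from ROI luminosity traces.

The chain is: detect beats on a detrended trace (peak detection with a
robust prominence floor and sub-frame parabolic refinement), then derive

* relative heartbeat frequency (sliding beat count, normalized to a
  pre-stimulus baseline),
* cardiac-arrest metrics (latency to arrest, time to resumption) by a
  missed-expected-beat rule on the inter-beat gaps,
* arrest-time ratios across consecutive trials (pharmacology readout),
* atrio-ventricular conduction delay by non-crossing peak matching with the
  0.5 s exclusion rule,
* per-larva cardiac arrest rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import find_peaks

from .core import LightSchedule, TimeSeries

__all__ = [
    "BeatSeries",
    "ArrestResult",
    "AvDelaySeries",
    "FrequencyTrace",
    "detect_beats",
    "relative_hb_frequency",
    "detect_arrest",
    "arrest_time_ratio",
    "av_delay",
    "cardiac_arrest_rate",
]


@dataclass(frozen=True)
class BeatSeries:
    """Ordered beat times extracted from one cardiac trace."""

    beat_times_s: np.ndarray
    trial_id: Optional[str] = None
    t_start: Optional[float] = None
    t_end: Optional[float] = None

    def __post_init__(self):
        bt = np.asarray(self.beat_times_s, dtype=float)
        if len(bt) > 1 and np.any(np.diff(bt) <= 0):
            raise ValueError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times_s", bt)
        t0 = self.t_start if self.t_start is not None else (bt[0] if len(bt) else 0.0)
        t1 = self.t_end if self.t_end is not None else (bt[-1] if len(bt) else 0.0)
        if len(bt) and (bt[0] < t0 - 1e-9 or bt[-1] > t1 + 1e-9):
            raise ValueError("beat times outside the trace span")
        object.__setattr__(self, "t_start", float(t0))
        object.__setattr__(self, "t_end", float(t1))

    def __len__(self) -> int:
        return len(self.beat_times_s)


@dataclass(frozen=True)
class ArrestResult:
    """Arrest metrics for one trial; times are None when not arrested."""

    arrested: bool
    latency_to_arrest_s: Optional[float] = None
    time_to_resumption_s: Optional[float] = None
    arrest_duration_s: Optional[float] = None

    def __post_init__(self):
        if self.arrested:
            for name in ("latency_to_arrest_s",):
                v = getattr(self, name)
                if v is not None and v < 0:
                    raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AvDelaySeries:
    """Matched atrial/ventricular peak pairs and their conduction delays."""

    atrial_peaks_s: np.ndarray
    ventricular_peaks_s: np.ndarray
    delays_s: np.ndarray
    n_excluded: int
    max_delay_s: float = 0.5

    def __post_init__(self):
        a = np.asarray(self.atrial_peaks_s, dtype=float)
        v = np.asarray(self.ventricular_peaks_s, dtype=float)
        d = np.asarray(self.delays_s, dtype=float)
        if not (len(a) == len(v) == len(d)):
            raise ValueError("pair arrays must have equal length")
        if np.any(d <= 0) or np.any(d > self.max_delay_s + 1e-12):
            raise ValueError(f"retained delays must lie in (0, {self.max_delay_s}]")
        object.__setattr__(self, "atrial_peaks_s", a)
        object.__setattr__(self, "ventricular_peaks_s", v)
        object.__setattr__(self, "delays_s", d)

    def __len__(self) -> int:
        return len(self.delays_s)


@dataclass(frozen=True)
class FrequencyTrace:
    """Relative heartbeat frequency over time (1.0 = pre-stimulus baseline)."""

    t: np.ndarray
    rel_freq: np.ndarray
    window_halfwidth_s: float
    baseline_freq_hz: float


# --------------------------------------------------------------------------
# beat detection
# --------------------------------------------------------------------------

def _parabolic_refine(v: np.ndarray, i: int, dt: float, t0: float) -> float:
    """Sub-sample peak location via a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(v) - 1:
        return t0 + i * dt
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the sample
        return t0 + i * dt
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return t0 + (i + delta) * dt


def detect_beats(trace: TimeSeries, min_ibi_s: float = 0.25,
                 prominence_frac: float = 5.0,
                 smooth_s: float = 0.075,
                 detrend_window_s: float = 1.0,
                 refine: bool = True,
                 trial_id: Optional[str] = None) -> BeatSeries:
    """Detect heartbeat peaks on a luminosity trace.

    The trace is lightly smoothed (boxcar, ``smooth_s``), detrended by a
    rolling median (``detrend_window_s``), and peaks are kept if separated by
    at least ``min_ibi_s`` with both height and prominence of at least
    ``prominence_frac`` robust-sigma units (1.4826 x median absolute
    deviation of the detrended trace). The joint height+prominence floor
    suppresses spurious noise peaks during long beat-free (arrest) stretches.
    Peak times are refined to sub-frame resolution by parabolic
    interpolation. A flat trace yields an empty series.
    """
    if min_ibi_s <= 0:
        raise ValueError("min_ibi_s must be positive")
    if trace.duration < 2.0:
        raise ValueError("trace must span at least 2 s")
    dt = trace.dt
    v = trace.v.astype(float)

    nsm = max(1, int(round(smooth_s / dt)))
    if nsm > 1:
        v = uniform_filter1d(v, size=nsm, mode="nearest")
    ndet = max(3, int(round(detrend_window_s / dt)) | 1)  # odd
    v = v - median_filter(v, size=ndet, mode="nearest")

    mad = float(np.median(np.abs(v - np.median(v))))
    # MAD can be exactly 0 on noiseless pulse trains (majority of detrended
    # samples are 0); fall back to a small fraction of the dynamic range
    robust_sigma = max(1.4826 * mad, float(np.ptp(v)) / 100.0)
    if robust_sigma <= 0:
        return BeatSeries(np.array([]), trial_id, float(trace.t[0]), float(trace.t[-1]))
    prominence = prominence_frac * robust_sigma

    idx, _ = find_peaks(v, distance=max(1, int(round(min_ibi_s / dt))),
                        prominence=prominence, height=prominence)
    if refine:
        times = np.array([_parabolic_refine(v, int(i), dt, float(trace.t[0]))
                          for i in idx])
    else:
        times = trace.t[idx]
    return BeatSeries(times, trial_id, float(trace.t[0]), float(trace.t[-1]))


# --------------------------------------------------------------------------
# relative frequency
# --------------------------------------------------------------------------

def relative_hb_frequency(beats: BeatSeries,
                          baseline_window: tuple[float, float],
                          window_halfwidth_s: float = 0.5,
                          dt_s: Optional[float] = None) -> FrequencyTrace:
    """Sliding-window beat-count frequency relative to a baseline window.

    Raw frequency at t is the count of beats in the closed window
    [t-h, t+h] divided by 2h; the trace is normalized by the mean raw
    frequency over the (pre-stimulus) baseline window. Samples whose window
    extends beyond the record are NaN.
    """
    lo, hi = baseline_window
    if hi <= lo:
        raise ValueError("baseline window must be non-empty")
    bt = beats.beat_times_s
    n_base = np.searchsorted(bt, hi, "right") - np.searchsorted(bt, lo, "left")
    if n_base < 2:
        raise ValueError("baseline window must contain at least 2 beats")
    if dt_s is None:
        dt_s = 1.0 / 67.0
    h = window_halfwidth_s
    t = np.arange(beats.t_start, beats.t_end + dt_s / 2, dt_s)

    def _raw(tt: np.ndarray) -> np.ndarray:
        c = (np.searchsorted(bt, tt + h, "right")
             - np.searchsorted(bt, tt - h, "left"))
        return c / (2.0 * h)

    raw = _raw(t).astype(float)
    out_of_record = (t - h < beats.t_start - 1e-12) | (t + h > beats.t_end + 1e-12)
    raw[out_of_record] = np.nan

    in_base = (t >= lo) & (t <= hi) & ~out_of_record
    if not in_base.any():
        raise ValueError("baseline window contains no valid frequency samples")
    base = float(np.nanmean(raw[in_base]))
    if base <= 0:
        raise ValueError("baseline frequency is zero")
    return FrequencyTrace(t, raw / base, h, base)


# --------------------------------------------------------------------------
# arrest metrics
# --------------------------------------------------------------------------

def detect_arrest(beats: BeatSeries, stim: LightSchedule,
                  baseline_ibi_s: Optional[float] = None,
                  gap_factor: float = 2.0,
                  search_window_s: float = 8.0) -> ArrestResult:
    """Cardiac-arrest metrics from a beat series.

    Arrest onset is the last beat preceding the first post-stimulus
    inter-beat gap exceeding ``gap_factor`` x baseline IBI, plus one baseline
    IBI (the first missed expected beat). Latency is onset minus stimulation
    onset; resumption is the next beat minus onset. The trial counts as
    arrested only if the onset falls within ``search_window_s`` of the
    stimulus. The baseline IBI defaults to the median pre-stimulus IBI.
    """
    if not stim.segments:
        raise ValueError("stimulus schedule is empty")
    onset_stim = stim.segments[0].start_s
    bt = beats.beat_times_s
    if not (beats.t_start <= onset_stim <= beats.t_end):
        raise ValueError("stimulus onset outside the record")
    pre = bt[bt < onset_stim]
    if baseline_ibi_s is None:
        if len(pre) < 2:
            raise ValueError("need >= 2 pre-stimulus beats for a baseline IBI")
        baseline_ibi_s = float(np.median(np.diff(pre)))
    if len(pre) == 0:
        raise ValueError("no pre-stimulus beats")

    edges = np.concatenate([bt, [beats.t_end]])
    for i in range(len(bt)):
        gap = edges[i + 1] - edges[i]
        if edges[i + 1] <= onset_stim:
            continue
        if gap > gap_factor * baseline_ibi_s:
            arrest_onset = edges[i] + baseline_ibi_s
            if arrest_onset > onset_stim + search_window_s:
                break
            latency = arrest_onset - onset_stim
            if i + 1 < len(bt):
                resumption = float(bt[i + 1] - arrest_onset)
            else:
                resumption = None  # record ended while still arrested
            return ArrestResult(True, float(latency), resumption, resumption)
    return ArrestResult(False)


def arrest_time_ratio(trials: Sequence[ArrestResult]) -> list[float]:
    """Each trial's arrest duration as a ratio to trial 1's.

    Non-arrested trials contribute duration 0. Trial 1 must be arrested with
    a positive duration.
    """
    if not trials:
        raise ValueError("no trials given")
    first = trials[0]
    if not first.arrested or not first.arrest_duration_s:
        raise ValueError("trial 1 must be arrested with positive arrest duration")
    d1 = first.arrest_duration_s
    out = []
    for tr in trials:
        d = tr.arrest_duration_s if (tr.arrested and tr.arrest_duration_s) else 0.0
        out.append(d / d1)
    return out


# --------------------------------------------------------------------------
# AV conduction delay
# --------------------------------------------------------------------------

def av_delay(atrial: BeatSeries, ventricular: BeatSeries,
             max_delay_s: float = 0.5) -> AvDelaySeries:
    """Match each atrial peak to the earliest ventricular peak strictly after
    it and before the next atrial peak; exclude pairs with delay above
    ``max_delay_s`` (counted in ``n_excluded``). Matching is one-to-one and
    non-crossing by construction.
    """
    if len(atrial) == 0 or len(ventricular) == 0:
        raise ValueError("both beat series must be nonempty")
    a = atrial.beat_times_s
    v = ventricular.beat_times_s
    kept_a, kept_v, kept_d = [], [], []
    n_excl = 0
    for i, ta in enumerate(a):
        upper = a[i + 1] if i + 1 < len(a) else np.inf
        j = np.searchsorted(v, ta, "right")
        if j >= len(v) or v[j] >= upper:
            continue  # unmatched atrial peak
        d = float(v[j] - ta)
        if d > max_delay_s:
            n_excl += 1
            continue
        kept_a.append(float(ta))
        kept_v.append(float(v[j]))
        kept_d.append(d)
    return AvDelaySeries(np.array(kept_a), np.array(kept_v), np.array(kept_d),
                         n_excl, max_delay_s)


def cardiac_arrest_rate(results: Sequence[ArrestResult]) -> float:
    """Fraction of one larva's valid trials that showed cardiac arrest."""
    if len(results) == 0:
        raise ValueError("no valid trials")
    return sum(1 for r in results if r.arrested) / len(results)
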