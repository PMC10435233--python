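"""Tail-bout detection and trial-structured locomotion metrics.

Input is a pre-tracked lateral-displacement trace normalized by body length.
A bout is a maximal interval where the displacement envelope (rolling maximum
of |displacement| over 150 ms, so within-bout tail beats do not fragment it)
exceeds a threshold; nearby intervals are merged. Trials are then classified:
induced if the first post-stimulus bout starts within the induction window
(8 s), with latency, duration and strength (peak displacement) of that bout;
trials with pre-stimulus movement are flagged and excluded from rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy.ndimage import maximum_filter1d

from .core import TimeSeries

__all__ = [
    "BoutEvent",
    "LocomotionTrialResult",
    "detect_bouts",
    "classify_trial",
    "locomotion_rate",
    "inhibition_rate",
]


@dataclass(frozen=True)
class BoutEvent:
    """One tail-movement bout."""

    start_s: float
    end_s: float
    peak_displacement: float

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValueError("bout start must precede end")
        if self.peak_displacement < 0:
            raise ValueError("peak displacement must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class LocomotionTrialResult:
    """Classification of one stimulation trial."""

    pre_stimulus_active: bool
    induced: bool
    latency_s: Optional[float] = None
    duration_s: Optional[float] = None
    strength: Optional[float] = None

    def __post_init__(self):
        if self.strength is not None and self.strength < 0:
            raise ValueError("strength must be >= 0")


def detect_bouts(tail: TimeSeries, threshold: float = 0.05,
                 min_gap_s: float = 0.1, envelope_s: float = 0.15,
                 refine: bool = True, edge_frac: float = 0.5) -> list[BoutEvent]:
    """Detect movement bouts on a displacement trace.

    Bouts are maximal intervals where the rolling-maximum envelope of
    |displacement| exceeds ``threshold``; intervals separated by less than
    ``min_gap_s`` are merged. With ``refine``, bout edges are tightened to
    the first/last raw |displacement| crossing of ``edge_frac x threshold``
    inside each envelope interval (the centred rolling maximum widens
    intervals by up to half the envelope window on each side, and the
    oscillation ramps from zero, so the full-threshold crossing is
    systematically late).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dt = tail.dt
    absd = np.abs(tail.v)
    nenv = max(1, int(round(envelope_s / dt)))
    env = maximum_filter1d(absd, size=nenv, mode="nearest")
    above = env > threshold
    if not above.any():
        return []
    # maximal runs of True
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    # merge runs separated by < min_gap_s
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) * dt < min_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    bouts = []
    for s, e in merged:
        i0, i1 = s, e - 1
        if refine:
            raw = np.where(absd[s:e] > edge_frac * threshold)[0]
            if len(raw):
                i0, i1 = s + raw[0], s + raw[-1]
        peak = float(absd[s:e].max())
        t0, t1 = float(tail.t[i0]), float(tail.t[i1])
        if t1 <= t0:
            t1 = t0 + dt
        bouts.append(BoutEvent(t0, t1, peak))
    return bouts


def classify_trial(bouts: Sequence[BoutEvent], stim_onset_s: float,
                   induction_window_s: float = 8.0) -> LocomotionTrialResult:
    """Classify one trial from its bout list.

    Induced if the first bout starting at/after stimulation onset begins
    within ``induction_window_s`` of the onset; latency, duration and
    strength are taken from that bout. Any bout starting before onset flags
    the trial as pre-stimulus active (excluded from rates downstream).
    """
    pre = any(b.start_s < stim_onset_s for b in bouts)
    post = [b for b in bouts if b.start_s >= stim_onset_s]
    if not post:
        return LocomotionTrialResult(pre, False)
    first = min(post, key=lambda b: b.start_s)
    latency = first.start_s - stim_onset_s
    induced = latency <= induction_window_s
    return LocomotionTrialResult(pre, induced, latency, first.duration_s,
                                 first.peak_displacement)


def locomotion_rate(results: Sequence[LocomotionTrialResult]) -> float:
    """Percentage of induced trials among trials without pre-stimulus movement."""
    counted = [r for r in results if not r.pre_stimulus_active]
    if not counted:
        raise ValueError("all trials excluded (pre-stimulus movement)")
    return 100.0 * sum(1 for r in counted if r.induced) / len(counted)


def inhibition_rate(trials: Sequence[tuple[Sequence[BoutEvent], float]],
                    inhibition_window_s: float = 1.0) -> float:
    """Percentage of locomotion-inhibition trials.

    Each trial is (bouts, opsin-stimulation onset) and must have a bout
    ongoing at the onset (the white-light-evoked swim); it counts as an
    inhibition trial if that bout ends within ``inhibition_window_s`` after
    the onset. Trials without an ongoing bout are excluded with a warning.
    """
    n_inh = 0
    n_valid = 0
    for bouts, onset in trials:
        ongoing = [b for b in bouts if b.start_s <= onset <= b.end_s]
        if not ongoing:
            warnings.warn("trial without ongoing bout at stimulation onset excluded")
            continue
        n_valid += 1
        if min(b.end_s for b in ongoing) <= onset + inhibition_window_s:
            n_inh += 1
    if n_valid == 0:
        raise ValueError("no valid inhibition trials")
    return 100.0 * n_inh / n_valid
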