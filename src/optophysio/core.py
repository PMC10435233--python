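"""Shared data carriers for the pipeline.

Every signal in the package — heart-region luminosity, GCaMP fluorescence,
tail lateral displacement — travels as a uniformly sampled :class:`TimeSeries`.
Light stimulation protocols are :class:`LightSchedule` objects (piecewise
constant wavelength/irradiance), and each simulated or recorded stimulus
application to one larva is a :class:`Trial`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "LightSegment",
    "LightSchedule",
    "GroundTruth",
    "Trial",
]

#: relative tolerance for declaring sample spacing uniform
_UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing, uniformly spaced.
    v : ndarray
        Sample values (arbitrary units).
    """

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("t and v must be 1-D")
        if len(t) != len(v):
            raise ValueError(f"length mismatch: len(t)={len(t)} len(v)={len(v)}")
        if len(t) == 0:
            raise ValueError("empty time series")
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            step = dt[0]
            if np.any(np.abs(dt - step) > _UNIFORM_RTOL * max(abs(step), 1.0)):
                raise ValueError("sampling must be uniform")

    @classmethod
    def from_fps(cls, v: Sequence[float], fps: float, t0: float = 0.0) -> "TimeSeries":
        v = np.asarray(v, dtype=float)
        if fps <= 0:
            raise ValueError("fps must be positive")
        t = t0 + np.arange(len(v)) / float(fps)
        return cls(t, v)

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise ValueError("dt undefined for a single-sample series")
        return float(self.t[1] - self.t[0])

    @property
    def fps(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class LightSegment:
    """One constant-illumination interval of a light schedule."""

    start_s: float
    end_s: float
    wavelength_nm: float
    irradiance_mW_per_mm2: float

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValueError(f"segment start {self.start_s} must precede end {self.end_s}")
        if not (350.0 <= self.wavelength_nm <= 700.0):
            raise ValueError(f"wavelength {self.wavelength_nm} nm outside [350, 700]")
        if self.irradiance_mW_per_mm2 < 0:
            raise ValueError("irradiance must be >= 0")


@dataclass(frozen=True)
class LightSchedule:
    """Ordered, non-overlapping illumination segments; darkness elsewhere."""

    segments: tuple[LightSegment, ...] = ()

    def __post_init__(self):
        segs = tuple(
            s if isinstance(s, LightSegment) else LightSegment(*s) for s in self.segments
        )
        segs = tuple(sorted(segs, key=lambda s: s.start_s))
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s - 1e-12:
                raise ValueError(f"segments overlap: {a} and {b}")
        object.__setattr__(self, "segments", segs)

    @property
    def end_s(self) -> float:
        return max((s.end_s for s in self.segments), default=0.0)

    def breakpoints(self) -> np.ndarray:
        pts = {s.start_s for s in self.segments} | {s.end_s for s in self.segments}
        return np.array(sorted(pts))

    def at(self, t: float) -> Optional[LightSegment]:
        """Segment active at time ``t`` (start inclusive, end exclusive)."""
        for s in self.segments:
            if s.start_s <= t < s.end_s:
                return s
        return None


@dataclass
class GroundTruth:
    """Planted parameters of one simulated trial, for parameter-recovery tests.

    Only the fields relevant to the simulated modality are populated; the
    seed is always recorded.
    """

    seed: int
    # cardiac
    beat_times_s: Optional[np.ndarray] = None
    ventricular_beat_times_s: Optional[np.ndarray] = None
    av_delay_s: Optional[float] = None
    arrested: Optional[bool] = None
    arrest_onset_s: Optional[float] = None
    latency_to_arrest_s: Optional[float] = None
    time_to_resumption_s: Optional[float] = None
    arrest_duration_s: Optional[float] = None
    rate_profile: Optional["TimeSeries"] = None
    # tail
    bout_onsets_s: Optional[np.ndarray] = None
    bout_durations_s: Optional[np.ndarray] = None
    bout_amplitudes: Optional[np.ndarray] = None
    pre_stimulus_active: Optional[bool] = None
    stim_onset_s: Optional[float] = None
    # calcium
    baseline_F: Optional[float] = None
    beat_coupling: Optional[float] = None
    extra: dict = field(default_factory=dict)


@dataclass
class Trial:
    """One stimulus application to one larva: signals + stimulus + identity."""

    larva_id: str
    trial_index: int
    tool: str
    stim: LightSchedule
    signals: dict[str, TimeSeries] = field(default_factory=dict)
    truth: Optional[GroundTruth] = None

    @property
    def stim_onset_s(self) -> float:
        if not self.stim.segments:
            raise ValueError("trial has no stimulus segments")
        return self.stim.segments[0].start_s
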