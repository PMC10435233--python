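"""ROI luminosity extraction, dF/F normalization, and heart-area dynamics.

Frame stacks are plain ``(n, h, w)`` arrays wrapped with a frame rate; ROIs
are binary masks (optionally built from polygons). Fluorescence traces are
normalized to dF/F = (F - F0)/F0 under one of three baseline conventions
matching the assay variants: the sample at stimulation onset, a pre-stimulus
window mean, or a user-marked post-resumption steady-state window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.draw import polygon as _sk_polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label

from .core import LightSchedule, TimeSeries

__all__ = [
    "FrameStack",
    "Roi",
    "DffTrace",
    "extract_roi_luminosity",
    "compute_dff",
    "measure_heart_area",
]

BASELINE_CONVENTIONS = ("stim_onset", "pre_stimulus", "steady_state")


@dataclass(frozen=True)
class FrameStack:
    """Grayscale frame stack sampled at a fixed rate; frames timestamped at
    frame start, time origin at the first frame."""

    frames: np.ndarray  # (n, h, w)
    fps: float

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if f.shape[0] == 0:
            raise ValueError("frame stack is empty")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "frames", f)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) / self.fps

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class Roi:
    """Binary region-of-interest mask with a label."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any():
            raise ValueError("empty ROI rejected")
        object.__setattr__(self, "mask", m)

    @classmethod
    def from_polygon(cls, vertices_rc: np.ndarray, shape: tuple[int, int],
                     label: str = "roi") -> "Roi":
        """Rasterize a polygon given as (row, col) vertices."""
        v = np.asarray(vertices_rc, dtype=float)
        rr, cc = _sk_polygon(v[:, 0], v[:, 1], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return cls(mask, label)


@dataclass(frozen=True)
class DffTrace:
    """dF/F trace with the baseline convention and F0 that produced it."""

    t: np.ndarray
    dff: np.ndarray
    baseline_convention: str
    F0: float

    def __post_init__(self):
        if self.F0 <= 0:
            raise ValueError("F0 must be positive")
        if self.baseline_convention not in BASELINE_CONVENTIONS:
            raise ValueError(f"unknown convention {self.baseline_convention!r}")

    def as_timeseries(self) -> TimeSeries:
        return TimeSeries(self.t, self.dff)


def extract_roi_luminosity(stack: FrameStack, roi: Roi) -> TimeSeries:
    """Mean pixel intensity inside the ROI, per frame."""
    if roi.mask.shape != stack.frames.shape[1:]:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match frames {stack.frames.shape[1:]}")
    v = stack.frames[:, roi.mask].mean(axis=1)
    return TimeSeries(stack.times, v)


def compute_dff(F: TimeSeries, convention: str,
                stim: Optional[LightSchedule] = None,
                baseline_window_s: float = 2.0,
                steady_window: Optional[tuple[float, float]] = None) -> DffTrace:
    """Normalize a fluorescence trace to dF/F = (F - F0)/F0.

    ``stim_onset``: F0 is the sample at stimulation onset (requires ``stim``).
    ``pre_stimulus``: F0 is the mean over ``baseline_window_s`` immediately
    before stimulation onset. ``steady_state``: F0 is the mean over the
    user-marked ``steady_window`` (e.g. after heartbeat resumption).
    """
    if convention not in BASELINE_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if convention == "steady_state":
        if steady_window is None:
            raise ValueError("steady_state convention requires steady_window")
        lo, hi = steady_window
        sel = (F.t >= lo) & (F.t <= hi)
        if not sel.any():
            raise ValueError("steady_window contains no samples")
        F0 = float(F.v[sel].mean())
    else:
        if stim is None or not stim.segments:
            raise ValueError(f"{convention} convention requires a stimulus schedule")
        onset = stim.segments[0].start_s
        if convention == "stim_onset":
            idx = int(np.argmin(np.abs(F.t - onset)))
            F0 = float(F.v[idx])
        else:  # pre_stimulus
            sel = (F.t >= onset - baseline_window_s) & (F.t < onset)
            if not sel.any():
                raise ValueError("no samples in pre-stimulus baseline window")
            F0 = float(F.v[sel].mean())
    if F0 <= 0:
        raise ValueError(f"baseline F0 = {F0} must be positive")
    return DffTrace(F.t.copy(), (F.v - F0) / F0, convention, F0)


def measure_heart_area(stack: FrameStack, t0_arrest_s: float,
                       threshold_method: str = "otsu",
                       smooth_frames: int = 3) -> TimeSeries:
    """Heart area per frame as a ratio to the area at arrest onset (t0).

    Frames are smoothed temporally (moving average over ``smooth_frames``),
    thresholded with a global Otsu level computed on the frame nearest t0,
    and the largest connected foreground component is counted.
    """
    if threshold_method != "otsu":
        raise ValueError(f"unsupported threshold_method {threshold_method!r}")
    times = stack.times
    if not (times[0] <= t0_arrest_s <= times[-1]):
        raise ValueError("t0_arrest_s outside the record")
    f = stack.frames.astype(float)
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        pad = smooth_frames // 2
        fp = np.pad(f, ((pad, smooth_frames - 1 - pad), (0, 0), (0, 0)), mode="edge")
        f = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="valid"),
                                0, fp)
    i0 = int(np.argmin(np.abs(times - t0_arrest_s)))
    thr = threshold_otsu(f[i0])

    def _largest_component_area(frame: np.ndarray) -> int:
        lab = _sk_label(frame > thr)
        if lab.max() == 0:
            return 0
        return int(np.bincount(lab.ravel())[1:].max())

    areas = np.array([_largest_component_area(fr) for fr in f], dtype=float)
    if areas[i0] == 0:
        raise ValueError("zero segmented area at t0; cannot form ratio")
    return TimeSeries(times, areas / areas[i0])
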