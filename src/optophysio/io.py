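"""File formats, run configuration and provenance.

Traces travel as two-column CSV (``time_s,value``; comma, UTF-8, '.'
decimal, mandatory header, optional ``#`` metadata comment lines). Frame
stacks are multi-page grayscale TIFF with the frame rate in a JSON sidecar
or supplied by the caller. Run configuration is a flat-sectioned mapping
validated against the package defaults (unknown keys rejected); every
pipeline output carries the SHA-256 hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import TimeSeries
from .extraction import FrameStack

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_tiff_stack",
    "write_tiff_stack",
    "default_config",
    "load_config",
    "resolve_config",
    "config_hash",
    "load_trial_ledger",
]

_UNIFORM_RTOL = 1e-9


# --------------------------------------------------------------------------
# trace CSV
# --------------------------------------------------------------------------

def read_trace_csv(path: str | Path) -> TimeSeries:
    """Read a two-column (time_s, value) CSV into a TimeSeries.

    Lines starting with ``#`` are metadata comments. Malformed numeric rows
    and non-uniform or non-monotone sampling are rejected with the offending
    line reported.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    tcol, vcol = df.columns[0], df.columns[1]
    for col in (tcol, vcol):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced
    if df[tcol].isna().any() or df[vcol].isna().any():
        line = int(df[[tcol, vcol]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path}: missing value at line {line}")
    t = df[tcol].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            line = int(np.argmax(dt <= 0)) + 3
            raise ValueError(f"{path}: time not strictly increasing at line {line}")
        if np.any(np.abs(dt - dt[0]) > _UNIFORM_RTOL * max(abs(dt[0]), 1.0)):
            line = int(np.argmax(np.abs(dt - dt[0]) > _UNIFORM_RTOL * max(abs(dt[0]), 1.0))) + 3
            raise ValueError(f"{path}: non-uniform sampling near line {line}")
    return TimeSeries(t, df[vcol].to_numpy(dtype=float))


def write_trace_csv(ts: TimeSeries, path: str | Path,
                    meta: Optional[dict[str, Any]] = None,
                    value_name: str = "value") -> Path:
    """Write a TimeSeries as CSV, with optional ``# key: value`` header lines.

    Times are written with enough digits to round-trip losslessly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"time_s,{value_name}\n")
        for t, v in zip(ts.t, ts.v):
            fh.write(f"{t:.17g},{v:.17g}\n")
    return path


# --------------------------------------------------------------------------
# TIFF stacks
# --------------------------------------------------------------------------

def write_tiff_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a frame stack as multi-page grayscale TIFF + JSON fps sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32),
                     photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"fps": stack.fps}))
    return path


def read_tiff_stack(path: str | Path, fps: Optional[float] = None,
                    rgb_policy: str = "convert") -> FrameStack:
    """Read a multi-page grayscale TIFF into a FrameStack.

    ``fps`` is taken from the argument or from a ``.meta.json`` sidecar;
    missing in both places is an error. RGB input is averaged to grayscale
    with a warning (``rgb_policy='convert'``) or rejected
    (``rgb_policy='reject'``).
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        if rgb_policy == "reject":
            raise ValueError(f"{path}: RGB input rejected by configuration")
        warnings.warn(f"{path}: RGB input converted to grayscale by channel mean")
        frames = frames[..., :3].mean(axis=-1)
    if frames.ndim != 3:
        raise ValueError(f"{path}: unsupported TIFF shape {frames.shape}")
    if fps is None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            fps = float(json.loads(sidecar.read_text())["fps"])
        else:
            raise ValueError(f"{path}: fps not given and no metadata sidecar found")
    return FrameStack(frames, fps)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

def default_config() -> dict[str, Any]:
    """Package defaults for a full simulate-and-analyze run."""
    return {
        "seed": 1,
        "simulate": {
            "kind": "heart",          # heart | locomotion
            "opsin": "mosopn3",       # mosopn3 | puftmt | lampp
            "n_larvae": 4,
            "n_trials": 6,
            "duration_s": 25.0,
            "stim_onset_s": 5.0,
            "irradiance": 0.5,
            "reversal": False,
            "noise_sd": 0.05,
            "fps": 67.0,
        },
        "cardiac": {
            "min_ibi_s": 0.25,
            "prominence_frac": 5.0,
            "window_halfwidth_s": 0.5,
            "baseline_window_s": 5.0,
            "gap_factor": 2.0,
            "search_window_s": 8.0,
            "max_av_delay_s": 0.5,
        },
        "locomotion": {
            "threshold": 0.05,
            "min_gap_s": 0.1,
            "envelope_s": 0.15,
            "induction_window_s": 8.0,
            "inhibition_window_s": 1.0,
        },
        "dff": {
            "convention": "stim_onset",
            "baseline_window_s": 2.0,
        },
    }


def _merge_validate(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            sub = override.get(key, {})
            if not isinstance(sub, dict):
                raise ValueError(f"config section {path}{key} must be a mapping")
            out[key] = _merge_validate(dval, sub, f"{path}{key}.")
        else:
            out[key] = override.get(key, dval)
    unknown = set(override) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(path + k for k in unknown)}")
    return out


def resolve_config(override: Optional[dict] = None) -> dict[str, Any]:
    """Merge a user mapping over the defaults, rejecting unknown keys."""
    return _merge_validate(default_config(), override or {})


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config file and resolve it against the defaults."""
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return resolve_config(user)


def config_hash(config: dict[str, Any]) -> str:
    """Short SHA-256 hash of the canonical JSON form of a resolved config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_trial_ledger(path: str | Path) -> pd.DataFrame:
    """Load a trial-metadata ledger; (larva_id, trial_index) must be unique
    and any referenced trace files must exist."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"larva_id", "trial_index"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: ledger must contain columns {sorted(required)}")
    dup = df.duplicated(subset=["larva_id", "trial_index"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (larva_id, trial_index) keys")
    for col in df.columns:
        if col.endswith("_path"):
            for p in df[col].dropna():
                if not (path.parent / p).exists() and not Path(p).exists():
                    raise ValueError(f"{path}: referenced file {p} does not exist")
    return df
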