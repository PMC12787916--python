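"""Force-trace preprocessing: low-pass filtering and windowed MVC extraction.

The platform samples ground reaction force at 1.4 kHz.  Voluntary muscle
force lives well below 10 Hz; tremor, balance shifts and electrical
artifacts live above it.  Preprocessing therefore applies a zero-phase
Butterworth low-pass at 15 Hz, and the strength score is not the single
highest sample but the highest mean over any continuous 1.5 s segment —
a sliding-window maximum-mean that rewards sustained effort and is
robust to momentary spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ForceTrace",
    "PreprocessConfig",
    "MvcResult",
    "PreprocessError",
    "lowpass_filter",
    "lowpass_channel",
    "sliding_window_mvc",
    "best_of_trials",
    "read_force_csv",
    "write_force_csv",
]

AXES = ("fx", "fy", "fz")


class PreprocessError(ValueError):
    """Invalid trace or preprocessing configuration."""


@dataclass
class ForceTrace:
    """Uniformly sampled triaxial force series in newtons.

    fx is mediolateral, fy anteroposterior, fz vertical — the axes a
    force platform reports for a standing subject.
    """

    fs: float
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise PreprocessError(f"fs must be > 0, got {self.fs}")
        for axis in AXES:
            arr = np.asarray(getattr(self, axis), dtype=float)
            setattr(self, axis, arr)
            if arr.ndim != 1:
                raise PreprocessError(f"channel {axis} must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise PreprocessError(f"channel {axis} contains non-finite values")
        if not (len(self.fx) == len(self.fy) == len(self.fz)):
            raise PreprocessError("channels must have equal length")
        if len(self.fx) < 1:
            raise PreprocessError("trace must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return len(self.fx)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, axis: str) -> np.ndarray:
        if axis not in AXES:
            raise PreprocessError(f"unknown axis {axis!r}, expected one of {AXES}")
        return getattr(self, axis)


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter and window settings.

    cutoff : Hz
        Low-pass corner; 15 Hz keeps voluntary force content and rejects
        tremor and line artifacts.
    filter_order : int
        Butterworth order of the one-way design.  Applied zero-phase
        (forward-backward), the effective magnitude response is squared.
    window : s
        Sliding-window length; 1.5 s is the minimum sustained-effort
        duration the protocol demands.
    window_step : samples
        Placement stride; 1 evaluates every continuous segment.
    """

    cutoff: float = 15.0
    filter_order: int = 4
    window: float = 1.5
    window_step: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise PreprocessError(f"cutoff must be > 0, got {self.cutoff}")
        if self.filter_order < 1:
            raise PreprocessError(f"filter_order must be >= 1, got {self.filter_order}")
        if self.window <= 0:
            raise PreprocessError(f"window must be > 0, got {self.window}")
        if self.window_step < 1:
            raise PreprocessError(f"window_step must be >= 1, got {self.window_step}")


@dataclass(frozen=True)
class MvcResult:
    """Maximal voluntary contraction score: the highest windowed mean."""

    mvc: float  # newtons
    window_start: float  # seconds from trace start
    window_len: float  # seconds
    channel: str = ""


def _butter_sos(fs: float, cfg: PreprocessConfig):
    if cfg.cutoff >= fs / 2:
        raise PreprocessError(
            f"cutoff {cfg.cutoff} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    return signal.butter(cfg.filter_order, cfg.cutoff, btype="low", fs=fs, output="sos")


def lowpass_channel(x: np.ndarray, fs: float, cfg: PreprocessConfig) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a single channel."""
    x = np.asarray(x, dtype=float)
    sos = _butter_sos(fs, cfg)
    # sosfiltfilt pads by 3 * (n_sections * 2 + 1) samples on each side
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= padlen:
        raise PreprocessError(
            f"trace of {len(x)} samples is too short for zero-phase filtering "
            f"(needs > {padlen})"
        )
    return signal.sosfiltfilt(sos, x)


def lowpass_filter(trace: ForceTrace, cfg: PreprocessConfig) -> ForceTrace:
    """Zero-phase Butterworth low-pass applied to all three channels.

    Forward-backward filtering cancels phase delay, so the timing of the
    best window is not shifted; constant (DC) signals pass unchanged.
    """
    return ForceTrace(
        fs=trace.fs,
        fx=lowpass_channel(trace.fx, trace.fs, cfg),
        fy=lowpass_channel(trace.fy, trace.fs, cfg),
        fz=lowpass_channel(trace.fz, trace.fs, cfg),
    )


def sliding_window_mvc(
    trace_channel: Sequence[float],
    fs: float,
    cfg: PreprocessConfig | None = None,
    channel: str = "",
) -> MvcResult:
    """Highest mean force over any continuous window of ``cfg.window`` seconds.

    Windows are placed every ``cfg.window_step`` samples; the earliest
    window wins ties, so the result is deterministic.  Raises if the
    trace is shorter than one window — the protocol requires the effort
    to be sustained for at least the window length.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(trace_channel, dtype=float)
    win = int(round(cfg.window * fs))
    if win < 1:
        raise PreprocessError(f"window of {cfg.window} s is shorter than one sample at {fs} Hz")
    if len(x) < win:
        raise PreprocessError(
            f"trace of {len(x)} samples is shorter than the {win}-sample window"
        )
    # windowed means via a prefix sum: O(n), exact enough vs brute force
    cs = np.concatenate(([0.0], np.cumsum(x)))
    means = (cs[win:] - cs[:-win]) / win
    means = means[:: cfg.window_step]
    best = int(np.argmax(means))  # argmax returns the first maximum
    start_idx = best * cfg.window_step
    return MvcResult(
        mvc=float(means[best]),
        window_start=start_idx / fs,
        window_len=win / fs,
        channel=channel,
    )


def best_of_trials(mvc_values: Sequence[float]) -> float:
    """Definitive strength output of a direction: the maximum over its trials."""
    vals = list(mvc_values)
    if not vals:
        raise PreprocessError("best_of_trials needs at least one MVC value")
    return float(max(vals))


def write_force_csv(trace: ForceTrace, path: str | Path) -> None:
    """Write a trace as ``time_s,fx_n,fy_n,fz_n`` CSV."""
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "fx_n": trace.fx,
            "fy_n": trace.fy,
            "fz_n": trace.fz,
        }
    )
    # 9 decimals so the written time base stays uniform within the 1e-6 s
    # jitter the reader enforces
    df.to_csv(path, index=False, float_format="%.9f")


def read_force_csv(path: str | Path, jitter_tol: float = 1e-6) -> ForceTrace:
    """Read a ``time_s,fx_n,fy_n,fz_n`` CSV, validating uniform sampling."""
    df = pd.read_csv(path)
    required = {"time_s", "fx_n", "fy_n", "fz_n"}
    if not required.issubset(df.columns):
        raise PreprocessError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise PreprocessError(f"{path}: need at least 2 samples to infer the rate")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > jitter_tol):
        raise PreprocessError(f"{path}: sampling is not uniform within {jitter_tol} s")
    return ForceTrace(
        fs=1.0 / dt[0],
        fx=df["fx_n"].to_numpy(dtype=float),
        fy=df["fy_n"].to_numpy(dtype=float),
        fz=df["fz_n"].to_numpy(dtype=float),
    )
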