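"""Uniform signal reconstruction and analysis windowing.

The metabolic biomarkers are sampled once per minute; wavelet analysis needs
an evenly sampled signal.  Discrete samples are interpolated with a piecewise
cubic spline onto a uniform grid (no extrapolation beyond the knot span).
Recordings are split into named half-open analysis windows, e.g. a 10 min
baseline followed by 10 min of phenylephrine iontophoresis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import decimate

__all__ = ["IrregularSeries", "UniformSeries", "spline_reconstruct", "segment", "decimate_series"]


@dataclass(frozen=True)
class IrregularSeries:
    """Discrete samples at strictly increasing times (seconds)."""

    t_seconds: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t_seconds, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t_seconds", t)
        object.__setattr__(self, "values", v)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")


@dataclass(frozen=True)
class UniformSeries:
    """Evenly sampled signal with named half-open analysis windows.

    ``windows`` maps window name to (start_s, end_s); intervals are
    half-open [start, end), non-overlapping, and inside the series extent.
    """

    fs_hz: float
    t0_seconds: float
    values: np.ndarray
    label: str = ""
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        _check_windows(self.windows, self.t0_seconds, self.end_seconds)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0_seconds + np.arange(self.n) / self.fs_hz

    @property
    def end_seconds(self) -> float:
        """Time just past the last sample (extent end)."""
        return self.t0_seconds + self.n / self.fs_hz

    def window_mask(self, name: str) -> np.ndarray:
        lo, hi = self.windows[name]
        t = self.times
        return (t >= lo) & (t < hi)


def _check_windows(
    windows: dict[str, tuple[float, float]], t_lo: float, t_hi: float
) -> None:
    spans = sorted(windows.values())
    for lo, hi in spans:
        if not (lo < hi):
            raise ValueError(f"window [{lo}, {hi}) is empty or inverted")
        if lo < t_lo - 1e-9 or hi > t_hi + 1e-9:
            raise ValueError(
                f"window [{lo}, {hi}) outside series extent [{t_lo}, {t_hi})"
            )
    for (_, hi1), (lo2, _) in zip(spans, spans[1:]):
        if lo2 < hi1 - 1e-9:
            raise ValueError("windows overlap")


def spline_reconstruct(
    series: IrregularSeries, fs_hz: float, bc_type: str = "not-a-knot"
) -> UniformSeries:
    """Interpolate discrete samples onto a uniform grid with a cubic spline.

    Output samples lie at t0 + k/fs_hz for k = 0..floor((t_max-t_min)*fs);
    the interpolant passes through every knot exactly and is never evaluated
    outside the knot span.  ``bc_type`` is 'not-a-knot' (default, better end
    behaviour for short series) or 'natural'.
    """
    if series.t_seconds.size < 4:
        raise ValueError("cubic reconstruction needs at least 4 knots")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    spline = CubicSpline(series.t_seconds, series.values, bc_type=bc_type)
    t0, t_max = float(series.t_seconds[0]), float(series.t_seconds[-1])
    n = int(np.floor((t_max - t0) * fs_hz + 1e-9)) + 1
    t_out = t0 + np.arange(n) / fs_hz
    # guard against floating-point extrapolation past the last knot
    t_out = np.minimum(t_out, t_max)
    return UniformSeries(fs_hz=fs_hz, t0_seconds=t0, values=spline(t_out), label=series.label)


def segment(series: UniformSeries, windows: dict[str, tuple[float, float]]) -> UniformSeries:
    """Attach named half-open windows to a series without touching samples."""
    _check_windows(windows, series.t0_seconds, series.end_seconds)
    return replace(series, windows=dict(windows))


def decimate_series(series: UniformSeries, factor: int) -> UniformSeries:
    """Anti-aliased integer-factor downsampling (zero-phase IIR).

    Used to bring a 20 Hz blood-flow recording down to a rate matching the
    reconstructed metabolic signal before phase-coherence analysis; all
    analysed vasomotion bands lie well below the decimated Nyquist.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return series
    # large factors are decimated in stages to keep the IIR filter stable
    out = series.values
    remaining = int(factor)
    while remaining > 1:
        step = remaining
        while step > 10:
            for q in (10, 8, 5, 4, 2):
                if remaining % q == 0:
                    step = q
                    break
            else:
                step = remaining  # prime > 10: single stage, accepted
            break
        out = decimate(out, step, ftype="iir", zero_phase=True)
        remaining //= step
    return replace(series, values=out, fs_hz=series.fs_hz / factor)
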