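"""Morlet continuous wavelet transform on a logarithmic frequency grid.

The transform of a signal g is

    W(s, t) = s^{-1/2} \\int psi((u - t)/s) g(u) du,

with the Morlet mother wavelet psi(u) = pi^{-1/4} exp(i 2 pi f0 u) exp(-u^2/2)
and central frequency f0 (cyclic convention: the frequency attributed to
scale s is f = f0 / s; default f0 = 1).  The integral is evaluated by FFT
convolution against the analytic Fourier transform of the scaled wavelet,
which matches direct quadrature of the integral away from the record edges.

Edge effects are tracked with a cone of influence: a coefficient at (f, t)
is trusted only when t lies at least c_e * s from both record edges, with
c_e = sqrt(2) (the e-folding distance of the Morlet envelope's energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reconstruct import UniformSeries

__all__ = [
    "WaveletParams",
    "Scalogram",
    "TimeAveragedSpectrum",
    "log_frequency_grid",
    "morlet_cwt",
    "compute_coi",
    "time_average",
]

_MORLET_NORM = np.pi ** -0.25


@dataclass(frozen=True)
class WaveletParams:
    """Frequency grid and Morlet parameters for the transform.

    ``voices_per_octave`` controls grid density (>= 4); the analysed range
    is [f_min_hz, f_max_hz] with f_max below the signal's Nyquist frequency.
    ``central_frequency`` is the Morlet centre frequency in cycles; scale s
    maps to frequency f = central_frequency / s.
    """

    f_min_hz: float
    f_max_hz: float
    voices_per_octave: int = 16
    central_frequency: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.f_min_hz < self.f_max_hz):
            raise ValueError("require 0 < f_min < f_max")
        if self.voices_per_octave < 4:
            raise ValueError("voices_per_octave must be >= 4")
        if self.central_frequency <= 0:
            raise ValueError("central_frequency must be positive")


def log_frequency_grid(params: WaveletParams) -> np.ndarray:
    """Ascending log-spaced frequencies covering [f_min, f_max]."""
    n_oct = np.log2(params.f_max_hz / params.f_min_hz)
    k = np.arange(int(np.ceil(n_oct * params.voices_per_octave)) + 1)
    freqs = params.f_min_hz * 2.0 ** (k / params.voices_per_octave)
    return freqs[freqs <= params.f_max_hz * (1 + 1e-12)]


@dataclass(frozen=True)
class Scalogram:
    """Complex wavelet coefficients over (frequency, time) with a COI mask.

    ``coi_mask[i, j]`` is True where the coefficient at (freqs_hz[i],
    times_s[j]) lies inside the cone of influence (trustworthy region).
    """

    freqs_hz: np.ndarray
    times_s: np.ndarray
    coeffs: np.ndarray
    coi_mask: np.ndarray
    central_frequency: float = 1.0
    source_label: str = ""
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coeffs.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValueError("coeffs shape must be (n_freqs, n_times)")
        if self.coi_mask.shape != self.coeffs.shape:
            raise ValueError("coi_mask shape must match coeffs")

    def window_interval(self, window) -> tuple[float, float]:
        """Resolve a window name or (lo, hi) pair against stored windows."""
        if isinstance(window, str):
            return self.windows[window]
        lo, hi = window
        return float(lo), float(hi)


@dataclass(frozen=True)
class TimeAveragedSpectrum:
    """Time-mean power |W|^2 and amplitude |W| per frequency over a window.

    Rows with no admissible (in-window, in-cone) times carry NaN means and
    are marked in ``unreliable`` rather than dropped.
    """

    freqs_hz: np.ndarray
    mean_power: np.ndarray
    mean_amplitude: np.ndarray
    unreliable: np.ndarray
    #: per-frequency fraction of in-window times inside the cone of
    #: influence (computed regardless of ``coi_only``)
    admissible_fraction: np.ndarray = None
    window_label: str = ""


def compute_coi(
    times_s: np.ndarray,
    freqs_hz: np.ndarray,
    central_frequency: float = 1.0,
    e_folding: float = np.sqrt(2.0),
    record_extent: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boolean (n_freqs, n_times) mask; True inside the cone of influence.

    A point is inside the cone iff its distance from both record edges is
    at least ``e_folding * s`` with s = central_frequency / f.  Lower
    frequencies therefore never exclude less time than higher ones, and for
    a record of duration T all frequencies below e_folding*central_frequency
    / (T/2) have no interior points at all.
    """
    times_s = np.asarray(times_s, dtype=float)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if record_extent is None:
        t_lo, t_hi = float(times_s[0]), float(times_s[-1])
    else:
        t_lo, t_hi = record_extent
    margin = e_folding * central_frequency / freqs_hz  # per-frequency, seconds
    dist_left = times_s[None, :] - t_lo
    dist_right = t_hi - times_s[None, :]
    return (dist_left >= margin[:, None]) & (dist_right >= margin[:, None])


def _kernel_fourier(omega: np.ndarray, scale, f0: float) -> np.ndarray:
    # continuous FT of x -> psi(-x/s): s * pi^{-1/4} sqrt(2 pi) exp(-(s w + w0)^2 / 2)
    w0 = 2.0 * np.pi * f0
    return scale * _MORLET_NORM * np.sqrt(2.0 * np.pi) * np.exp(-0.5 * (scale * omega + w0) ** 2)


def morlet_cwt(
    signal: UniformSeries,
    params: WaveletParams,
    e_folding: float = np.sqrt(2.0),
    demean: bool = True,
    _chunk: int = 32,
) -> Scalogram:
    """Morlet CWT of a uniformly sampled signal.

    The signal mean is removed before the transform (a DC offset would
    otherwise produce a spurious low-frequency ridge).  Zero padding extends
    the record beyond the effective support of the widest wavelet so the
    circular FFT convolution matches the open-line integral; the padded
    region only influences coefficients outside the cone of influence.
    """
    values = np.asarray(signal.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("signal contains non-finite samples")
    nyquist = signal.fs_hz / 2.0
    if params.f_max_hz > nyquist:
        raise ValueError(f"f_max {params.f_max_hz} Hz exceeds Nyquist {nyquist} Hz")

    freqs = log_frequency_grid(params)
    scales = params.central_frequency / freqs
    n = values.size
    dt = 1.0 / signal.fs_hz
    if demean:
        values = values - values.mean()
    # trapezoid quadrature convention for the open-line integral: the two
    # record-edge samples carry half weight (visible only outside the cone)
    values = values.copy()
    values[0] *= 0.5
    values[-1] *= 0.5

    # pad past the widest kernel's support (6 s ~ envelope 1.5e-8 of peak)
    support = int(np.ceil(6.0 * scales.max() / dt))
    n_fft = int(2 ** np.ceil(np.log2(n + support)))
    g_hat = np.fft.fft(values, n_fft)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, dt)

    coeffs = np.empty((freqs.size, n), dtype=complex)
    for start in range(0, freqs.size, _chunk):
        sl = slice(start, min(start + _chunk, freqs.size))
        kern = _kernel_fourier(omega[None, :], scales[sl, None], params.central_frequency)
        rows = np.fft.ifft(g_hat[None, :] * kern, axis=1)[:, :n]
        coeffs[sl] = rows / np.sqrt(scales[sl, None])

    times = signal.times
    coi = compute_coi(
        times,
        freqs,
        central_frequency=params.central_frequency,
        e_folding=e_folding,
        record_extent=(signal.t0_seconds, signal.end_seconds),
    )
    return Scalogram(
        freqs_hz=freqs,
        times_s=times,
        coeffs=coeffs,
        coi_mask=coi,
        central_frequency=params.central_frequency,
        source_label=signal.label,
        windows=dict(signal.windows),
    )


def time_average(
    scalogram: Scalogram, window=None, coi_only: bool = True, label: str | None = None
) -> TimeAveragedSpectrum:
    """Per-frequency time means of |W|^2 and |W| over a window.

    ``window`` is a window name stored on the scalogram, a (lo, hi) pair in
    seconds, or None for the whole record.  With ``coi_only`` (default) only
    times inside the cone of influence contribute; frequency rows with no
    admissible times get NaN means and an ``unreliable`` flag.
    """
    t = scalogram.times_s
    if window is None:
        in_window = np.ones_like(t, dtype=bool)
        win_label = label or "full"
    else:
        lo, hi = scalogram.window_interval(window)
        in_window = (t >= lo) & (t < hi)
        win_label = label or (window if isinstance(window, str) else f"[{lo},{hi})")
    if not np.any(in_window):
        raise ValueError("window contains no samples")

    coi = scalogram.coi_mask if coi_only else np.ones_like(scalogram.coi_mask)
    admissible = in_window[None, :] & coi
    counts = admissible.sum(axis=1)
    if np.all(counts == 0):
        raise ValueError("window lies fully outside the cone of influence at all frequencies")

    mag = np.abs(scalogram.coeffs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_amp = np.where(admissible, mag, 0.0).sum(axis=1) / counts
        mean_pow = np.where(admissible, mag**2, 0.0).sum(axis=1) / counts
    empty = counts == 0
    mean_amp[empty] = np.nan
    mean_pow[empty] = np.nan
    in_cone = (in_window[None, :] & scalogram.coi_mask).sum(axis=1)
    return TimeAveragedSpectrum(
        freqs_hz=scalogram.freqs_hz,
        mean_power=mean_pow,
        mean_amplitude=mean_amp,
        unreliable=empty,
        admissible_fraction=in_cone / in_window.sum(),
        window_label=win_label,
    )
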