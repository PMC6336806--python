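"""Physiological frequency bands, per-band spectral metrics, and phase coherence.

Mouse laser-Doppler vasomotion decomposes into six oscillators (cardiac,
respiratory, myogenic, neurogenic, endothelial NO-dependent, endothelial
NO-independent/EDHF); the reconstructed metabolic signals show three slow
metabolic oscillators MO-1/2/3.  Per band we report:

* E_abs — trapezoidal integral of the time-averaged power over the band
* e_rel — E_abs / (E_tot * n_i), n_i = number of grid frequencies in band
* A_abs — maximum time-averaged amplitude in the band
* a_rel — A_abs / (A_tot * n_i)
* f_peak — frequency of the band's amplitude maximum

Wavelet phase coherence (WPCO) between two simultaneous signals is the
resultant length of the time-averaged unit phasor of their wavelet phase
difference, per frequency: values near 1 mean a fixed phase relation,
near 0 no phase relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelet import Scalogram, TimeAveragedSpectrum

__all__ = [
    "Band",
    "BandCatalog",
    "BandMetrics",
    "WpcoSpectrum",
    "BandCoherence",
    "MOUSE_LDF_BANDS",
    "METABOLIC_BANDS",
    "band_metrics",
    "metrics_table",
    "wpco",
    "band_coherence",
]


@dataclass(frozen=True)
class Band:
    """Named half-open frequency interval [f_lo, f_hi) in Hz."""

    name: str
    f_lo_hz: float
    f_hi_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo_hz < self.f_hi_hz):
            raise ValueError(f"band {self.name}: require 0 < f_lo < f_hi")

    def mask(self, freqs_hz: np.ndarray) -> np.ndarray:
        return (freqs_hz >= self.f_lo_hz) & (freqs_hz < self.f_hi_hz)


@dataclass(frozen=True)
class BandCatalog:
    """Ordered, non-overlapping set of bands."""

    catalog_id: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b.f_lo_hz)
        for a, b in zip(ordered, ordered[1:]):
            if b.f_lo_hz < a.f_hi_hz:
                raise ValueError(f"bands {a.name} and {b.name} overlap")

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


#: mouse LDF vasomotion bands (Hz); half-open so shared edges are not double-counted
MOUSE_LDF_BANDS = BandCatalog(
    "mouse_ldf",
    (
        Band("cardiac", 1.35, 5.0),
        Band("respiratory", 0.15, 1.35),
        Band("myogenic", 0.05, 0.15),
        Band("neurogenic", 0.02, 0.05),
        Band("endothelial_no", 0.009, 0.02),
        Band("edhf", 0.005, 0.009),
    ),
)

#: slow metabolic oscillator bands of the reconstructed biomarker signals (Hz)
METABOLIC_BANDS = BandCatalog(
    "metabolic",
    (
        Band("mo1", 0.005, 0.009),
        Band("mo2", 0.0025, 0.005),
        Band("mo3", 0.0015, 0.0025),
    ),
)


@dataclass(frozen=True)
class BandMetrics:
    """Absolute/relative spectral energy and amplitude of one band."""

    band: str
    E_abs: float
    e_rel: float
    A_abs: float
    a_rel: float
    f_peak_hz: float
    n_freqs: int
    reliable: bool = True


@dataclass(frozen=True)
class WpcoSpectrum:
    """Per-frequency phase coherence in [0, 1] between two signals.

    Rows with no admissible times (window outside both cones) are NaN and
    flagged in ``unreliable``.
    """

    freqs_hz: np.ndarray
    cphi: np.ndarray
    unreliable: np.ndarray
    pair_label: str = ""
    window_label: str = ""


@dataclass(frozen=True)
class BandCoherence:
    band: str
    cphi_band: float
    n_freqs: int


def _finite_trapz(y: np.ndarray, x: np.ndarray) -> float:
    """Trapezoidal integral restricted to finite samples."""
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return 0.0
    return float(np.trapezoid(y[ok], x[ok]))


def band_metrics(
    tas: TimeAveragedSpectrum,
    band: Band,
    integration: str = "trapezoid",
    min_coi_fraction: float = 0.5,
) -> BandMetrics:
    """Energy/amplitude metrics of one band from a time-averaged spectrum.

    Energy integrates mean power over linear frequency (trapezoid, the
    area-under-the-curve convention); ``integration='sum'`` uses a plain sum
    of grid values instead for sensitivity checks.  Relative quantities are
    normalised by the full-grid total and by the number of grid frequencies
    inside the band, making them invariant to any rescaling of the signal.

    A band is ``reliable`` only when none of its rows is fully outside the
    cone of influence and, on average over its rows, at least
    ``min_coi_fraction`` of the window lies inside the cone — bands sitting
    largely at the edges of the cone (MO-2/MO-3 on a 20-min record) are
    flagged.
    """
    freqs = tas.freqs_hz
    sel = band.mask(freqs)
    n_freqs = int(sel.sum())
    if n_freqs == 0:
        raise ValueError(f"band {band.name} does not intersect the frequency grid")

    if integration == "trapezoid":
        e_abs = _finite_trapz(tas.mean_power[sel], freqs[sel])
        e_tot = _finite_trapz(tas.mean_power, freqs)
    elif integration == "sum":
        e_abs = float(np.nansum(tas.mean_power[sel]))
        e_tot = float(np.nansum(tas.mean_power))
    else:
        raise ValueError("integration must be 'trapezoid' or 'sum'")

    amp_band = tas.mean_amplitude[sel]
    reliable = bool(~np.any(tas.unreliable[sel]))
    if tas.admissible_fraction is not None:
        reliable = reliable and float(np.mean(tas.admissible_fraction[sel])) >= min_coi_fraction
    if np.all(~np.isfinite(amp_band)):
        a_abs = float("nan")
        f_peak = float("nan")
    else:
        k = np.nanargmax(amp_band)
        a_abs = float(amp_band[k])
        f_peak = float(freqs[sel][k])
    a_tot = float(np.nanmax(tas.mean_amplitude))

    e_rel = e_abs / (e_tot * n_freqs) if e_tot > 0 else 0.0
    a_rel = a_abs / (a_tot * n_freqs) if a_tot > 0 else 0.0
    return BandMetrics(
        band=band.name,
        E_abs=e_abs,
        e_rel=e_rel,
        A_abs=a_abs,
        a_rel=a_rel,
        f_peak_hz=f_peak,
        n_freqs=n_freqs,
        reliable=reliable,
    )


def metrics_table(
    tas: TimeAveragedSpectrum,
    catalog: BandCatalog,
    integration: str = "trapezoid",
    min_coi_fraction: float = 0.5,
) -> list[BandMetrics]:
    """``band_metrics`` for every band of a catalogue, in catalogue order.

    Bands lying largely outside the cone of influence (e.g. MO-2/MO-3 on a
    20-min record) come out with ``reliable=False``.
    """
    return [
        band_metrics(tas, band, integration=integration, min_coi_fraction=min_coi_fraction)
        for band in catalog
    ]


def wpco(
    scal_a: Scalogram,
    scal_b: Scalogram,
    window=None,
    pair_label: str = "",
) -> WpcoSpectrum:
    """Wavelet phase coherence between two simultaneous signals.

    Per frequency k, with phase difference dphi_k(t) = arg W_a - arg W_b
    over times inside the window and inside both cones of influence,

        Cphi(w_k) = sqrt(<cos dphi>^2 + <sin dphi>^2)

    i.e. the resultant length of the mean unit phasor; 1 for a fixed phase
    relation, ~0 for independent phases.
    """
    if scal_a.freqs_hz.shape != scal_b.freqs_hz.shape or not np.allclose(
        scal_a.freqs_hz, scal_b.freqs_hz
    ):
        raise ValueError("scalograms have different frequency grids")
    if scal_a.times_s.shape != scal_b.times_s.shape or not np.allclose(
        scal_a.times_s, scal_b.times_s
    ):
        raise ValueError("scalograms have different time grids")

    t = scal_a.times_s
    if window is None:
        in_window = np.ones_like(t, dtype=bool)
        win_label = "full"
    else:
        lo, hi = scal_a.window_interval(window)
        in_window = (t >= lo) & (t < hi)
        win_label = window if isinstance(window, str) else f"[{lo},{hi})"

    admissible = in_window[None, :] & scal_a.coi_mask & scal_b.coi_mask
    counts = admissible.sum(axis=1)

    dphi = np.angle(scal_a.coeffs) - np.angle(scal_b.coeffs)
    phasor = np.exp(1j * dphi)
    with np.errstate(invalid="ignore", divide="ignore"):
        resultant = np.abs(np.where(admissible, phasor, 0.0).sum(axis=1) / counts)
    empty = counts == 0
    resultant[empty] = np.nan
    # numerical safety: a resultant of unit phasors cannot exceed 1
    resultant = np.clip(resultant, 0.0, 1.0)
    return WpcoSpectrum(
        freqs_hz=scal_a.freqs_hz.copy(),
        cphi=resultant,
        unreliable=empty,
        pair_label=pair_label,
        window_label=win_label,
    )


def band_coherence(w: WpcoSpectrum, band: Band) -> BandCoherence:
    """Arithmetic mean of Cphi over the band's admissible grid frequencies."""
    sel = band.mask(w.freqs_hz)
    vals = w.cphi[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"band {band.name} has no admissible coherence values")
    return BandCoherence(band=band.name, cphi_band=float(vals.mean()), n_freqs=int(vals.size))
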