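"""Scalar biomarkers from skin optical spectra.

UV-excited autofluorescence spectra contain overlapping emission peaks of
elastin (~450 nm), NAD(P)H (~490 nm) and FAD+ (~550 nm).  From the peak
amplitudes two dimensionless ratios are formed:

* redox ratio index  RR = NAD(P)H / FAD+   (proxy for mitochondrial redox state)
* NAD(P)H_normalised = NAD(P)H / elastin   (blood-volume artefact correction)

Visible-reflectance absorption data yield percentage haemoglobin oxygen
saturation (SO2) by Beer-Lambert unmixing of oxy- and deoxyhaemoglobin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "FluorophoreAmplitudes",
    "MetabolicTimePoint",
    "ExtinctionTable",
    "AbsorptionObservation",
    "OxygenationResult",
    "FLUOROPHORE_CENTRES_NM",
    "MissingChannelError",
    "extract_fluorophore_amplitudes",
    "compute_rr_index",
    "compute_nadph_normalised",
    "build_metabolic_series",
    "estimate_so2",
    "default_extinction_table",
]

#: nominal emission-peak centres (nm) of the three fluorophores
FLUOROPHORE_CENTRES_NM = {"elastin": 450.0, "nadph": 490.0, "fad": 550.0}


class MissingChannelError(ValueError):
    """A fluorophore search window does not intersect the wavelength grid."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """One discrete autofluorescence emission spectrum at a timestamp.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing emission wavelengths in nm; must cover the
        450, 490 and 550 nm fluorophore channels.
    intensities : array-like
        Non-negative fluorescence intensities (arbitrary units).
    t_minutes : float
        Acquisition time since recording start, in minutes.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    t_minutes: float

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.ndim != 1 or wl.size < 3 or wl.size != inten.size:
            raise ValueError("spectrum needs >=3 matching wavelength/intensity samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass(frozen=True)
class FluorophoreAmplitudes:
    """Peak amplitudes (a.u.) of the three fluorophores, with peak locations."""

    elastin_amp: float
    nadph_amp: float
    fad_amp: float
    elastin_wl_nm: float = float("nan")
    nadph_wl_nm: float = float("nan")
    fad_wl_nm: float = float("nan")


@dataclass(frozen=True)
class MetabolicTimePoint:
    """RR index and normalised NAD(P)H at one acquisition time."""

    t_minutes: float
    rr_index: float
    nadph_normalised: float


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of oxy/deoxyhaemoglobin per wavelength."""

    wavelengths_nm: np.ndarray
    eps_oxy: np.ndarray
    eps_deoxy: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        eo = np.asarray(self.eps_oxy, dtype=float)
        ed = np.asarray(self.eps_deoxy, dtype=float)
        for name, arr in (("wavelengths_nm", wl), ("eps_oxy", eo), ("eps_deoxy", ed)):
            object.__setattr__(self, name, arr)
        if not (wl.size == eo.size == ed.size):
            raise ValueError("extinction table columns must have equal length")
        if np.any(eo <= 0) or np.any(ed <= 0):
            raise ValueError("extinction coefficients must be positive")


@dataclass(frozen=True)
class AbsorptionObservation:
    """Measured absorption coefficient mu_a per wavelength (units match table)."""

    wavelengths_nm: np.ndarray
    mu_a: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        mu = np.asarray(self.mu_a, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "mu_a", mu)
        if wl.size != mu.size or wl.size < 2:
            raise ValueError("need mu_a at >=2 wavelengths (two unknown absorbers)")
        if np.any(mu < 0):
            raise ValueError("mu_a must be non-negative")


@dataclass(frozen=True)
class OxygenationResult:
    """Fitted haemoglobin concentrations and percentage oxygen saturation.

    ``so2_percent`` is NaN and ``undefined`` True when both fitted
    concentrations clip to zero.
    """

    c_oxy: float
    c_deoxy: float
    so2_percent: float
    undefined: bool = field(default=False)


def extract_fluorophore_amplitudes(
    spectrum: EmissionSpectrum, window_nm: float = 10.0
) -> FluorophoreAmplitudes:
    """Peak amplitude of each fluorophore inside a +/- ``window_nm`` window.

    The amplitude is the maximum raw intensity inside the window around the
    nominal centre (no curve fitting or baseline subtraction); the wavelength
    where it occurs is reported alongside.

    Raises
    ------
    MissingChannelError
        If a window lies entirely outside the wavelength grid.
    """
    if window_nm <= 0:
        raise ValueError("window_nm must be positive")
    wl = spectrum.wavelengths_nm
    out: dict[str, float] = {}
    for name, centre in FLUOROPHORE_CENTRES_NM.items():
        sel = (wl >= centre - window_nm) & (wl <= centre + window_nm)
        if not np.any(sel):
            raise MissingChannelError(
                f"{name} window {centre - window_nm:.0f}-{centre + window_nm:.0f} nm "
                "does not intersect the wavelength grid"
            )
        idx = np.flatnonzero(sel)
        k = idx[np.argmax(spectrum.intensities[idx])]
        out[f"{name}_amp"] = float(spectrum.intensities[k])
        out[f"{name}_wl_nm"] = float(wl[k])
    return FluorophoreAmplitudes(**out)


def compute_rr_index(amps: FluorophoreAmplitudes) -> float:
    """Redox ratio index: NAD(P)H amplitude over FAD+ amplitude."""
    if amps.fad_amp <= 0:
        raise ZeroDivisionError("FAD+ amplitude must be positive for RR index")
    return amps.nadph_amp / amps.fad_amp


def compute_nadph_normalised(amps: FluorophoreAmplitudes) -> float:
    """NAD(P)H amplitude normalised by the elastin amplitude."""
    if amps.elastin_amp <= 0:
        raise ZeroDivisionError("elastin amplitude must be positive for normalisation")
    return amps.nadph_amp / amps.elastin_amp


def build_metabolic_series(
    spectra: list[EmissionSpectrum], window_nm: float = 10.0
) -> list[MetabolicTimePoint]:
    """Per-spectrum RR index and normalised NAD(P)H, order preserved.

    Timestamps must be strictly increasing; at least two spectra are required
    (a single point cannot be reconstructed into a signal downstream).
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to build a metabolic series")
    times = np.array([s.t_minutes for s in spectra], dtype=float)
    if not np.all(np.diff(times) > 0):
        bad = times[np.flatnonzero(np.diff(times) <= 0)[0] + 1]
        raise ValueError(f"timestamps must be strictly increasing (offending t={bad} min)")
    points = []
    for s in spectra:
        try:
            amps = extract_fluorophore_amplitudes(s, window_nm=window_nm)
            points.append(
                MetabolicTimePoint(
                    t_minutes=s.t_minutes,
                    rr_index=compute_rr_index(amps),
                    nadph_normalised=compute_nadph_normalised(amps),
                )
            )
        except (ValueError, ZeroDivisionError) as exc:
            raise type(exc)(f"at t={s.t_minutes} min: {exc}") from exc
    return points


def default_extinction_table() -> ExtinctionTable:
    """Two-wavelength oxy/deoxyHb extinction table at 530 and 630 nm.

    Rounded molar extinction coefficients (cm^-1 / M) of human haemoglobin
    at the green/red probe wavelengths; the columns are strongly
    non-collinear (deoxyHb dominates in the red), which is what makes the
    two-wavelength unmixing well conditioned.  Users may supply any table.
    """
    return ExtinctionTable(
        wavelengths_nm=np.array([530.0, 630.0]),
        eps_oxy=np.array([39036.0, 610.0]),
        eps_deoxy=np.array([39437.0, 5149.0]),
    )


def estimate_so2(
    obs: AbsorptionObservation,
    table: ExtinctionTable | None = None,
    cond_limit: float = 1e8,
) -> OxygenationResult:
    """Percentage SO2 by Beer-Lambert unmixing of oxy/deoxyhaemoglobin.

    Solves mu_a(lambda) = eps_oxy(lambda)*c_oxy + eps_deoxy(lambda)*c_deoxy
    in least squares over the observation wavelengths, clips negative
    concentrations to zero, and returns SO2 = 100*c_oxy/(c_oxy+c_deoxy).

    Raises
    ------
    ValueError
        If an observation wavelength is absent from the table, or the two
        extinction columns are (near-)collinear over those wavelengths.
    """
    if table is None:
        table = default_extinction_table()
    idx = []
    for w in obs.wavelengths_nm:
        hits = np.flatnonzero(np.isclose(table.wavelengths_nm, w))
        if hits.size == 0:
            raise ValueError(f"wavelength {w} nm not present in extinction table")
        idx.append(hits[0])
    design = np.column_stack([table.eps_oxy[idx], table.eps_deoxy[idx]])
    if np.linalg.cond(design) > cond_limit:
        raise ValueError("extinction columns are collinear; SO2 unmixing ill-conditioned")
    coef, *_ = np.linalg.lstsq(design, obs.mu_a, rcond=None)
    c_oxy, c_deoxy = (max(float(c), 0.0) for c in coef)
    total = c_oxy + c_deoxy
    if total == 0.0:
        return OxygenationResult(0.0, 0.0, float("nan"), undefined=True)
    return OxygenationResult(c_oxy, c_deoxy, 100.0 * c_oxy / total)
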