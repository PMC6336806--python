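"""Synthetic study generator with known ground truth.

Emulates the study's recordings: per subject, a 20-min laser-Doppler
blood-flow (LDF) signal sampled at 20 Hz containing six band-resident
oscillators plus 1/f noise, with a baseline -> phenylephrine (PE) amplitude
transition at 10 min; and a series of 20 UV autofluorescence spectra (one
per minute) whose NAD(P)H and FAD+ peak heights oscillate in the MO-1 band.

Oscillators are phase-diffused sinusoids (Wiener phase) so their energy
stays inside the nominal band while the instantaneous frequency wanders,
as physiological vasomotion does.  The phase of the metabolic MO-1
modulation can be coupled to the LDF EDHF oscillator's phase with strength
``coupling_rho`` in [0, 1]: 0 = independent phases, 1 = identical phase
track (up to a constant offset).

Everything is deterministic from (config, seed); the returned ``truth``
dictionaries record the realised parameters so downstream recovery can be
checked against ground truth rather than against another pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .reconstruct import UniformSeries
from .spectral import AbsorptionObservation, EmissionSpectrum, default_extinction_table

__all__ = [
    "OscillatorSpec",
    "SyntheticStudyConfig",
    "SyntheticSubject",
    "default_ldf_oscillators",
    "generate_ldf",
    "generate_spectra",
    "generate_coupled_pair",
    "generate_study",
    "pink_noise",
]


@dataclass(frozen=True)
class OscillatorSpec:
    """One injected band-limited oscillator.

    ``phase_jitter_sd`` is the phase-diffusion standard deviation in
    rad/sqrt(s); 0 gives a pure sinusoid.  ``amplitude_pe_factor``
    multiplies the amplitude during the stimulus window (smooth 10 s ramp
    at the boundary).
    """

    name: str
    freq_hz: float
    amplitude: float
    phase_jitter_sd: float = 0.0
    amplitude_pe_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.phase_jitter_sd < 0:
            raise ValueError("amplitude and phase_jitter_sd must be >= 0")
        if self.freq_hz <= 0:
            raise ValueError("freq_hz must be positive")


def _default_jitter(freq_hz: float) -> float:
    # period-averaged instantaneous-frequency spread of ~ +/-20% (2 sd) of
    # the nominal frequency: sd of (phi(t+T)-phi(t))/(2 pi T) is
    # sigma*sqrt(f)/(2 pi), so sigma = 0.1 * 2 pi * sqrt(f); a wider spread
    # would push oscillator energy outside its nominal band
    return 0.2 * np.pi * np.sqrt(freq_hz)


def default_ldf_oscillators(pe_factor_vasomotor: float = 0.7) -> tuple[OscillatorSpec, ...]:
    """Six mouse LDF oscillators with band-centred frequencies.

    ``pe_factor_vasomotor`` applies to the four vasomotor components
    (myogenic..EDHF); cardiac and respiratory are left unchanged by the
    stimulus.  Use a factor < 1 for a vasoconstriction-like energy decrease
    (wild-type-like) and > 1 for the opposite reactivity.
    """

    def osc(name, f, amp, pe):
        return OscillatorSpec(name, f, amp, phase_jitter_sd=_default_jitter(f),
                              amplitude_pe_factor=pe)

    return (
        osc("cardiac", 3.0, 8.0, 1.0),
        osc("respiratory", 0.7, 5.0, 1.0),
        osc("myogenic", 0.1, 4.0, pe_factor_vasomotor),
        osc("neurogenic", 0.03, 3.0, pe_factor_vasomotor),
        osc("endothelial_no", 0.014, 2.5, pe_factor_vasomotor),
        osc("edhf", 0.007, 2.5, pe_factor_vasomotor),
    )


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study-level generation parameters (defaults mirror the recordings)."""

    seed: int = 0
    group_labels: tuple[str, ...] = ("WT", "KO")
    n_subjects: tuple[int, ...] = (5, 6)
    #: PE amplitude factor of the vasomotor LDF oscillators, per group:
    #: group A decreases (vasoconstriction-like), group B increases
    pe_factor_vasomotor: tuple[float, ...] = (0.7, 1.4)
    ldf_dc: float = 174.0
    #: multiplicative DC change during the stimulus (mild vasoconstriction
    #: lowers mean perfusion by a few percent)
    dc_pe_factor: float = 0.94
    ldf_noise_sd: float = 2.0
    noise_beta: float = 1.0
    baseline_s: float = 600.0
    stimulus_s: float = 600.0
    ramp_s: float = 10.0
    fs_ldf_hz: float = 20.0
    spectra_per_minute: int = 1
    #: MO-1 modulation of the fluorophore peak heights
    mo1_freq_hz: float = 0.007
    #: inter-subject spread of the independent metabolic frequency (an
    #: uncoupled metabolic oscillator does not sit at exactly the vascular
    #: EDHF frequency; peak-frequency SDs of ~1e-3 Hz are typical)
    mo1_freq_sd_hz: float = 1.0e-3
    mo1_depth: float = 0.1
    mo1_jitter_sd: float = field(default=_default_jitter(0.007))
    #: phase-coupling strength between metabolic MO-1 and the LDF EDHF phase
    coupling_rho: float = 0.8
    #: per-timepoint Gaussian noise on the modulated peak heights (fractional)
    height_noise_sd: float = 0.05
    elastin_height: float = 2.0
    nadph_height: float = 3.4
    fad_height: float = 1.545
    #: true per-window oxygen saturation used to forward-model absorption
    so2_true: dict[str, float] = field(
        default_factory=lambda: {"baseline": 47.0, "pe": 45.0}
    )
    so2_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_rho <= 1.0):
            raise ValueError("coupling_rho must be in [0, 1]")
        if self.baseline_s <= 0 or self.stimulus_s <= 0:
            raise ValueError("window durations must be positive")
        if len(self.group_labels) != len(self.n_subjects) or len(self.group_labels) != len(
            self.pe_factor_vasomotor
        ):
            raise ValueError("group_labels, n_subjects, pe_factor_vasomotor lengths differ")

    @property
    def duration_s(self) -> float:
        return self.baseline_s + self.stimulus_s

    @property
    def windows(self) -> dict[str, tuple[float, float]]:
        return {
            "baseline": (0.0, self.baseline_s),
            "pe": (self.baseline_s, self.duration_s),
        }


@dataclass(frozen=True)
class SyntheticSubject:
    """One simulated recording session with its generation ground truth."""

    subject_id: str
    group: str
    ldf: UniformSeries
    spectra: list[EmissionSpectrum]
    absorption: dict[str, AbsorptionObservation]
    truth: dict


def pink_noise(rng: np.random.Generator, n: int, beta: float = 1.0) -> np.ndarray:
    """Unit-variance Gaussian 1/f^beta noise (beta=0 gives white noise)."""
    white = rng.standard_normal(n)
    if beta == 0.0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    out = np.fft.irfft(spec * shape, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _pe_envelope(t: np.ndarray, t_switch: float, ramp_s: float, factor: float) -> np.ndarray:
    """1 before the switch, ``factor`` after, cosine ramp over ``ramp_s``."""
    ramp = np.clip((t - t_switch) / ramp_s, 0.0, 1.0) if ramp_s > 0 else (t >= t_switch) * 1.0
    smooth = 0.5 * (1.0 - np.cos(np.pi * ramp))
    return 1.0 + (factor - 1.0) * smooth


def _diffused_phase(
    rng: np.random.Generator, n: int, dt: float, freq_hz: float, jitter_sd: float
) -> np.ndarray:
    """phi(t) = phi0 + 2 pi f t + Wiener(jitter_sd); phi0 ~ U(0, 2 pi)."""
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) * dt
    drift = 2.0 * np.pi * freq_hz * t
    if jitter_sd > 0:
        steps = jitter_sd * np.sqrt(dt) * rng.standard_normal(n)
        steps[0] = 0.0
        wander = np.cumsum(steps)
    else:
        wander = np.zeros(n)
    return phi0 + drift + wander


def generate_ldf(
    config: SyntheticStudyConfig,
    subject_seed,
    oscillators: tuple[OscillatorSpec, ...] | None = None,
) -> tuple[UniformSeries, dict]:
    """Synthesise one LDF recording; returns (series, truth).

    signal = DC + sum_i A_i * env_i(t) * cos(phi_i(t)) + noise, where
    env_i ramps smoothly to amplitude_pe_factor at the stimulus onset and
    phi_i is a phase-diffused track at the oscillator's frequency.  The
    truth dict records the realised parameters and the per-sample phase
    track of each oscillator (needed for metabolic phase coupling).
    """
    if oscillators is None:
        oscillators = default_ldf_oscillators()
    rng = np.random.default_rng(subject_seed)
    fs = config.fs_ldf_hz
    dt = 1.0 / fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) * dt

    values = config.ldf_dc * _pe_envelope(
        t, config.baseline_s, config.ramp_s, config.dc_pe_factor
    )
    truth_osc = {}
    phase_tracks = {}
    for spec in oscillators:
        phi = _diffused_phase(rng, n, dt, spec.freq_hz, spec.phase_jitter_sd)
        env = _pe_envelope(t, config.baseline_s, config.ramp_s, spec.amplitude_pe_factor)
        values = values + spec.amplitude * env * np.cos(phi)
        phase_tracks[spec.name] = phi
        truth_osc[spec.name] = {
            "freq_hz": spec.freq_hz,
            "amplitude": spec.amplitude,
            "phase_jitter_sd": spec.phase_jitter_sd,
            "amplitude_pe_factor": spec.amplitude_pe_factor,
            "phi0": float(phi[0]),
        }
    if config.ldf_noise_sd > 0:
        values = values + config.ldf_noise_sd * pink_noise(rng, n, config.noise_beta)

    series = UniformSeries(
        fs_hz=fs, t0_seconds=0.0, values=values, label="ldf", windows=config.windows
    )
    truth = {
        "oscillators": truth_osc,
        "dc": config.ldf_dc,
        "noise_sd": config.ldf_noise_sd,
        "noise_beta": config.noise_beta,
        "phase_tracks": phase_tracks,
    }
    return series, truth


_SPECTRUM_GRID_NM = np.arange(400.0, 651.0, 1.0)
_PEAK_SIGMA_NM = 15.0
_PEAK_CENTRES = {"elastin": 450.0, "nadph": 490.0, "fad": 550.0}


def _gaussian_peaks(heights: dict[str, float]) -> np.ndarray:
    wl = _SPECTRUM_GRID_NM
    out = np.zeros_like(wl)
    for name, centre in _PEAK_CENTRES.items():
        out = out + heights[name] * np.exp(-0.5 * ((wl - centre) / _PEAK_SIGMA_NM) ** 2)
    return out


def generate_spectra(
    config: SyntheticStudyConfig,
    subject_seed,
    coupled_phase: np.ndarray | None = None,
) -> tuple[list[EmissionSpectrum], dict]:
    """Synthesise the per-minute UV emission spectra; returns (spectra, truth).

    Each spectrum is three Gaussian fluorophore peaks (450/490/550 nm,
    sigma 15 nm) on a 400-650 nm grid.  The NAD(P)H height is modulated
    sinusoidally at the MO-1 frequency (FAD+ in antiphase, so the redox
    ratio oscillates too); the modulation phase mixes the supplied LDF EDHF
    phase track (weight ``coupling_rho``) with an independent diffused
    phase (weight 1 - rho).

    ``coupled_phase`` is the EDHF phase track sampled at the LDF rate; when
    None the metabolic phase is fully independent regardless of rho.
    """
    rng = np.random.default_rng(subject_seed)
    n_spectra = int(round(config.duration_s / 60.0)) * config.spectra_per_minute
    t_minutes = np.arange(n_spectra) / config.spectra_per_minute
    t_seconds = t_minutes * 60.0

    f_ind = config.mo1_freq_hz + config.mo1_freq_sd_hz * rng.standard_normal()
    f_ind = float(np.clip(f_ind, 0.0052, 0.0088))  # keep inside the MO-1 band
    phi_ind = _diffused_phase(
        rng, n_spectra, 60.0 / config.spectra_per_minute, f_ind, config.mo1_jitter_sd
    )
    rho = config.coupling_rho
    if coupled_phase is not None and rho > 0:
        idx = np.minimum(
            np.round(t_seconds * config.fs_ldf_hz).astype(int), coupled_phase.size - 1
        )
        phi_met = rho * coupled_phase[idx] + (1.0 - rho) * phi_ind
    else:
        phi_met = phi_ind

    noise = config.height_noise_sd * rng.standard_normal((2, n_spectra))
    mod = config.mo1_depth * np.cos(phi_met)
    nadph = config.nadph_height * np.clip(1.0 + mod + noise[0], 0.05, None)
    fad = config.fad_height * np.clip(1.0 - mod + noise[1], 0.05, None)
    elastin = np.full(n_spectra, config.elastin_height)

    spectra = [
        EmissionSpectrum(
            wavelengths_nm=_SPECTRUM_GRID_NM,
            intensities=_gaussian_peaks(
                {"elastin": elastin[k], "nadph": nadph[k], "fad": fad[k]}
            ),
            t_minutes=float(t_minutes[k]),
        )
        for k in range(n_spectra)
    ]
    truth = {
        "mo1_freq_hz": config.mo1_freq_hz,
        "mo1_freq_independent_hz": f_ind,
        "mo1_depth": config.mo1_depth,
        "coupling_rho": rho if coupled_phase is not None else 0.0,
        "heights": {
            "elastin": config.elastin_height,
            "nadph": config.nadph_height,
            "fad": config.fad_height,
        },
        "phi_met": phi_met,
        "nadph_track": nadph,
        "fad_track": fad,
    }
    return spectra, truth


def generate_coupled_pair(
    config: SyntheticStudyConfig,
    subject_seed,
    fs_hz: float = 1.0,
    snr: float = 1.0,
) -> tuple[UniformSeries, UniformSeries, dict]:
    """Two uniformly sampled signals sharing an MO-1-band oscillator.

    Signal A carries a phase-diffused oscillator at the EDHF/MO-1 frequency;
    signal B carries an oscillator whose phase is the rho-weighted mixture
    of A's phase track and an independent track at a subject-specific
    frequency (as in :func:`generate_spectra`).  Independent white noise is
    added to each at the given amplitude signal-to-noise ratio.  This is
    the phase-coherence testbed stripped of the discrete spectral-sampling
    step: it isolates the discrimination power of the coherence estimator
    itself.
    """
    rng = np.random.default_rng(subject_seed)
    n = int(round(config.duration_s * fs_hz))
    dt = 1.0 / fs_hz
    f0 = config.mo1_freq_hz
    phi_a = _diffused_phase(rng, n, dt, f0, config.mo1_jitter_sd)
    f_ind = float(np.clip(f0 + config.mo1_freq_sd_hz * rng.standard_normal(), 0.0052, 0.0088))
    phi_ind = _diffused_phase(rng, n, dt, f_ind, config.mo1_jitter_sd)
    rho = config.coupling_rho
    phi_b = rho * phi_a + (1.0 - rho) * phi_ind

    noise_sd = (1.0 / np.sqrt(2.0)) / snr if snr > 0 else 0.0
    sig_a = np.cos(phi_a) + noise_sd * rng.standard_normal(n)
    sig_b = np.cos(phi_b) + noise_sd * rng.standard_normal(n)
    truth = {"freq_a_hz": f0, "freq_independent_hz": f_ind, "coupling_rho": rho, "snr": snr}
    return (
        UniformSeries(fs_hz=fs_hz, t0_seconds=0.0, values=sig_a, label="oscillator_a"),
        UniformSeries(fs_hz=fs_hz, t0_seconds=0.0, values=sig_b, label="oscillator_b"),
        truth,
    )


def _synth_absorption(
    config: SyntheticStudyConfig, rng: np.random.Generator
) -> tuple[dict[str, AbsorptionObservation], dict[str, float]]:
    table = default_extinction_table()
    obs = {}
    so2_real = {}
    for window, so2 in config.so2_true.items():
        frac = np.clip(so2 / 100.0 + config.so2_noise_sd * rng.standard_normal(), 0.0, 1.0)
        total_hb = 1.0 + 0.1 * rng.standard_normal()
        mu_a = total_hb * (frac * table.eps_oxy + (1.0 - frac) * table.eps_deoxy)
        obs[window] = AbsorptionObservation(
            wavelengths_nm=table.wavelengths_nm.copy(), mu_a=mu_a
        )
        so2_real[window] = float(100.0 * frac)
    return obs, so2_real


def generate_study(config: SyntheticStudyConfig) -> dict[str, list[SyntheticSubject]]:
    """Generate all subjects of all groups, deterministic per (seed, index).

    Groups differ in the PE reactivity factor of the vasomotor oscillators
    (``pe_factor_vasomotor``), emulating the opposite baseline->stimulus
    energy trends of the two phenotypes.
    """
    study: dict[str, list[SyntheticSubject]] = {}
    for gi, (label, n_subj, pe_factor) in enumerate(
        zip(config.group_labels, config.n_subjects, config.pe_factor_vasomotor)
    ):
        oscillators = default_ldf_oscillators(pe_factor_vasomotor=pe_factor)
        subjects = []
        for si in range(n_subj):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(gi, si))
            seed_ldf, seed_spec, seed_so2 = ss.spawn(3)
            ldf, ldf_truth = generate_ldf(config, seed_ldf, oscillators)
            spectra, spec_truth = generate_spectra(
                config, seed_spec, coupled_phase=ldf_truth["phase_tracks"]["edhf"]
            )
            absorption, so2_real = _synth_absorption(config, np.random.default_rng(seed_so2))
            truth = {
                "ldf": {k: v for k, v in ldf_truth.items() if k != "phase_tracks"},
                "metabolic": {
                    k: v
                    for k, v in spec_truth.items()
                    if k not in ("phi_met", "nadph_track", "fad_track")
                },
                "so2_realised": so2_real,
                "seed": config.seed,
                "group": label,
            }
            subjects.append(
                SyntheticSubject(
                    subject_id=f"{label.lower()}{si + 1:02d}",
                    group=label,
                    ldf=ldf,
                    spectra=spectra,
                    absorption=absorption,
                    truth=truth,
                )
            )
        study[label] = subjects
    return study
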