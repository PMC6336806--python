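"""Fluorophore amplitude extraction, biomarker ratios, and SO2 unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasomet.spectral import (
    AbsorptionObservation,
    EmissionSpectrum,
    ExtinctionTable,
    FluorophoreAmplitudes,
    MissingChannelError,
    build_metabolic_series,
    compute_nadph_normalised,
    compute_rr_index,
    default_extinction_table,
    estimate_so2,
    extract_fluorophore_amplitudes,
)

CENTRES = {"elastin": 450.0, "nadph": 490.0, "fad": 550.0}


def gaussian_sum(wl, heights, sigma=15.0):
    out = np.zeros_like(wl, dtype=float)
    for name, centre in CENTRES.items():
        out += heights[name] * np.exp(-0.5 * ((wl - centre) / sigma) ** 2)
    return out


def make_spectrum(heights, wl_lo=400.0, wl_hi=650.0, t_minutes=0.0):
    wl = np.arange(wl_lo, wl_hi + 1.0, 1.0)
    return EmissionSpectrum(wl, gaussian_sum(wl, heights), t_minutes)


class TestExtractAmplitudes:
    def test_gaussian_peaks_match_window_max_oracle(self):
        heights = {"elastin": 1.0, "nadph": 2.0, "fad": 0.9}
        spec = make_spectrum(heights)
        amps = extract_fluorophore_amplitudes(spec, window_nm=10.0)
        # oracle: window maximum of the analytic summed curve on a fine grid
        fine = np.arange(400.0, 650.0, 0.01)
        curve = gaussian_sum(fine, heights)
        for name, got in (
            ("elastin", amps.elastin_amp),
            ("nadph", amps.nadph_amp),
            ("fad", amps.fad_amp),
        ):
            win = (fine >= CENTRES[name] - 10) & (fine <= CENTRES[name] + 10)
            assert got == pytest.approx(curve[win].max(), rel=0.02)

    def test_peak_wavelength_inside_window(self):
        spec = make_spectrum({"elastin": 1.0, "nadph": 2.0, "fad": 0.9})
        amps = extract_fluorophore_amplitudes(spec)
        for name, wl in (
            ("elastin", amps.elastin_wl_nm),
            ("nadph", amps.nadph_wl_nm),
            ("fad", amps.fad_wl_nm),
        ):
            assert CENTRES[name] - 10 <= wl <= CENTRES[name] + 10

    def test_flat_spectrum_gives_constant_amplitudes(self):
        wl = np.arange(400.0, 651.0, 1.0)
        spec = EmissionSpectrum(wl, np.full_like(wl, 5.0), 0.0)
        amps = extract_fluorophore_amplitudes(spec)
        assert amps.elastin_amp == amps.nadph_amp == amps.fad_amp == 5.0

    def test_missing_channel_names_fluorophore(self):
        wl = np.arange(470.0, 641.0, 1.0)
        spec = EmissionSpectrum(wl, np.ones_like(wl), 0.0)
        with pytest.raises(MissingChannelError, match="elastin"):
            extract_fluorophore_amplitudes(spec)

    def test_all_zero_spectrum_is_not_an_error(self):
        wl = np.arange(400.0, 651.0, 1.0)
        amps = extract_fluorophore_amplitudes(EmissionSpectrum(wl, np.zeros_like(wl), 0.0))
        assert amps.nadph_amp == 0.0


class TestRatios:
    @pytest.mark.parametrize(
        "nadph,fad,expected", [(4.4, 2.0, 2.2), (0.0, 1.0, 0.0), (3.0, 3.0, 1.0)]
    )
    def test_rr_index(self, nadph, fad, expected):
        amps = FluorophoreAmplitudes(elastin_amp=1.0, nadph_amp=nadph, fad_amp=fad)
        assert compute_rr_index(amps) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "nadph,elastin,expected", [(3.4, 2.0, 1.7), (2.5, 2.5, 1.0)]
    )
    def test_nadph_normalised(self, nadph, elastin, expected):
        amps = FluorophoreAmplitudes(elastin_amp=elastin, nadph_amp=nadph, fad_amp=1.0)
        assert compute_nadph_normalised(amps) == pytest.approx(expected)

    def test_zero_denominator_guards(self):
        amps = FluorophoreAmplitudes(elastin_amp=0.0, nadph_amp=1.0, fad_amp=0.0)
        with pytest.raises(ZeroDivisionError):
            compute_rr_index(amps)
        with pytest.raises(ZeroDivisionError):
            compute_nadph_normalised(amps)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_ratios_invariant_under_intensity_scaling(self, scale):
        heights = {"elastin": 1.3, "nadph": 2.1, "fad": 1.1}
        spec = make_spectrum(heights)
        scaled = EmissionSpectrum(spec.wavelengths_nm, spec.intensities * scale, 0.0)
        a0 = extract_fluorophore_amplitudes(spec)
        a1 = extract_fluorophore_amplitudes(scaled)
        assert compute_rr_index(a1) == pytest.approx(compute_rr_index(a0), rel=1e-12)
        assert compute_nadph_normalised(a1) == pytest.approx(
            compute_nadph_normalised(a0), rel=1e-12
        )

    def test_increasing_nadph_increases_both_ratios(self):
        lo = FluorophoreAmplitudes(elastin_amp=2.0, nadph_amp=3.0, fad_amp=1.5)
        hi = FluorophoreAmplitudes(elastin_amp=2.0, nadph_amp=3.5, fad_amp=1.5)
        assert compute_rr_index(hi) > compute_rr_index(lo)
        assert compute_nadph_normalised(hi) > compute_nadph_normalised(lo)


class TestMetabolicSeries:
    def test_constant_spectra_give_identical_points(self):
        heights = {"elastin": 2.0, "nadph": 3.4, "fad": 1.5}
        spectra = [make_spectrum(heights, t_minutes=float(k)) for k in range(20)]
        points = build_metabolic_series(spectra)
        assert len(points) == 20
        rr = {p.rr_index for p in points}
        assert len(rr) == 1

    def test_oscillating_nadph_tracks_per_spectrum_ratios(self):
        ts = np.arange(20.0)
        spectra = []
        expected_rr = []
        for t in ts:
            h = {"elastin": 2.0, "nadph": 3.4 * (1 + 0.1 * np.sin(0.5 * t)), "fad": 1.5}
            spec = make_spectrum(h, t_minutes=t)
            spectra.append(spec)
            amps = extract_fluorophore_amplitudes(spec)
            expected_rr.append(amps.nadph_amp / amps.fad_amp)
        points = build_metabolic_series(spectra)
        assert [p.rr_index for p in points] == pytest.approx(expected_rr)

    def test_single_spectrum_rejected(self):
        with pytest.raises(ValueError):
            build_metabolic_series([make_spectrum({"elastin": 1, "nadph": 1, "fad": 1})])

    def test_duplicate_timestamps_rejected(self):
        h = {"elastin": 1.0, "nadph": 1.0, "fad": 1.0}
        spectra = [make_spectrum(h, t_minutes=0.0), make_spectrum(h, t_minutes=0.0)]
        with pytest.raises(ValueError, match="increasing"):
            build_metabolic_series(spectra)


class TestOximetry:
    def test_pure_oxyhaemoglobin_gives_100_percent(self):
        table = default_extinction_table()
        obs = AbsorptionObservation(table.wavelengths_nm, 1.0 * table.eps_oxy)
        assert estimate_so2(obs, table).so2_percent == pytest.approx(100.0)

    def test_equal_mixture_gives_50_percent(self):
        table = default_extinction_table()
        obs = AbsorptionObservation(
            table.wavelengths_nm, 0.5 * table.eps_oxy + 0.5 * table.eps_deoxy
        )
        assert estimate_so2(obs, table).so2_percent == pytest.approx(50.0)

    def test_two_wavelength_round_trip_exact(self):
        # independent oracle: the 2x2 forward model is inverted exactly
        table = ExtinctionTable(
            wavelengths_nm=np.array([530.0, 630.0]),
            eps_oxy=np.array([10.0, 1.0]),
            eps_deoxy=np.array([9.0, 8.0]),
        )
        c_oxy, c_deoxy = 0.3, 0.7
        obs = AbsorptionObservation(
            table.wavelengths_nm, c_oxy * table.eps_oxy + c_deoxy * table.eps_deoxy
        )
        res = estimate_so2(obs, table)
        assert res.so2_percent == pytest.approx(30.0, abs=1e-6)

    @given(
        c_oxy=st.floats(min_value=0.01, max_value=5.0),
        c_deoxy=st.floats(min_value=0.01, max_value=5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, c_oxy, c_deoxy):
        table = default_extinction_table()
        obs = AbsorptionObservation(
            table.wavelengths_nm, c_oxy * table.eps_oxy + c_deoxy * table.eps_deoxy
        )
        res = estimate_so2(obs, table)
        expected = 100.0 * c_oxy / (c_oxy + c_deoxy)
        assert res.so2_percent == pytest.approx(expected, rel=1e-6)

    def test_collinear_columns_rejected(self):
        table = ExtinctionTable(
            wavelengths_nm=np.array([530.0, 630.0]),
            eps_oxy=np.array([2.0, 4.0]),
            eps_deoxy=np.array([1.0, 2.0]),
        )
        obs = AbsorptionObservation(table.wavelengths_nm, np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="ill-conditioned"):
            estimate_so2(obs, table)

    def test_zero_absorption_flagged_undefined(self):
        table = default_extinction_table()
        obs = AbsorptionObservation(table.wavelengths_nm, np.zeros(2))
        res = estimate_so2(obs, table)
        assert res.undefined and np.isnan(res.so2_percent)
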