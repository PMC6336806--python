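"""End-to-end orchestration: one subject, one study, one config.

Per subject: UV spectra -> biomarker ratios -> cubic-spline reconstruction;
LDF -> (optional anti-aliased decimation) -> Morlet CWT -> cone of
influence -> per-window time-averaged spectra -> band metrics; paired
scalograms -> wavelet phase coherence -> MO-1/EDHF band coherence; tissue
SO2 from reflectance absorption where available.  The CWT is computed once
over the full record and windows are separated only at the averaging
stage, so the baseline/stimulus boundary introduces no extra edge
artefacts.

Per study: all subjects are analysed (duplicate recordings of a subject
are averaged at the metrics level), the per-window variable table is
assembled, and the statistics layer produces the summary table,
within/between-group comparisons and the correlation screen.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .bands import (
    METABOLIC_BANDS,
    MOUSE_LDF_BANDS,
    BandCatalog,
    band_coherence,
    metrics_table,
    wpco,
)
from .reconstruct import IrregularSeries, UniformSeries, decimate_series, segment, spline_reconstruct
from .spectral import AbsorptionObservation, ExtinctionTable, build_metabolic_series, estimate_so2
from .stats import compare, correlate, normality_gate, summarise
from .synth import SyntheticStudyConfig, SyntheticSubject, generate_study
from .wavelet import WaveletParams, morlet_cwt, time_average

__all__ = [
    "RunConfig",
    "run_subject",
    "run_study",
    "mo1_edhf_coherence",
    "DEFAULT_CORRELATION_PAIRS",
]

#: metabolic-vs-vascular association screen (x, y) run per group on pooled rows
DEFAULT_CORRELATION_PAIRS = (
    ("e_rel_nadph_mo1", "e_rel_edhf"),
    ("e_rel_nadph_mo1", "e_rel_endothelial_no"),
    ("e_rel_nadph_mo1", "e_rel_neurogenic"),
    ("e_rel_nadph_mo1", "e_rel_myogenic"),
    ("e_rel_nadph_mo1", "f_endothelial_no"),
    ("a_rel_rr_mo1", "e_rel_edhf"),
    ("a_rel_rr_mo1", "perfusion"),
    ("f_rr_mo1", "perfusion"),
    ("f_endothelial_no", "so2"),
)

#: study-table row order
TABLE_VARIABLES = (
    "perfusion", "so2", "nadph_normalised", "rr_index",
    "e_rel_edhf", "e_rel_endothelial_no", "e_rel_neurogenic", "e_rel_myogenic",
    "a_rel_edhf", "a_rel_endothelial_no", "a_rel_neurogenic", "a_rel_myogenic",
    "f_edhf", "f_endothelial_no", "f_neurogenic", "f_myogenic",
    "e_rel_nadph_mo1", "e_rel_rr_mo1", "a_rel_nadph_mo1", "a_rel_rr_mo1",
    "f_nadph_mo1", "f_rr_mo1",
    "cphi_nadph_mo1_edhf", "cphi_rr_mo1_edhf",
)


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: windows, wavelet grids, toggles, output location."""

    seed: int = 0
    out_dir: str | None = None
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"baseline": (0.0, 600.0), "pe": (600.0, 1200.0)}
    )
    metabolic_fs_hz: float = 1.0
    #: integer decimation factor applied to the LDF signal before its own CWT
    #: (1 = native rate); all analysed LDF bands must stay below the new
    #: Nyquist/2, which caps the usable factor
    ldf_decimate: int = 1
    voices_per_octave: int = 16
    f_min_hz: float = 1.5e-3
    ldf_f_max_hz: float | None = None  # None -> min(fs/4, 6 Hz)
    metabolic_f_max_hz: float = 0.05
    coi_only: bool = True
    integration: str = "trapezoid"
    spline_bc: str = "not-a-knot"
    peak_window_nm: float = 10.0
    synth: SyntheticStudyConfig = field(default_factory=SyntheticStudyConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = {k: list(v) for k, v in self.windows.items()}
        return d

    @property
    def cfg_hash(self) -> str:
        return vio.config_hash(self.to_dict())

    def ldf_params(self, fs_hz: float) -> WaveletParams:
        f_max = self.ldf_f_max_hz if self.ldf_f_max_hz is not None else min(fs_hz / 4.0, 6.0)
        return WaveletParams(self.f_min_hz, f_max, self.voices_per_octave)

    def metabolic_params(self) -> WaveletParams:
        return WaveletParams(self.f_min_hz, self.metabolic_f_max_hz, self.voices_per_octave)


def _clip_windows(
    windows: dict[str, tuple[float, float]], t_lo: float, t_hi: float
) -> dict[str, tuple[float, float]]:
    out = {}
    for name, (lo, hi) in windows.items():
        lo_c, hi_c = max(lo, t_lo), min(hi, t_hi)
        if lo_c < hi_c:
            out[name] = (lo_c, hi_c)
    return out


def _window_mean(series: UniformSeries, name: str) -> float:
    return float(series.values[series.window_mask(name)].mean())


def _window_demean(series: UniformSeries) -> UniformSeries:
    """Subtract each analysis window's own mean (full-record mean elsewhere).

    Removing means per window rather than globally keeps a stimulus-induced
    shift of the signal's DC level (e.g. the perfusion drop at the
    iontophoresis onset) from appearing as a broadband step transient in
    the low-frequency scalogram rows.
    """
    values = series.values - series.values.mean()
    out = values.copy()
    for name in series.windows:
        m = series.window_mask(name)
        if m.any():
            out[m] = values[m] - values[m].mean()
    return UniformSeries(
        fs_hz=series.fs_hz, t0_seconds=series.t0_seconds, values=out,
        label=series.label, windows=series.windows,
    )


def run_subject(
    config: RunConfig,
    ldf: UniformSeries,
    spectra,
    absorption: dict[str, AbsorptionObservation] | None = None,
    extinction: ExtinctionTable | None = None,
    subject_id: str = "subject",
    group: str = "",
) -> dict:
    """Analyse one subject's simultaneous LDF + spectral recording.

    Returns a dict with 'metrics' (one row per analysis window holding all
    scalar variables), 'ldf_bands' / 'metabolic_bands' (long-form band
    metric tables) and 'wpco' (per-frequency coherence).
    """
    windows = config.windows
    ldf = segment(ldf, _clip_windows(windows, ldf.t0_seconds, ldf.end_seconds))

    # --- biomarker series from the spectra -------------------------------
    points = build_metabolic_series(list(spectra), window_nm=config.peak_window_nm)
    t_s = np.array([p.t_minutes for p in points]) * 60.0
    met_series = {
        "nadph": IrregularSeries(t_s, np.array([p.nadph_normalised for p in points]), "nadph"),
        "rr": IrregularSeries(t_s, np.array([p.rr_index for p in points]), "rr"),
    }
    met_uniform = {
        name: segment(
            spline_reconstruct(s, config.metabolic_fs_hz, bc_type=config.spline_bc),
            _clip_windows(windows, t_s[0], t_s[-1] + 1.0 / config.metabolic_fs_hz),
        )
        for name, s in met_series.items()
    }

    # --- wavelet analysis -------------------------------------------------
    ldf_for_cwt = _window_demean(decimate_series(ldf, config.ldf_decimate))
    scal_ldf = morlet_cwt(ldf_for_cwt, config.ldf_params(ldf_for_cwt.fs_hz), demean=False)
    met_params = config.metabolic_params()
    scal_met = {
        name: morlet_cwt(_window_demean(s), met_params, demean=False)
        for name, s in met_uniform.items()
    }

    # common-grid LDF scalogram for phase coherence: decimate to the
    # metabolic rate and crop to the metabolic record span
    n_met = met_uniform["nadph"].n
    factor = ldf.fs_hz / config.metabolic_fs_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("ldf rate must be an integer multiple of the metabolic rate")
    ldf_slow = decimate_series(ldf, int(round(factor)))
    ldf_slow = UniformSeries(
        fs_hz=ldf_slow.fs_hz, t0_seconds=ldf_slow.t0_seconds,
        values=ldf_slow.values[:n_met], label="ldf_slow",
        windows=_clip_windows(windows, ldf_slow.t0_seconds, ldf_slow.t0_seconds + n_met / ldf_slow.fs_hz),
    )
    scal_ldf_slow = morlet_cwt(_window_demean(ldf_slow), met_params, demean=False)

    # --- per-window tables ------------------------------------------------
    metric_rows = []
    ldf_band_rows, met_band_rows, wpco_rows = [], [], []
    mo1 = METABOLIC_BANDS["mo1"]
    for win in ldf.windows:
        row: dict = {"subject": subject_id, "group": group, "window": win}
        row["perfusion"] = _window_mean(ldf, win)
        for name, series in met_uniform.items():
            key = "nadph_normalised" if name == "nadph" else "rr_index"
            row[key] = _window_mean(series, win)
        if absorption and win in absorption:
            row["so2"] = estimate_so2(absorption[win], extinction).so2_percent
        else:
            row["so2"] = np.nan

        tas_ldf = time_average(scal_ldf, win, coi_only=config.coi_only)
        # decimation may push the highest bands past the analysed range;
        # only bands intersecting the grid are reported
        ldf_catalog = BandCatalog(
            MOUSE_LDF_BANDS.catalog_id,
            tuple(b for b in MOUSE_LDF_BANDS if np.any(b.mask(tas_ldf.freqs_hz))),
        )
        for bm in metrics_table(tas_ldf, ldf_catalog, integration=config.integration):
            ldf_band_rows.append(
                {"subject": subject_id, "group": group, "window": win,
                 **dataclasses.asdict(bm)}
            )
            if bm.band in ("edhf", "endothelial_no", "neurogenic", "myogenic"):
                row[f"e_rel_{bm.band}"] = bm.e_rel
                row[f"a_rel_{bm.band}"] = bm.a_rel
                row[f"f_{bm.band}"] = bm.f_peak_hz

        for name, scal in scal_met.items():
            tas = time_average(scal, win, coi_only=config.coi_only)
            for bm in metrics_table(tas, METABOLIC_BANDS, integration=config.integration):
                met_band_rows.append(
                    {"subject": subject_id, "group": group, "window": win,
                     "signal": name, **dataclasses.asdict(bm)}
                )
                if bm.band == "mo1":
                    row[f"e_rel_{name}_mo1"] = bm.e_rel
                    row[f"a_rel_{name}_mo1"] = bm.a_rel
                    row[f"f_{name}_mo1"] = bm.f_peak_hz

            w = wpco(scal, scal_ldf_slow, window=win, pair_label=f"{name}/ldf")
            bc = band_coherence(w, mo1)
            row[f"cphi_{name}_mo1_edhf"] = bc.cphi_band
            wpco_rows.extend(
                {"subject": subject_id, "window": win, "pair": f"{name}/edhf",
                 "freq_hz": f, "cphi": c}
                for f, c in zip(w.freqs_hz, w.cphi)
            )
        metric_rows.append(row)

    return {
        "metrics": pd.DataFrame(metric_rows),
        "ldf_bands": pd.DataFrame(ldf_band_rows),
        "metabolic_bands": pd.DataFrame(met_band_rows),
        "wpco": pd.DataFrame(wpco_rows),
    }


def mo1_edhf_coherence(
    run_config: RunConfig,
    synth_config: SyntheticStudyConfig,
    seed: int,
    signal: str = "nadph",
) -> float:
    """MO-1/EDHF band coherence of one synthetic subject, full record.

    Generates one LDF + spectra pair from ``synth_config`` (metabolic MO-1
    phase coupled to the LDF EDHF phase with the configured strength), runs
    the measurement chain — biomarkers, spline reconstruction, matched-grid
    scalograms, WPCO — and returns the mean coherence over the MO-1 band.
    Used for coupling-recovery experiments where the window split is not of
    interest.
    """
    from .synth import generate_ldf, generate_spectra

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0, 0))
    seed_ldf, seed_spec = ss.spawn(2)
    oscillators = None  # group-default reactivity
    ldf, ldf_truth = generate_ldf(synth_config, seed_ldf, oscillators)
    spectra, _ = generate_spectra(
        synth_config, seed_spec, coupled_phase=ldf_truth["phase_tracks"]["edhf"]
    )
    points = build_metabolic_series(list(spectra), window_nm=run_config.peak_window_nm)
    t_s = np.array([p.t_minutes for p in points]) * 60.0
    key = "nadph_normalised" if signal == "nadph" else "rr_index"
    series = IrregularSeries(t_s, np.array([getattr(p, key) for p in points]), signal)
    met = spline_reconstruct(series, run_config.metabolic_fs_hz, bc_type=run_config.spline_bc)
    params = run_config.metabolic_params()
    scal_m = morlet_cwt(met, params)
    factor = int(round(ldf.fs_hz / run_config.metabolic_fs_hz))
    slow = decimate_series(ldf, factor)
    slow = UniformSeries(
        fs_hz=slow.fs_hz, t0_seconds=slow.t0_seconds, values=slow.values[: met.n]
    )
    scal_l = morlet_cwt(slow, params)
    w = wpco(scal_m, scal_l, pair_label=f"{signal}/edhf")
    return band_coherence(w, METABOLIC_BANDS["mo1"]).cphi_band


def _analyse_synthetic_subject(config: RunConfig, subj: SyntheticSubject) -> dict:
    return run_subject(
        config, subj.ldf, subj.spectra, absorption=subj.absorption,
        subject_id=subj.subject_id, group=subj.group,
    )


def run_study(
    config: RunConfig,
    study: dict[str, list[SyntheticSubject]] | None = None,
    write: bool = True,
) -> dict:
    """Analyse a whole study and run the statistics layer.

    ``study`` defaults to a synthetic study generated from ``config.synth``
    (with the run seed).  Subjects that fail a stage are skipped with a
    warning; statistics are skipped when a group retains fewer than two
    subjects.  Duplicate recordings of one subject id are averaged at the
    metrics level before statistics.
    """
    if study is None:
        synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
        study = generate_study(synth_cfg)

    per_subject, failures = [], []
    detail = {"ldf_bands": [], "metabolic_bands": [], "wpco": []}
    for label, subjects in study.items():
        for subj in subjects:
            try:
                res = _analyse_synthetic_subject(config, subj)
            except Exception as exc:  # noqa: BLE001 - per-subject isolation
                warnings.warn(f"subject {subj.subject_id}: {exc}", stacklevel=2)
                failures.append(subj.subject_id)
                continue
            per_subject.append(res["metrics"])
            for key in detail:
                detail[key].append(res[key])

    if not per_subject:
        raise RuntimeError("no subject could be analysed")
    metrics = pd.concat(per_subject, ignore_index=True)
    # duplicate-recording averaging at the metrics level
    metrics = (
        metrics.groupby(["subject", "group", "window"], sort=False, as_index=False).mean()
    )

    out: dict = {
        "metrics": metrics,
        "failures": failures,
        **{k: pd.concat(v, ignore_index=True) for k, v in detail.items()},
    }

    counts = metrics.groupby("group")["subject"].nunique()
    if (counts < 2).any() or len(counts) < 2:
        warnings.warn("fewer than 2 subjects in a group: statistics skipped", stacklevel=2)
    else:
        variables = [v for v in TABLE_VARIABLES if v in metrics.columns]
        out["table1"] = summarise(metrics, variables)
        out["normality"] = pd.DataFrame(
            [dataclasses.asdict(r) for r in normality_gate(metrics, variables)]
        )
        comp_rows = []
        for var in variables:
            if metrics[var].isna().all():
                continue
            for grp in counts.index:
                try:
                    c = compare(metrics, var, "within", group=grp)
                    comp_rows.append({**dataclasses.asdict(c), "significant": c.significant})
                except ValueError:
                    pass
            for win in config.windows:
                try:
                    c = compare(metrics, var, "between", window=win)
                    comp_rows.append(
                        {**dataclasses.asdict(c), "window": win, "significant": c.significant}
                    )
                except ValueError:
                    pass
        out["comparisons"] = pd.DataFrame(comp_rows)

        corr_rows = []
        for grp in counts.index:
            for var_x, var_y in DEFAULT_CORRELATION_PAIRS:
                if var_x not in metrics.columns or var_y not in metrics.columns:
                    continue
                try:
                    c = correlate(metrics, var_x, var_y, subgroup="pooled", group=grp)
                except ValueError:
                    continue
                corr_rows.append(
                    {"group": grp, **dataclasses.asdict(c), "relevant": c.relevant}
                )
        out["correlations"] = pd.DataFrame(corr_rows)
        out["n_tests"] = len(comp_rows) + len(corr_rows)

    if write and config.out_dir:
        out_dir = Path(config.out_dir)
        h = config.cfg_hash
        for key in ("metrics", "ldf_bands", "metabolic_bands", "wpco",
                    "comparisons", "correlations", "normality"):
            if key in out:
                vio.write_csv(out[key], out_dir / f"{key}.csv", cfg_hash=h)
        if "table1" in out:
            vio.write_csv(out["table1"], out_dir / "table1.csv", cfg_hash=h, index=True)
    return out
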