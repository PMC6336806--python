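# Methods

## Signal model and measurement chain

A recording session couples two simultaneous observations of the same skin
patch: a laser-Doppler blood-perfusion signal (uniform sampling, default
20 Hz, 20 min: 10 min baseline, 10 min phenylephrine iontophoresis) and a
series of discrete UV autofluorescence emission spectra (default one per
minute).  From each spectrum the package extracts fluorophore peak
amplitudes and forms the redox ratio (NAD(P)H/FAD⁺) and elastin-normalised
NAD(P)H; these per-minute samples are interpolated to a uniform signal and
both channels undergo the same time–frequency analysis.

### Fluorophore amplitude extraction

The amplitude of a fluorophore is the **maximum raw intensity within ±10 nm
of its nominal emission centre** (elastin 450, NAD(P)H 490, FAD⁺ 550 nm) —
no curve fitting, no baseline subtraction.  This is deliberately the
simplest reproducible convention; its cost is a small positive bias where
peaks overlap: with 15 nm-wide Gaussian peaks the NAD(P)H tail inflates the
elastin window maximum by ~6%, so NAD(P)H_normalised sits ~4% below the
underlying height ratio while RR_index is accurate to ~2‰.  The half-width
is a configuration knob (`peak_window_nm`).

### Oximetry

SO₂ comes from a linear Beer–Lambert unmixing of the absorption coefficient
over the probe wavelengths into oxy/deoxyhaemoglobin contributions (least
squares, negative concentrations clipped to zero and flagged).  A default
two-wavelength extinction table at 530/630 nm is shipped (rounded molar
extinction coefficients of human haemoglobin); any non-collinear table may
be supplied.  Melanin/scattering corrections and absolute concentrations
are out of scope; the two-concentration solve is flagged ill-conditioned
when the extinction columns are nearly collinear (condition number > 1e8).

### Reconstruction

Per-minute biomarker samples are interpolated with a **cubic spline**
(not-a-knot boundary by default — better end behaviour for a 20-point
series; natural boundary available) onto a 1 Hz grid, never extrapolating
beyond the knot span.  1 Hz is far above the ≤9 mHz metabolic bands and
avoids pretending sub-minute information exists; it is a configuration
knob.  The LDF channel is analysed at its native rate or after anti-aliased
integer decimation (`ldf_decimate`); all vasomotor bands lie below 0.15 Hz,
so analysis at 5 Hz (factor 4) is lossless for every band except cardiac,
which requires the native rate.

## Wavelet analysis

The continuous wavelet transform uses the Morlet wavelet
`ψ(u) = π^{-1/4} exp(i2πf₀u) exp(−u²/2)` with central frequency `f₀ = 1` in
the cyclic convention (scale s ↔ frequency f = f₀/s), evaluated by FFT
convolution against the analytic Fourier transform of the scaled wavelet.
Numerical conventions:

* admissibility correction ignored (standard for this f₀, equivalent to
  ω₀ = 2π);
* the transform adopts the **trapezoid quadrature convention** — the two
  record-edge samples carry half weight — so the FFT path agrees with
  direct numerical quadrature of the integral to better than 1e-3
  (in practice ~1e-12) even on very short records; the difference is only
  visible outside the cone of influence;
* zero padding extends the record past 6× the largest scale, so circular
  convolution matches the open-line integral;
* signals are mean-subtracted **per analysis window** before the transform.
  This matters: a stimulus-induced DC shift (the perfusion drop at
  iontophoresis onset) otherwise produces a broadband step transient at
  the window boundary that corrupts the 5–9 mHz rows in both windows;
* default grid: 16 voices per octave from 1.5 mHz (covers MO-3) to
  min(fs/4, 6 Hz) for LDF and 50 mHz for metabolic signals.  The energy
  convention is power = |W|², amplitude = |W|; both are exposed.

### Cone of influence

A coefficient at (f, t) is trusted when t lies at least `c_e·s` from both
record edges, with `c_e = √2` (Morlet envelope e-folding).  On a 20-min
record every frequency below √2/600 ≈ 2.36 mHz has no trusted times at
all.  Band reliability goes further: a band is `reliable` only when no row
is fully excluded **and** on average at least half of the window's
time–frequency area lies inside the cone.  On a 20-min record this keeps
MO-1 (~65% inside) and all LDF bands while flagging MO-2 (~25%) and MO-3
(~1%) — bands sitting largely at the cone's edge, whose metrics are still
reported but should not be interpreted.

### Band metrics

From the per-window time-averaged spectrum (means over in-cone times
only), each band reports the trapezoidal integral of mean power over
linear frequency (`E_i`, "area under the curve"; a plain grid-sum variant
exists behind `integration="sum"`), the relative energy
`e_i = E_i/(E_tot·n_i)` with `n_i` the number of log-grid frequencies in
the band (grid-density dependent, so the grid spec always travels with the
metrics), the band's peak mean amplitude `A_i`, `a_i = A_i/(A_tot·n_i)`,
and the peak frequency.  Relative metrics are invariant under any positive
rescaling of the signal.  Band intervals are half-open `[lo, hi)` so a
shared edge belongs to the upper band.

### Wavelet phase coherence

For two signals on identical grids, `Cφ(ω_k)` is the resultant length of
the time-averaged unit phasor of the wavelet phase difference, over times
inside the window and inside both cones.  The band summary is the
arithmetic mean over the band's admissible frequencies.  No surrogate-based
significance thresholding is applied — at 5–9 mHz a 20-min record holds
only ~8 oscillation periods, and the wavelet correlates neighbouring phase
estimates, so even independent oscillators in the same band show a
coherence floor of ~0.5–0.6.  Absolute coherence values at rest should
therefore not be over-interpreted; contrasts between conditions and
coupling strengths are meaningful, and a surrogate test is a natural
future hook.

For metabolic-vs-LDF coherence the pipeline brings both channels to a
common grid: the LDF signal is decimated to the metabolic reconstruction
rate (1 Hz), cropped to the metabolic record span, and transformed on the
metabolic frequency grid.

## Synthetic data

The generator emulates the study conditions, not the biophysics: LDF =
DC + six phase-diffused sinusoids + 1/f noise; spectra = three Gaussian
peaks (450/490/550 nm, σ 15 nm) on a 400–650 nm grid with sinusoidally
modulated NAD(P)H/FAD⁺ heights (antiphase, so the redox ratio oscillates).
Defaults and their rationale:

* **Oscillators** at band-centred frequencies (cardiac 3 Hz … EDHF 7 mHz),
  amplitudes a few percent of the DC perfusion level (174 a.u.), 1/f noise
  of SD 2 — band signal-to-noise of order 10 in power for the vasomotor
  bands, enough that single-subject recovery is non-trivial but reliable.
* **Phase diffusion** (Wiener phase) models band-limited physiological
  oscillators; the default diffusion gives a period-averaged
  instantaneous-frequency spread of ±20% (2 SD), keeping energy inside
  the nominal band.
* **Stimulus transition**: oscillator amplitudes and the DC level switch
  multiplicatively at 600 s over a smooth 10 s cosine ramp (avoiding an
  artificial broadband edge).  Group A uses a vasomotor factor 0.7
  (vasoconstriction-like decrease), group B 1.4 (opposite reactivity);
  the DC factor is 0.94 in both.  Default group sizes are 5 and 6.
* **Metabolic coupling**: the MO-1 modulation phase is the ρ-weighted
  mixture of the LDF EDHF phase track and an independent track whose
  frequency is drawn per subject (SD 1 mHz, clipped to the MO-1 band) —
  an uncoupled metabolic oscillator does not sit at exactly the vascular
  frequency, and two same-frequency oscillators with slow diffusion would
  remain quasi-locked over 20 min.  ρ = 1 shares the phase track exactly;
  the default ρ = 0.8 reproduces measured band coherences of ~0.8.
* **SO₂**: per-window absorption observations are forward-modelled from a
  true saturation (baseline 47%, stimulus 45%) with small noise, so the
  oximetry inversion is exercised end to end.

Everything is deterministic from (config, seed); per-subject streams are
spawned from a `SeedSequence`, and each subject carries a truth record
sufficient to recompute every injected component.

What the generator does **not** emulate: realistic cardiac/respiratory
waveform shapes (only band placement), motion artefacts, slow drifts other
than the stimulus step, spatially varying optical properties, or any
biophysical NADH/haemodynamic kinetics.  Passing recovery tests therefore
demonstrates correctness of the measurement chain under the stated signal
model, not robustness to every property of in-vivo recordings.

### Known measurement ceilings

Sampling the MO-1 band at one spectrum per minute (2.4 samples per period
at 7 mHz) limits phase tracking: with the default phase diffusion and
per-sample noise equal to the modulation (SNR 1), the full-chain MO-1/EDHF
band coherence saturates near 0.77 even at ρ = 1 (≈0.92 noise-free), while
the same estimator on uniformly sampled 1 Hz signals reaches ≈0.97.  The
coherence-discrimination experiment is therefore run at the signal level
(`generate_coupled_pair`), and the full chain is validated by monotonicity
of coherence in ρ (≈0.54/0.65/0.77 at ρ = 0/0.5/1).

## Statistics

Within-group baseline-vs-stimulus contrasts use the paired t-test,
between-group contrasts the unpaired Student t-test (Welch behind a flag);
all tests two-sided, significance at p < 0.05.  Pearson correlations run
per group on pooled rows (each subject contributes a baseline and a
stimulus row) and are "relevant" when p ≤ 0.05 and |r| > 0.5.  A
Shapiro–Wilk gate flags non-normal variables without excluding them.  No
multiple-testing correction is applied; the report carries the number of
tests performed so users can apply their own.  Duplicate recordings of one
subject are averaged at the metrics level before statistics.

In the reactivity-recovery experiment the injected opposite EDHF amplitude
change is tested on the band's **absolute** energy: the relative energy
normalises by a total that changes simultaneously (all vasomotor bands
share the stimulus factor), which partially cancels the effect when the
stimulus-invariant cardiac band is outside the analysed range.

## Problem sizes

The test suite and the reproduction script run the full chain at
study-scale records (1200 s; 24 000-sample LDF, 20 spectra) with the LDF
analysed at 5 Hz (decimation factor 4, cardiac band excluded from the
analysed range) for repeated-study experiments; Monte-Carlo experiments use
20–25 replicates.  Single-subject analyses at the native 20 Hz rate,
including the cardiac band, are exercised in the unit tests.
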