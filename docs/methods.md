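# Methods

## The measurement problem

IDH-mutant gliomas accumulate 2-hydroxyglutarate (2-HG). In vivo proton
spectra at 3 T cannot resolve the 2-HG C4 multiplet (~2.25 ppm) from the
glutamate+glutamine C3 composite (Glx3, 2.25–2.35 ppm), but the Glx C4
composite (Glx4, 2.31–2.40 ppm) carries no 2-HG. The package therefore
quantifies 2-HG indirectly: any excess of the fitted Glx3 area over the
fitted Glx4 area, beyond the ratio seen in healthy tissue, is attributed
to 2-HG.

With R = area(Glx3)/area(Glx4),

    elevation % = 100 · (R_tumor / R_ref − 1)

where R_ref is the Glx3/Glx4 ratio of uninvolved contralateral voxels
(population value 0.81, between-voxel SD 0.06). The "ratio of ratios" form
and the difference form 100·(R_t − R_c)/R_c are algebraically identical;
the package states the formula explicitly because it is usually given only
in words. A voxel with elevation strictly > 0 % is called positive
(IDH-mutant). Under the assumption that 2-HG and Glx have comparable T1/T2
relaxation, an elevation *e* maps to a concentration estimate
(e/100)·([Glu]+[Gln]) mmoles/kg, with literature concentrations
Glu 11.7 / Gln 3.2 (gray matter) and 7.1 / 1.7 (white matter).

Areas, not amplitudes, enter the ratio: areas are robust to linewidth
differences between voxels (amplitude-based ratios are available as an
option in `quantify_voxel(use="amplitude")`).

## Synthetic-data generator (`synthspec`)

The generator is the package's ground-truth source; no raw clinical
spectra are distributed.

**Forward model.** Each voxel's FID is a sum of Gaussian-decaying complex
exponentials, one per resonance group:

    s(t) = Σ_r A_r · exp(i 2π f_r t − (a_r t)²) · e^{iφ0} + baseline + noise

with A_r = concentration × rel_signal, f_r = (δ_r + shift − δ_ref)·f0, and
a_r = π·FWHM/(2√ln2) so the real lineshape after transform is a Gaussian
of the stated FWHM. Defaults: 1024 complex points, dwell 0.5 ms (2000 Hz
spectral width, 512 ms acquisition), f0 = 123.25 MHz (3 T), carrier on
water at 4.7 ppm, TR/TE = 1500/40 ms. Nine groups: NAA 2.008, Cr1 3.03,
Cr2 3.91, Cho 3.19, Ins1 3.55, Ins2 3.64, Glx3 2.29, Glx4 2.35, 2-HG
2.25 ppm — canonical in vivo shifts, each inside its fitting window.
J-coupling fine structure is deliberately collapsed to one Gaussian per
group, mirroring the one-Gaussian-per-window quantification.

**Linewidth.** Metabolite FWHM defaults to 6 Hz. The shim-quality figure
usually quoted (12 Hz) refers to the water line; metabolite lines in a
well-shimmed 3 T voxel are narrower. The value is a configurable parameter
of `build_basis`.

**Calibration.** The rel_signal factors absorb proton counts and
relaxation weighting. They are set so that a 2-HG-free voxel has a Glx3/Glx4
signal ratio exactly equal to its `glx3_glx4_ratio` field (default 0.81),
and the 2-HG factor is tied to the same per-voxel ratio, which makes

    true elevation = 100 · [2-HG] / ([Glu] + [Gln])

hold identically for every voxel, whatever its healthy-ratio draw. Cohorts
draw the per-patient ratio from Normal(0.81, 0.06) truncated positive,
shared by the tumor and contralateral voxel of each patient.

**Distortions.** Zero-order phase (cohort default uniform ±20°), global
frequency shift (±0.03 ppm), a degree-6 polynomial baseline injected as
the inverse transform of the polynomial evaluated on the native spectral
grid, and complex white Gaussian noise. The default time-domain noise SD
of 0.04 yields a spectral SNR (NAA peak height over spectral noise SD)
around 20, typical for CSI voxels of this size at 3 T. All randomness
flows from a single integer seed; identical seeds give bit-identical
output.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: J-coupling multiplet structure and its
TE-dependent phase modulation (the real Glx/2-HG overlap is harder than
two clean Gaussians), macromolecule/lipid background (the baseline here is
a smooth polynomial by construction, so degree-6 correction can be exact),
residual water (only available as an explicit optional resonance),
voxel-bleed between CSI grid cells, and relaxation differences between
2-HG and Glx (assumed away by the concentration conversion itself).

## Processing chain (`specproc`)

Fixed order: eddy-current correction (when a water reference exists) →
Hanning apodization (w(t) = 0.5(1+cos(πt/512 ms)) for t ≤ 512 ms, zero
beyond) → zero filling 1024→2048 → Fourier transform → frequency alignment
→ degree-6 baseline correction → zero-order phase correction. Baseline
runs before phase deliberately, matching the automated clinical pipeline
this package mirrors, although most research packages phase first. Each
step appends to the spectrum's provenance with its applied parameters.

Numerical choices:

- **FFT normalization:** forward transform unscaled; Parseval reads
  Σ|S|² = N·Σ|s|². `to_spectrum` is a plain DFT by default and is tested
  against an O(N²) brute-force oracle.
- **First-point scaling:** inside `process` the t = 0 sample is halved
  before the FFT. A one-sided FID double-counts the origin; without the
  correction a constant pedestal of half the first sample sits under the
  whole real spectrum and corrupts both the baseline-fit support and
  narrow-window areas.
- **Eddy-current correction** divides out the water reference's per-sample
  phase (Klose method); magnitudes are untouched. Because the water scan
  shares the voxel's phase and frequency distortions, this also removes
  the global shift.
- **Frequency alignment** rolls the spectrum so the magnitude maximum in
  the NAA window (1.82–2.22 ppm) lands on the bin nearest 2.008 ppm; NAA
  is the dominant singlet in vivo. If no point in the window exceeds 5×
  the median spectral magnitude, the spectrum is returned unshifted and
  flagged `alignment_failed`. Alignment is quantized to the grid
  (±half a bin, ~0.004 ppm); the Gaussian fits re-center, so area
  estimates are insensitive to this.
- **Baseline correction** least-squares-fits a degree-6 polynomial to the
  real part at all axis points outside the eight fitting windows and
  outside 4.4–5.0 ppm (residual water), then subtracts it everywhere. At
  least 14 support points are required. The fit support is a package
  choice; the reference pipeline does not document one.
- **Phase correction** maximizes the integral of the real part. Over the
  full axis the maximizer is exactly φ = arg(Σ S) = arg(N·s[0]), because
  every dispersive contribution integrates out; the estimator is then
  unbiased, idempotent, and recovers an injected rotation to machine
  precision. Restricting the integral to a sub-band (supported via a
  parameter, e.g. to dodge an unsuppressed water line) truncates the
  slowly decaying one-sided dispersion tails asymmetrically and biases
  the phase by several degrees even on ideal data — enough to distort Glx
  areas by ~10% — so the full axis is the default. Only zero-order phase
  is corrected; first-order phase is out of scope for this short-TE
  echo acquisition.

## Peak fitting (`peakfit`)

Windows (ppm): Cr2 3.80–4.05, Ins2 3.62–3.70, Ins1 3.50–3.60, Cho
3.14–3.34, Cr1 2.94–3.14, Glx3 2.25–2.35, Glx4 2.31–2.40, NAA 1.82–2.22.
The Cho range is sometimes printed as 2.14–3.34, which would swallow the
NAA and Cr1 windows; 3.14–3.34 brackets choline at 3.19 ppm and keeps the
eight windows disjoint except for the intended Glx3/Glx4 overlap. All
windows are configurable.

Six windows are fitted independently with one Gaussian
A·exp(−(δ−δ0)²/2σ²) on the real part; bounds are δ0 inside the window,
σ ∈ [0.005, 0.15] ppm, A ≥ 0; initialization from the window maximum.
Fits run on scipy's trust-region-reflective least squares with native box
constraints (chosen over MINPACK-style bound transforms, which needed
thousands of function evaluations per fit on this problem). Area =
A·σ·√2π; a parameter pinned at a bound raises the `at_bound` flag.

The overlapping pair is fitted jointly over 2.25–2.40 ppm with up to
three components: one for Glx4 (center in its own window) and one or two
sharing a width for the Glx3 window. The second Glx3 component represents
2-HG; the Glx/2-HG sub-split is ill-conditioned at 3 T, but only their
sum enters the statistic, and the sum is well-conditioned. Three
safeguards make the decomposition identifiable:

1. Both Glx3-window centers are confined to the non-overlap part of the
   window (2.25–2.31 ppm, where Glx C3 and 2-HG actually resonate).
   Otherwise a Glx3 component can migrate into the 2.31–2.35 overlap,
   model the Glx4 peak, zero out the Glx4 component and explode the
   ratio — this failure mode was observed on noisy contralateral voxels.
2. The fit is staged: a single line per window first (multi-started from
   deterministic, data-driven centers; a user-provided init adds one more
   start and therefore cannot change the selected solution), then the
   second Glx3 line seeded at the stage-1 residual maximum.
3. The second line is kept only if it cuts the residual sum of squares
   below 0.2× the single-line fit *and* by more than 13.8× the per-point
   noise variance (χ² with 2 extra parameters, p ≈ 0.001; noise estimated
   by MAD in the resonance-free 0.4–1.6 ppm region). Wing-chasing on
   single-line spectra gains at most ~2×, a genuine second line ≫5×, so
   the gate separates cleanly; without it the extra component inflates
   the healthy ratio by ~1%.

**Residual lineshape error.** Hanning apodization convolves each Gaussian
line with the window's transform, so fitted single Gaussians carry a
small model error (individual areas recover simulator truth to within
~2% noiselessly; the 15% elevation round-trip recovers [2-HG] to within
~3%). This bias is common-mode between Glx3 and Glx4 and between tumor
and reference, so the elevation statistic cancels most of it — the
measured healthy-voxel ratio is 0.8101 against a generator truth of 0.81.

## Cohort statistics (`cohort`)

The packaged clinical table (11 patients; checksum-verified on load)
carries per-patient MRS elevation, ex vivo GC-MS 2-HG concentration, IDH
genotype, and the TP/TN/FN label, which is validated against the >0 %
rule on load. Statistics:

- Pearson correlation (scipy), with a case-resampling bootstrap
  (default 10,000 resamples, percentile 95% interval, seeded; degenerate
  constant resamples are skipped and counted). The printed clinical values
  recompute exactly: r = 0.80, PPV 100%, NPV 33% (exactly 33.33, reported
  to the nearest integer), 8 positive calls, subgroup means 5.45
  (non-R132H) and 1.38 (R132H) mmoles/kg, median ex vivo 1.73.
- Subgroup comparison uses Welch's t-test by default (Student's optional);
  the test behind the originally reported subgroup p-values is not
  documented, and recomputing from the printed per-patient values gives
  p ≈ 0.08, not 0.001 — the printed p-values are therefore not
  reproduced, only the means.
- Excluding the three non-R132H cases and recomputing r from the printed
  values gives 0.76 rather than the reported 0.81; per-sample (two
  biopsies per patient) and voxel-matched data are unpublished, so the
  per-sample correlations (0.82/0.83) and the sample-level median
  1.70 (IQR 0.82–3.25) cannot be desk-checked either. Only per-patient
  statistics are asserted.
- `power_check` estimates the power of the two-sided Pearson test by
  Monte-Carlo on bivariate-normal draws. At r = 0 it reproduces the
  nominal test size (measured 0.0515 at α = 0.05, n = 10, 2000 sims); at
  the design point r = 0.70, n = 10 it gives ≈ 0.69, close to the 0.75
  design figure, whose exact assumptions are unstated — reported, not
  asserted.

## Reference handling (`hgquant`)

The default reference is the per-patient contralateral voxel ratio
(`reference_ratio` averages several voxels when available; sample SD with
ddof = 1, zero for a single voxel). A cohort-level fallback constant 0.81
serves single-voxel use. Whether the original clinical elevations used
per-patient or pooled references is not documented; per-patient is the
default here. Non-converged Glx fits raise instead of silently producing
a call.

## Problem sizes used in validation

The shipped validation suite runs noiseless single-voxel recoveries, a
20-patient synthetic cohort at low noise (pipeline-vs-truth r ≈ 0.99,
asserted > 0.9), a 600-voxel noiseless contralateral calibration (mean
and SD of the measured ratio within four Monte-Carlo standard errors of
0.81/0.06), and 2000-simulation power checks. These sizes keep the whole
suite under two minutes for the expensive parts while leaving the
Monte-Carlo error bars well below the asserted tolerances.

## Known limitations

- Single Gaussians per group ignore J-modulation; absolute areas are
  ~1–2% biased by the apodization kernel (largely cancelled by the ratio
  statistic).
- The 2-HG/Glx sub-split inside the Glx3 window is reported only as a
  composite; do not interpret the individual sub-components.
- No absolute quantification (water scaling), no relaxation correction,
  no first-order phase, no HLSVD water removal, no k-space/voxel-bleed
  modeling, no vendor raw-format ingestion (CSV+JSON interchange only).
- The elevation-to-concentration conversion inherits the equal-relaxation
  assumption; treat the mmoles/kg output as an order-of-magnitude
  estimate, not an assay.
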