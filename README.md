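# hgmrs

Quantification of the oncometabolite **2-hydroxyglutarate (2-HG)** from in
vivo proton MR spectroscopy, for non-invasive prediction of **IDH mutation
status** in diffuse glioma.

IDH-mutant gliomas accumulate 2-HG, whose C4-proton multiplet resonates
near 2.25 ppm and overlaps the glutamate+glutamine C3 composite (**Glx3**,
2.25–2.35 ppm). The C4 composite (**Glx4**, 2.31–2.40 ppm) is free of 2-HG.
The package implements the resulting ratio statistic: with
R = area(Glx3)/area(Glx4) fitted by Gaussian lineshapes,

```
elevation % = 100 · (R_tumor / R_contralateral − 1)
```

where healthy contralateral tissue has R = 0.81 ± 0.06 (SD across
individuals and voxel locations). An elevation strictly above 0 % calls the
tumor IDH-mutant. Assuming comparable relaxation of 2-HG and Glx, an
elevation *e* converts to an approximate tissue concentration
`(e/100)·([Glu]+[Gln])` mmoles/kg.

The package is aimed at spectroscopists and imaging researchers who want a
fully scripted, testable version of this workflow:

- **`hgmrs.synthspec`** — ground-truth simulator: 1024-point complex FIDs
  for a 3 T CSI-PRESS acquisition (TR/TE = 1500/40 ms, 2000 Hz spectral
  width), eight metabolite resonance groups plus 2-HG, polynomial
  baselines, phase/frequency errors, noise, paired tumor/contralateral
  cohorts with known truth.
- **`hgmrs.specproc`** — the processing chain, in fixed order: water-reference
  (eddy-current) correction, Hanning apodization (0–512 ms), zero filling
  1024→2048, Fourier transform, frequency alignment to NAA at 2.008 ppm,
  sixth-order polynomial baseline correction, zero-order phase correction.
- **`hgmrs.peakfit`** — Gaussian fits in the eight chemical-shift windows
  (Cr2 3.80–4.05, Ins2 3.62–3.70, Ins1 3.50–3.60, Cho 3.14–3.34,
  Cr1 2.94–3.14, Glx3 2.25–2.35, Glx4 2.31–2.40, NAA 1.82–2.22 ppm), with
  a joint fit resolving the Glx3/Glx4 overlap.
- **`hgmrs.hgquant`** — the elevation statistic, IDH classification, and
  concentration conversion.
- **`hgmrs.cohort`** — validation statistics on the packaged 11-patient
  clinical table (Pearson r with case-resampling bootstrap, PPV/NPV,
  IDH1-subtype subgroup means, median/IQR, Monte-Carlo power checks).
- **`hgmrs.cli_io`** — `hgmrs` command-line interface and the CSV+JSON
  signal interchange format.

## Worked example

Simulate a small cohort, quantify it, and correlate against the ground
truth:

```sh
$ hgmrs simulate --n-patients 4 --noise-sd 0.01 --seed 11 --out cohort
wrote cohort/truth.csv and 8 FID files
$ hgmrs quantify cohort --out quantified.csv
wrote quantified.csv (4 patients)
$ hgmrs analyze quantified.csv --truth cohort/truth.csv
measured elevation vs true [2-HG]: r = 0.99, 95% bootstrap CI [-1.00, 1.00] (162 degenerate resamples)
```

(The interval is wide because four patients resample degenerately; at
n = 20 the same pipeline recovers r > 0.99.) Each `quantified.csv` row
holds the fitted tumor ratio, the per-patient contralateral reference, the
percentage elevation, and the call:

```
patient,tumor_ratio,ref_ratio,elevation_pct,call,...
1,0.9278,0.8943,3.75,positive,...
```

The same workflow in Python, for a single noiseless voxel carrying a true
15 % elevation ([2-HG] = 2.235 mmoles/kg over gray-matter Glu+Gln = 14.9):

```python
from hgmrs import hgquant, peakfit, specproc, synthspec
from hgmrs.containers import AcquisitionParams

acq = AcquisitionParams()
tumor = synthspec.VoxelTruth(
    concentrations=synthspec.tissue_concentrations("gray", hg=2.235),
    label="tumor")
panel = peakfit.fit_panel(specproc.process(synthspec.simulate_fid(tumor, acq, seed=2)))
result = hgquant.quantify_voxel(panel, ref_ratio=0.81)
print(result.elevation_pct)                                   # 15.38
print(hgquant.estimate_concentration(result.elevation_pct, 11.7, 3.2))  # 2.29
```

The recovered elevation (15.38 %) and back-converted concentration
(2.29 mmoles/kg) match the injected truth to within the fit's lineshape
error.

Reproduce the clinical-table statistics:

```sh
$ hgmrs reproduce-table1
n patients                 11
positive 2-HG calls        8
Pearson r (MRS vs ex vivo) 0.80 (p = 0.003)
PPV                        100%
NPV                        33%
mean ex vivo, non-R132H    5.45 mmoles/kg
mean ex vivo, R132H        1.38 mmoles/kg
median ex vivo             1.73 mmoles/kg (IQR 0.71-2.92)
...
all checks passed
```

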