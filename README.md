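# glycospec

SWIR hyperspectral chemometrics for predicting total glycoalkaloids
(TGA) in potato tubers.

Glycoalkaloids (α-solanine + α-chaconine) accumulate in tubers under
light exposure ("greening") and are toxic above ~200 ppm, but the
reference assay (extraction + HPLC) is destructive and slow.
Short-wave-infrared (900–2500 nm) hyperspectral imaging offers a
non-destructive alternative: each tuber's image cube is reduced to one
mean reflectance spectrum, and a multivariate calibration maps spectra
to TGA concentration.  `glycospec` implements that full analysis chain
for anyone building or stress-testing such calibrations:

- **hypercube I/O and ROI extraction** — ENVI (.hdr + raw, BIL/BSQ)
  reading/writing, reflectance calibration `R = (raw − dark)/(white − dark)`,
  Otsu masking on the band-averaged image, mean-spectrum extraction into
  an *n* × 169 matrix;
- **pre-processing** — SNV, Savitzky–Golay derivatives, orthogonal
  signal correction (OSC), composable chains (`"snv + 1st derivative"`,
  `"|1st der| + snv"`, …) that fit response-dependent steps on training
  rows only;
- **wavelength selection** — CARS (Monte-Carlo |β|-reweighted sampling
  under an exponentially decaying retention schedule), IRIV (per-band
  Mann–Whitney classification over random binary subsets), and greedy
  backward elimination, all scored by 5-fold PLS RMSECV;
- **calibration and validation** — NIPALS PLS1 and RBF ε-SVR, LOOCV and
  70:30 split evaluation with R², RMSE (ppm) and RPD = SD_p/RMSE_p;
- **synthetic study generator** — spectra, hypercubes and reference
  values with known ground truth (day-group TGA means 97.13/159.56/128.41
  ppm, matrix absorption peaks at 976/1214/1431/1781/1905 nm, linear
  TGA-linked absorptions, scatter/baseline/noise), so every stage can be
  tested against a known answer.

The core statistics: PLS1 projects the centered spectra onto latent
variables *t*ₖ that maximize covariance with TGA, choosing the number of
LVs by minimal cross-validated RMSE,

    R² = 1 − Σ(yᵢ − Ŷᵢ)² / Σ(yᵢ − ȳ)²,  RMSE = √(Σ(yᵢ − Ŷᵢ)²/n),  RPD = SD_p / RMSE_p,

with RPD ≈ 1.4–1.8 a fair screening model and > 2.5 a good quantitative one.

## Worked example

```sh
python examples/06_full_experiment.py
```

runs a pre-processing × selector grid on the default synthetic study
(210 tubers, 169 bands) and prints:

```
selector  preprocessing model  n_selected  LV  R2cv  RMSEcv   R2c  RMSEc   R2p  RMSEp   RPD
    full           none  plsr         169   3 0.699  22.064 0.797 18.320 0.686 21.903 1.799
 cars+be           none  plsr          35   4 0.742  20.428 0.832 16.672 0.704 21.258 1.853
    full 1st derivative  plsr         169   3 0.732  20.836 0.806 17.925 0.792 17.838 2.209
 cars+be 1st derivative  plsr          30  12 0.786  18.614 0.852 15.678 0.782 18.261 2.157

best by R2cv: cars+be / 1st derivative / plsr -> R2cv 0.786, RMSEcv 18.61 ppm
```

Each row is one model: R²cv/RMSEcv from leave-one-out cross-validation,
R²c/RMSEc on the 70% calibration split, R²p/RMSEp on the held-out 30%,
and RPD. Reducing 169 bands to ~30 informative wavelengths with CARS +
backward elimination improves every metric — the central claim this kind
of pipeline is built to test.  The other `examples/` scripts cover each
capability separately (simulation, cube extraction, pre-processing,
selection, calibration); a thin CLI (`glycospec simulate|extract|run|
report|fixtures`) wraps the same functions for shell use.

Published wavelength selections from a greening study on Yukon Gold
tubers are packaged as fixtures
(`glycospec.load_fixture("table3", "CARS", "osc + 1st derivative")` →
26 wavelengths) for comparison against freshly computed selections.

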