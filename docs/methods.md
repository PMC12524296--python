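# Methods

This note documents the models, algorithms and design choices behind
`glycospec`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and which knobs matter.

## The synthetic study generator

`glycospec.synthetic` emulates a light-exposure (greening) study on
potato tubers scanned by a push-broom SWIR camera.

**Spectral model.** Reflectance on the 169-band grid
λₖ = 901.121 + 9.527·k nm is

    R(λ) = clip( g · [ R₀ − Σⱼ dⱼ G(λ; cⱼ, wⱼ) − f(TGA) · Σₗ aₗ G(λ; cₗ, wₗ) + b·(λ − λ̄) ] + ε, 0, 1.2 )

with Gaussian peak shape G, a matrix term (water/starch/sugar bands at
976, 1214, 1431, 1781, 1905 nm; widths 30 nm; depths 0.08–0.30 around a
0.55 baseline), a TGA term at the carbohydrate/water bands repeatedly
selected by wavelength selection (1166.3, 1649.3, 1791.4, 2047.1,
2085.0, 2378.5 and 1933.4 nm; widths 20 nm; depths 1–2.5 × 10⁻⁴ per
ppm), multiplicative scatter g ~ lognormal(0, 0.05), baseline slope
b ~ N(0, 5·10⁻⁵ /nm) and white noise ε ~ N(0, noise_sd).  f(TGA) is
linear by default (`tga_nonlinearity` adds an optional quadratic term).
With all noise scales zero, TGA → spectrum is exactly affine — the basis
for finite-difference recovery tests.

**Reference values.** Three day groups of 70 tubers with TGA means
97.13 / 159.56 / 128.41 ppm (day 0 / 7 / 14 — rise to a day-7 peak,
partial decline by day 14) and a common within-group SD of 30 ppm,
drawn truncated-normal at zero.  Group means are the study's pattern;
the within-group spread is unpublished, so it is a package choice.

**Noise calibration.** `noise_sd` defaults to 0.02 reflectance units,
chosen (once, over a small candidate grid) so that the default
full-spectrum first-derivative PLSR model lands in the "fair" RPD band:
R²cv ≈ 0.70, RPD ≈ 1.6–1.9 at default conditions.  This mirrors the
performance regime reported for real tubers and keeps the synthetic
problem neither trivial nor hopeless.

**Images.** A tuber frame is a centered ellipse of spectrum-carrying
pixels (per-pixel multiplicative jitter, SD 1%) over a dark (0.02)
background; white (0.99) and dark (0) reference cubes match the frame
shape.  This supports the masking/extraction chain, not radiometry: no
shading, specular lobes, or spatial TGA gradients are modeled.

**Selector benchmark.** `make_band_recovery_benchmark` is a separate
construction for wavelength-selection tests: 10 of 169 bands each
reflect one independent latent factor and the response is the factor
sum, so every informative band carries unique information and "recovery"
is well-posed.  Per-band noise SD 0.5 puts the population R² of the best
linear predictor at 1/(1+0.5²) = 0.8.  The day-group generator is a
one-factor model (all TGA bands move together) and deliberately cannot
play this role.

**What passing tests show — and don't.** Green suites demonstrate the
algorithms are implemented correctly and recover planted structure under
realistic noise; they do not certify performance on real tubers, where
scatter is structured, peaks shift with temperature/moisture, and the
TGA–absorbance link need not be linear.

## Hypercube handling

ENVI support is a narrow, fully-tested dialect: BIL and BSQ interleave,
32-bit little-endian floats, wavelengths (nm) in the header.  Masking
thresholds the band-averaged intensity image — more robust to single-band
noise than any one band — with Otsu's criterion over a 256-bin histogram,
then keeps the largest connected component.  Empty-bin histogram
plateaus make the Otsu argmax a tie set; the implementation returns the
first maximizer, and tests compare achieved between-class variance.  No
dead-pixel filtering is applied.  Calibration averages the white/dark
references over their spatial extent per band before the pixelwise
`(raw − dark)/(white − dark)`, clipped to [0, 1.2].

## Pre-processing

Chains are ordered lists of steps applied left-to-right.  SNV centers
and scales each spectrum (sample SD, ddof 1).  Derivatives use
Savitzky–Golay (defaults window 11, polyorder 2) per band index — the
grid is uniform, so per-nm derivatives differ only by a constant —
with polynomial ("interp") edge handling.  `"|1st der| + snv"` is the
elementwise absolute derivative followed by SNV.

OSC removes components whose scores are orthogonal to the training
response: each component alternates projections between the column space
of centered X and the orthogonal complement of y, so the removed score
satisfies t = Xw exactly and t ⊥ y to machine precision; deflation is
then reproducible on unseen rows from the stored (w, p) pair, and the
corrected matrix keeps its training mean so chains compose on the
reflectance scale.  One component is removed by default.

Leakage policy: inside any reported cross-validation, OSC is refit on
each fold's training rows; y-free steps are rowwise and fold-invariant.
The selection stage, by contrast, operates on the full-dataset
pre-processed matrix — selection is treated as a modeling decision, not
a reported metric, matching common chemometric practice.

## PLS, SVR and evaluation

PLS1 is NIPALS with mean-centering; for a single response each weight
vector is X′y (normalized) exactly, no inner iteration.  Collapsed
coefficients are B = W(P′W)⁻¹q.  The LV count minimizes 5-fold RMSECV
over the path 1..15 (ties → fewer LVs); LOOCV is reserved for reported
metrics.  SVR is RBF ε-SVR on training-standardized inputs; (C, ε) are
grid-tuned by 5-fold RMSECV over C ∈ {1,10,100,1000}, ε ∈ {1,5,10,20}
ppm (ties → smaller C, larger ε) and then frozen for all models in a
run.  R² is computed about the mean of the actual values of the
evaluated set; RPD uses the prediction-set reference SD (ddof 1).
The 70:30 split takes round(0.7·n) training samples uniformly at random
(unstratified by default; stratification by day group is available).

**Subset evaluator.** Selection needs 5-fold PLS RMSECV for thousands of
band subsets.  k CGLS iterations on the centered normal equations
produce the least-squares fit over the k-step Krylov subspace, which is
exactly the k-LV PLS1 fit, and the restriction of the gradient X′r to a
band subset commutes through the recurrence.  All subsets in a chunk
therefore share one dense centered training matrix and evaluate as a few
(n × p)(p × chunk) GEMMs per iteration — no per-subset copies or
deflation.  Equality with scalar NIPALS is asserted to 10⁻¹⁰ in tests.

## Wavelength selection

**CARS** (n_runs = 50, Monte-Carlo ratio 0.8): at run i a random 80%
sample subset is fit by PLS on the surviving bands; normalized |β|
weights drive weighted sampling without replacement within a retention
budget ⌈rᵢ·p⌉, where the exponentially decaying ratio rᵢ = a·e^(−kᵢ) is
pinned to keep all p bands at run 1 and exactly 2 at run N.  Each run's
surviving set is scored by full-sample 5-fold RMSECV (minimized over the
LV path); the best-scoring run's set is returned, with the full trace
(retained counts, RMSECV path, |β| history) kept for plotting.

**IRIV** (inclusion probability 0.5): each round draws a binary
inclusion matrix over surviving bands (rows forced to ≥ 2 bands),
scores every row, and for each band pairs the rows containing it against
the same rows with that band flipped out.  A two-sided Mann–Whitney test
(exact by enumeration for m+n ≤ 12, normal approximation with tie and
continuity correction otherwise) on the two RMSECV samples classifies
the band as strongly/weakly informative (exclusion worsens RMSECV; p
below/above α = 0.05) or uninformative/interfering (otherwise); the
latter two are dropped and rounds repeat until stable.  The library
default is 500 rows per round; benchmark suites use 150 rows, which
gives ≈ 75 pairs per band — ample power for the planted-structure tests
at a fraction of the runtime.

**Backward elimination**: repeatedly remove the band whose removal
yields the lowest evaluator RMSECV, accepting while RMSECV does not
worsen by more than `tolerance` (default 0; ties remove the lowest
band index).  A genuinely useless band can still sit at a statistical
near-tie — it costs one latent variable but barely moves the best
RMSECV — so small positive tolerances ("a near-tie is not a decline")
make elimination decisive when that matters.

All three selectors are deterministic given (inputs, seed); folds are
fixed per call from the seed.

## Orchestration

`RunConfig` → `run_experiment` executes chain × selector × regressor
combinations sequentially, each stage seeded by
`SeedSequence((global_seed, crc32(stage_name)))` so any stage can be
re-run in isolation; identical config + seed reproduces the report
byte-for-byte.  A failed combination is logged and skipped, the rest
continue.  Reports are CSV (+ markdown), selections JSON, config YAML.

## Numerical notes and limitations

- NIPALS stops extracting when the weight norm falls below 1e−13 (rank
  exhaustion); predictions then freeze along the LV path.
- PLS/OLS equivalence at full rank holds to 1e−8 and is tested; scores
  are mutually orthogonal to the same tolerance.
- The CGLS subset evaluator runs in float64; CARS/BE comparisons use it
  and the scalar NIPALS path interchangeably.
- Benchmark suite sizes (20 seeds; IRIV 150 rows; 5 benchmark seeds in
  the acceptance script) are desk-scale choices; statistical thresholds
  (e.g. ≥ 8/10 bands in ≥ 80% of seeds) were verified against those
  sizes.
- Printed wavelength fixtures do not sit exactly on the uniform
  acquisition grid (e.g. 1166.3 nm); they are matched by nearest band,
  which is unique for every fixture list.
- No MSC/detrending variants, no per-pixel TGA maps, no radiative
  transfer or greening kinetics: the package models the analysis chain,
  not tuber physiology.
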