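# Methods

`octexture` re-implements, as a tested pipeline, a texture-based analysis
of macular OCT volumes that discriminates healthy-control (HC),
Alzheimer's-disease (AD) and Parkinson's-disease (PD) eyes.  Because no
patient data are available, every stage runs against a synthetic cohort
generator; this note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Pipeline

For each eye:

1. **Mean-value fundus (MVF) images.**  Given the intensity volume and the
   segmented boundary surfaces of the six inner retinal layers (RNFL, GCL,
   IPL, INL, OPL, ONL), the MVF image of a layer is the en-face map of the
   mean A-scan intensity between the layer's two interfaces.  The depth
   segment is half-open `[upper, lower)` after rounding boundary depths to
   the voxel grid; a zero-extent layer falls back to the nearest boundary
   voxel.  Left eyes are mirrored horizontally once, so all downstream
   arrays are in right-eye orientation (columns temporal → nasal, rows
   superior → inferior).

2. **Local texture (80 features/layer).**  The MVF image is resampled to
   128x128 (exact local-mean pooling for integer factors, anti-aliased
   resampling otherwise), quantised into 16 equal-width grey bins of its
   own range, cropped centrally to 126x126 and tiled by 7x7 blocks of
   18x18 px.  For each block, grey-level co-occurrence matrices (GLCMs;
   symmetric, normalised, unit distance) are computed in four directions
   (0°, 45°, 90°, 135°) and 20 metrics are taken per matrix; the supremum
   over directions is the block's value.  Block values are averaged per
   macular quadrant over the 3x3 corner blocks, excluding the central row
   and column through the fovea: 4 quadrants x 20 metrics.

3. **Global texture (6 features/layer).**  A one-level dual-tree complex
   wavelet transform of the same 128x128 resampled (un-quantised) image
   yields six directionally selective complex subbands (±15°, ±45°, ±75°);
   the feature is the population variance of the coefficient magnitudes
   per subband.  Detail subbands have no DC response, so these features
   are invariant to additive intensity offsets.

4. **Classification.**  One binary RBF-kernel SVM per (layer, class-pair):
   3 pairs x 5 layers = 15 models by default (18 when the RNFL is
   included).  Features are z-score normalised with training-fold
   statistics; each model uses exactly 6 features chosen by greedy forward
   selection.  An eye gets one vote per (layer, pair) decision; strict
   plurality wins, a three-way tie is "Unknown", a two-way top tie is
   broken by the pairwise sub-tally between the tied classes (itself tied
   → "Unknown").  Evaluation is repeated stratified k-fold
   cross-validation; reported indicators are distributions over runs
   (max / Q3 / median / Q1 / min, linear-interpolation quantiles).

## The 20 GLCM metrics

The source analysis never enumerates its 20 metrics, so the set here is
the extended-Haralick collection most consistent with the named measures
(IMC1/IMC2 appear by name): autocorrelation, contrast, correlation,
cluster prominence, cluster shade, dissimilarity, energy, entropy,
homogeneity, maximum probability, variance (sum of squares), sum average,
sum variance, sum entropy, difference variance, difference entropy, IMC1,
IMC2, inverse difference normalised, inverse difference moment
normalised.  Conventions: grey levels are indexed 0–15; entropies are in
bits; the entropies inside IMC1/IMC2 use natural logs as in their
classical definitions; sum variance is the variance of the i+j marginal
about the sum average; degenerate marginals give correlation 0 and IMC1 0.
The metric set is a single table in `texture.py` and is deliberately easy
to swap.

## Numerical and design choices

- **ETDRS grid**: central disc radius 500 µm, inner annulus 500–1500 µm,
  outer 1500–3000 µm; quadrants split at the ±45° diagonals, diagonal
  pixels assigned to the horizontal (temporal/nasal) quadrants.  A pixel
  belongs to the sector containing its centre; grids may fall 1% short of
  the 3000 µm radius (a nominal 6 mm field on a power-of-two grid does).
- **126 vs 128**: 128 is not divisible by 7; the quantised image is
  cropped centrally by one pixel per side, preserving the foveal
  alignment of the centre block row/column.
- **DTCWT level-1 filters**: only level 1 is used, where any odd-length
  symmetric biorthogonal pair admits the dual-tree phase construction.
  The CDF 9/7 (Antonini) analysis pair, taken from PyWavelets
  (`bior4.4`), is used with symmetric boundary extension; subband
  ordering is (+15°, +45°, +75°, −75°, −45°, −15°).  Orientation
  selectivity is verified in the tests with oriented gratings at all six
  subband angles.
- **Forward-selection scorer**: stratified 3-fold cross-validated
  accuracy inside the training fold, computed with the same RBF SVM that
  is finally trained (via scikit-learn's low-level libsvm binding for
  speed; prediction-identical to `SVC`, which is asserted in the tests).
  Ties break to the lowest feature index, which makes selection
  deterministic.  `internal_cv` is configurable.
- **SVM hyperparameters**: C = 1; gamma = 1/(d · mean feature variance)
  for d selected features (≈ 1/6 on z-scored features).  Only the kernel
  family is inherited from the source analysis; these defaults are the
  package's own.
- **Partition unit**: subject-level stratified folds by default (both
  eyes of a subject in one fold) — eye-level splitting would leak the
  within-subject texture correlation into the test folds.  `unit="eye"`
  reproduces the laxer reading.
- **Selection placement**: per training fold by default (leak-free);
  `selection="global"` reproduces the variant that selects once per run
  on all data, which is optimistic by construction.
- **Specificity with an Unknown column**: Unknown predictions are
  negatives for every class — they reduce sensitivity and accuracy and
  can only help specificity.  Empty denominators yield NaN, never a
  silent 0.

## Synthetic cohort generator

Each layer's texture is a stationary Gaussian random field: white noise
smoothed by an anisotropic Gaussian kernel (`correlation_length_x/y`, in
en-face pixels), standardised to unit variance, scaled by
`contrast_gain * noise_sd` and shifted by `base_intensity`.  Boundary
surfaces are flat per-layer thicknesses (RNFL 35, GCL 40, IPL 35, INL 35,
OPL 30, ONL 80, photoreceptor complex 65 µm; 320 µm ILM→RPE total)
deformed by a radially symmetric Gaussian foveal pit (default depth
90 µm, radius 500 µm) whose displacement fades with the fraction of
tissue below each boundary — the pit thins the centre by exactly its
depth and can never cross boundaries — plus a gentle smooth undulation
common to all boundaries (thickness-neutral scan tilt).  The resulting
central-subfield thickness (~250 µm) sits inside the published
healthy-adult range.  Two eyes per subject share a fraction
`within_subject_correlation` (default 0.5) of each texture field via a
variance-preserving mixture; the left eye is the exact horizontal mirror
of the right-eye geometry.  Every (subject, eye, layer) has a named RNG
substream, so enlarging a cohort never perturbs existing subjects.

The default acquisition grid is 512x128x128 voxels at (11.7, 47, 3.9) µm,
approximating a 6x6 mm macular cube.  The simulation studies use a
reduced grid — 256x128 A-scans at (23.4, 47) µm with 64 depth voxels at
7.8 µm — which preserves ETDRS coverage and the 128x128 texture geometry
at a quarter of the volume.

Class effects are illustrative knobs, not disease claims: AD texture is
coarser and higher-contrast (correlation lengths 16/4 px, gain 1.35), PD
texture elongated and lower-contrast (24/2 px, gain 0.8, noise 10)
relative to HC (8/2 px, gain 1.0, noise 12).  `effect_scale`
interpolates toward HC; 0 gives the null cohort.

**What the generator does not emulate**: OCT speckle statistics, vessel
shadows, motion artefacts, device noise spectra, focal (non-stationary)
pathology, and between-eye surface differences (a subject's two eyes
share one mirrored geometry — thickness analyses therefore use one
observation per subject).  Passing end-to-end tests show the pipeline
recovers class-conditional *stationary texture* differences; they are
silent on whether real AD/PD retinas differ this way.  A side effect of
stationarity: the four quadrants are statistically exchangeable, so
selected-feature origin tallies concentrate on the first-listed quadrant
through the deterministic tie-break and carry no regional meaning here.

## Reference studies and problem sizes

- **Strong-effect study**: 20 subjects/class (120 eyes), k = 10, 20 runs,
  layers GCL/IPL/INL/OPL/ONL.  Expected: median cross-validated accuracy
  well above 85%.
- **Null study**: 12 subjects/class (72 eyes), k = 5, 6 runs with
  `effect_scale = 0`.  Expected: mean accuracy within Monte-Carlo error
  of 1/3.  The Monte-Carlo SE is taken as the larger of the between-run
  SE and the binomial SE over eyes (runs share one cohort, so the
  run-to-run spread alone understates the uncertainty).
- **Calibration**: the per-sector one-way ANOVA rejects at ~5% under
  2000 null replicates; Pearson feature–thickness correlation recovers
  ρ ∈ {0, 0.7} within sampling error.

## Known limitations

- Real Cirrus volumes and OCT-Explorer surface files are out of scope;
  the real-data path expects plain numeric arrays in the documented axis
  conventions.
- The exact 20-metric list, GLCM distance, and whether the supremum also
  ran over scales are unrecoverable from the source text; distance 1 and
  direction-only suprema are implemented, with the metric table pluggable.
- The two-way tie-break ("the result of the classification between those
  two classes") is read as the majority of the pairwise sub-tally and is
  isolated in a single function (`classify._resolve_votes`) for easy
  revision.
- Published patient-level results (thickness tables, sensitivity/
  specificity distributions) derive from undeposited clinical data and
  are not reproduction targets; synthetic results are compared only
  against the generator's own ground truth.
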