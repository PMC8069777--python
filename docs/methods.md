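# Methods

This note documents the models, conventions and numerical choices behind
`echotexture`, and what its synthetic-data tests do and do not establish
about real ultrasound data.

## Coordinate and naming conventions

Images are 2-D arrays indexed `pixels[y, x]`, 0-based, with `y` (rows)
increasing downward and `x` (columns) rightward — the on-screen raster
convention. ROIs are half-open rectangles `[x0, x0+w) × [y0, y0+h)` with a
minimum side of 16 px (needed by offset-5 co-occurrence matrices and a
depth-2 wavelet decomposition). Co-occurrence offsets are written
`S(dx,dy)` with `dx` columns rightward and `dy` rows downward, so `S(d,d)`
pairs run down-right as displayed and `S(d,−d)` up-right; the 45° run-length
direction scans lines running up-right, step `(+1,−1)`. The source material
names these descriptors but does not define its axes; a single
self-consistent convention was required and this one is used throughout.

## Quantization

Each texture family sees the patch requantized to `2^bits` levels: GLCM 6,
run-length 4, wavelet 12 and gradient 8 bits (the latter two are no-ops on
8-bit input under the default full-scale mapping). Three normalization
modes are provided and recorded with the output:

* `roi-minmax` (default): the patch's own `[min, max]` is mapped linearly
  onto `[0, 2^bits − 1]`, rounding to the nearest level; a constant patch
  maps to all zeros.
* `plus-minus-3-sigma`: `[μ − 3σ, μ + 3σ]` with clipping.
* `full-range`: the fixed range `[0, 255]`.

The original MaZda analysis does not state which of its normalization
options was used; this shifts absolute GLCM/run-length values, which is one
reason exact numeric parity with that binary is not claimed (see
Limitations).

## Descriptor families

**Histogram.** Mean, population variance, skewness, excess kurtosis and
percentiles 1/10/50/90/99 of the raw intensities. Percentiles use the
inverted-CDF rule (the smallest observed intensity whose cumulative
frequency reaches the level), so they are always observed gray values.

**Gradient.** `G(x,y) = √((I(x+1,y)−I(x−1,y))² + (I(x,y+1)−I(x,y−1))²)`
over interior pixels; moments of `G` plus the fraction of non-zero
gradients. Kurtosis is excess kurtosis (a normal gradient map gives 0),
verified against a moment oracle on 10⁶ normal draws.

**Autoregressive model.** The causal four-neighbour model
`f(x,y) = θ₁f(x−1,y) + θ₂f(x,y−1) + θ₃f(x−1,y−1) + θ₄f(x+1,y−1) + e(x,y)`
is fitted by ordinary least squares on the mean-subtracted patch over all
sites whose four neighbours exist; `Sigma` is the residual SD. The
published neighbour ordering/sign convention is not documented; this
ordering is consistent with the published group-level value `Teta2 ≈ −0.45`
(strong negative coupling to the pixel above in speckled texture) and is
validated by parameter recovery: over 20 seeded 256×256 patches generated
by the same recursion (θ = 0.3, −0.45, 0.05, 0.10; σ = 5) the mean absolute
estimation error is below 0.03. The minimum-norm least-squares solution is
used when the normal equations are singular; a patch with no variation
reports all five outputs as undefined.

**Co-occurrence.** For each of the 20 offsets {(d,0),(0,d),(d,d),(d,−d),
d = 1..5}, pairs and their reverses are accumulated (symmetric matrix) and
normalized to sum 1 — required for the standard Haralick marginals. Eleven
descriptors per matrix (AngScMom, Contrast, Correlat, SumOfSqs, InvDfMom,
SumAverg, SumVarnc, SumEntrp, Entropy, DifVarnc, DifEntrp) with 0-based
gray-level indices and `0·log 0 ≡ 0`. The entropy logarithm base is
configurable (natural log by default); the published descriptor magnitudes
cannot disambiguate the base, so it is exposed in `QuantizationConfig`.
Correlation of a zero-variance matrix is flagged undefined.

**Run-length.** Maximal constant-level runs along every lattice line in
four directions (horizontal, vertical, up-right, down-right). The matrix
stores raw counts; normalization by the total run count `C` happens inside
each of the five Galloway descriptors (ShrtREmp, LngREmp, GLevNonU,
RLNonUni, Fraction), matching the classic definitions. Note that on a
checkerboard the axis-aligned scans see only length-1 runs while the
diagonal scans see constant lines — orientation sensitivity is the point
of the family.

**Wavelet.** Orthonormal Haar decomposition of the largest centered
dyadic square (no padding), up to five scales; per scale the mean squared
coefficient of each subband (LL, LH, HL, HH; HL holds the detail along x).
Energies satisfy Parseval's identity at full depth, which is the
correctness oracle. Wavelet features are completeness-only: they are not
inputs to the prediction equation.

Degenerate statistics (zero variance, singular fits) are reported as NaN
and collected in `FeatureVector.undefined`, never silently zero-filled, so
downstream selection can exclude them explicitly.

## ROI sampling

Manual ROI selection is emulated by drawing a target area from
N(33 952.15, 15 146.17²) px² — the observed mean ± SD of manually drawn
rectangles — clipped to what the image can hold, with aspect ratio
(width/height) uniform in [0.5, 2.0] (unstated in the source; configurable)
and position uniform over valid placements. Clipping, rather than
resample-truncation, keeps the realized mean area within ~70 px² of the
target on large images; resampling the lower tail would bias it upward by
~500 px². The minimum ROI is 16×16. Constraints of real scans (muscle
boundaries, artifact avoidance) are not modelled; the package takes one
chosen image per sample and does not score image quality.

## Prediction, grouping, stepwise selection

`predict_imf` is a pure linear evaluation; any missing or undefined
required descriptor raises an error naming it. The default grouping uses
the published cutoffs (group 1 ≤ 4.24 %, group 3 ≥ 5.76 %, both outer
boundaries inclusive); `derive_cutoffs` recomputes mean ± ½SD (sample SD)
with the same boundary semantics. The published cutoffs are *not* exactly
mean ± ½SD of the published cohort moments (5.10 ± 0.72 → 4.38/5.82); both
schemes are therefore provided and the discrepancy is left documented, not
resolved.

`stepwise_select` is classic forward–backward stepwise OLS on partial
t-test p-values with entry/stay thresholds of 0.15 (the common SAS
default; configurable) and an in-loop collinearity gate: a candidate whose
entry would push any variance inflation factor to ≥ 10 is skipped with a
log entry. Candidates containing undefined values are dropped up front.
Selection stops when the residual sum of squares is numerically exhausted
(relative tolerance 1e−12), which makes noise-free recoveries terminate
cleanly. `vif` is computed as 1/(1−R²) per column and cross-checked against
the inverse-correlation-matrix diagonal.

## Validation battery

* **ROC**: positive class = IMFqa above the low cutoff (groups 2+3),
  decision rule "score ≥ threshold". AUC is the Mann–Whitney midrank
  statistic (equal to the trapezoid area under the empirical curve; both
  routes are computed and asserted equal in tests). The Youden cutoff
  maximizes sensitivity + specificity − 1 with ties broken toward the lower
  threshold. The 95% CI uses DeLong's structural-components estimator.
  LR+ is computed from the package's own sensitivity/specificity; the
  published LR+ (16.97) is inconsistent with the published 88%/90%
  operating point (which implies 8.8) and is not reproduced.
* **Bland–Altman**: differences are IMFqa − IMFpred (sign conventions vary;
  this one matches the published mean difference of −0.04 ≈ 5.10 − 5.13);
  limits are mean ± 1.96·SD (sample SD, literal 1.96 rather than a
  t-quantile).
* **Kruskal–Wallis**: tie-corrected H with a χ² p-value on k−1 df
  (delegated to scipy), plus Dunn z-tests on pooled midranks with the tie
  correction and Bonferroni multiplication by k(k−1)/2. An all-identical
  pooled sample returns H = 0, p = 1.
* **Agreement summary**: R² as the squared Pearson correlation; a constant
  series makes the correlation undefined, reported as 0 with a warning.

## Synthetic data: what it does and does not show

The cohort generator draws (IMFqa, IMFpred) from a bivariate normal with
means 5.10/5.13 %, SDs 1.44/1.31 % and correlation √0.76, so its population
R² equals the published determination coefficient exactly and the
population SD of differences is 0.7075 %, giving limits of agreement
+1.356/−1.416 — within ~1.5 % of the published +1.34/−1.42. Matching the
marginals does not pin down the small-sample operating point of the ROC:
the population AUC of this generator (~0.926) is close to the published
0.9176, but the published sensitivity/specificity/cutoff (88 %/90 %/4.50)
were computed on 27 animals with a feature-conditional error structure the
generator does not model; tests therefore assert a plausible band for the
operating point (cutoff in [4, 5], both rates ≥ 0.75) rather than exact
reproduction.

The feature-cohort generator draws the seven equation descriptors
independently within groups from the published per-group means/SDs — no
covariances are published, so independence is a deliberate simplification,
adequate for exercising stepwise selection (the equation's seven terms are
recovered with coefficients within 10 % at n = 300 under 0.3 % response
noise) and group statistics, but not the real joint feature distribution.

The image generator (smooth echo level × unit-mean Rayleigh speckle +
bright elliptical deposits) produces qualitatively marbling-like texture:
streak density monotonically increases diagonal co-occurrence contrast,
and the speckle histogram is right-skewed. It makes no claim of acoustic
realism (no point-spread function, attenuation or scan conversion), and
its descriptors do **not** live on the absolute scales of real muscle
sonograms — applying the prediction equation to them yields out-of-range
IMF values. Passing image-based tests demonstrates the extraction
machinery, not field accuracy.

## Problem sizes and tolerances

Cohort-level checks use n = 10⁵ (agreement statistics; Monte-Carlo error on
R² ≈ 0.002) and n = 10⁴ (ROC). Oracle agreement uses 100 random patches up
to 16×16 at 1e−10..1e−13 absolute tolerance; AR recovery uses 20 seeds at
256×256; Kruskal–Wallis calibration uses 1 000 label permutations with a
Kolmogorov–Smirnov check at α = 0.01. All randomness flows through
seeded `numpy.random.default_rng` streams, so every test and the
acceptance script are reproducible bit for bit.

## Known limitations

* Exact numeric parity with the original MaZda binary is guaranteed only
  for the documented formulas; normalization mode, entropy base and the
  AR neighbour convention of that tool are not fully documented upstream.
* The descriptor count (279) is asserted as ≥ 250 across exactly six
  families; the original "~300" may include configuration-dependent
  duplicates.
* No image pre-processing, despeckling or quality scoring: scans are taken
  as-is, mirroring the source workflow.
* The three-group classification and the validation battery refer to
  chemically quantified IMF as ground truth; `predict` falls back to
  grouping by predicted IMF when no ground truth is supplied, while
  `validate` requires a complete IMFqa column.
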