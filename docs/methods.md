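# Methods

This note documents the models and procedures implemented in `mitedamage`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical decisions a maintainer should know about.

## The measurement problem

Spider-mite feeding produces chlorotic spots on Arabidopsis leaves; the
phenotype of interest is the total chlorotic area per rosette in mm².  The
difficulty is not resolution but specificity: pale tissue that is *not*
damage — trichome-rich glints, young-leaf pallor at the rosette centre,
brightened leaf margins — is abundant, varies between plants, and is what a
naive classifier detects on perfectly healthy controls.  The pipeline
therefore has two explicit error-removal stages on top of classification:
a cluster-size noise filter and a control-based correction, both calibrated
from uninfested plants of the same genotype scanned under the same
conditions.

## Physical calibration

A scan's pixel pitch follows from its dpi metadata: one pixel covers
`(25.4 / dpi)²` mm².  Areas are always pixel counts times this constant.
Reading a file without dpi metadata is an error unless an explicit override
is supplied; silently assuming a resolution would corrupt every area
downstream.

## Scanner condition emulation

Flatbed scanner brightness/contrast settings are modelled as a per-channel
linear map about mid-gray,

    out = clip[ gain(C) · (in − 128) + 128 + B ],
    gain(C) = 259·(C + 255) / (255·(259 − C)),

the standard 8-bit contrast curve.  `gain(0) = 1`, so brightness alone is
an exact additive offset in counts — a "+10 brightness" condition moves
every non-saturated pixel by exactly 10.  Real scanner firmware is
undocumented; this mapping is monotone, identity at zero, and sufficient to
replay a condition grid on a fixed scene.  `ScanCondition` stores
brightness and contrast as named fields because published condition tables
are ambiguous about their order.

## Segmentation

Plant pixels are those whose RGB Euclidean distance from the background
reference (pure white or pure black per the background tag) exceeds 60
counts (configurable); the largest connected component is kept and its
holes filled (a strongly bleached lesion interior can otherwise fall out of
the mask on a white background).  On synthetic scans this reproduces the
true rosette mask with Jaccard ≥ 0.95 and total area within 5%, and the
masks obtained from the same plant rendered on white and black backgrounds
agree with Jaccard ≥ 0.9.

## Damage classifiers

**Random forest (the recommended method).**  Per-pixel features are raw
RGB plus, at each smoothing scale σ ∈ {1, 2, 4, 8} px: Gaussian-smoothed
RGB, gradient magnitude, Laplacian of Gaussian, and the two structure-
tensor eigenvalues of the intensity channel (3 + 7·|scales| features).
A 100-tree forest is trained on sparse annotations of three classes
(background / healthy / damaged); bootstrapping of the labelled pixels
happens inside the forest's per-tree bagging.  Ties in the arg-max are
broken by the fixed class order background < healthy < damaged for
determinism.  The per-pixel uncertainty `1 − (p₁ − p₂)` (top minus
runner-up probability) ranks pixels for the annotate-where-uncertain
retraining loop; adding labels in the top decile measurably lowers mean
uncertainty on held-out scans.  Forest size and feature recipe are package
defaults chosen to mirror common interactive-segmentation practice, not
reconstructions of any particular tool's internals.

**Colour threshold.**  Two fixed-boundary selections: stage 1 keeps pixels
whose value on one plane of {R, G, B, H, S, I} lies in [lower, upper]
(rosette selection), stage 2 marks damage within that selection by a second
rule.  HSI follows the standard geometric conversion: I = mean(R,G,B),
S = 1 − min/I, H the arccos form in degrees with H = 0 on degenerate
(gray) pixels.  The default tuned rules for the synthetic palette are
I ∈ [25, 235] (rosette; excludes both backgrounds) then H ∈ [0, 80]°
(yellowish tissue).  This strategy inevitably marks pale-yellow confounder
specks as damage — the behaviour the control correction exists to fix.

**Grid mean-colour rule.**  The image is tiled into squares of a chosen
physical size; for each square overlapping the rosette the mean RGB of its
rosette pixels is taken and the square is marked damaged when the
green-deficiency score `g = mean(R, B) / max(meanG, 1)` exceeds a cutoff.
Sensitivity levels 1..9 map to the strictly decreasing cutoff ladder
0.92 − 0.04·(s−1), so marked sets are nested in sensitivity.  The score and
ladder are this package's concrete stand-in for the undocumented
"lack of green" detectors in legacy leaf-analysis tools.

**Manual-grid emulator.**  The manual reference protocol is emulated by
overlaying a grid of `grid_size` mm squares (0.25 mm by convention) on a
damage annotation and counting squares — either any-overlap (≥ 1 damaged
pixel, the practice the protocol implies) or majority (> 50% of the
square's pixels).  Under any-overlap the counted squares geometrically
cover every damaged pixel, so the returned area is provably ≥ the
pixel-exact area, with strict excess whenever lesions do not tile the grid
exactly: whole-square counting is an overestimator by construction, which
is why automatic pixel-level methods read systematically *below* the
manual standard.

## Noise filter and its calibration

Connected components of the damage mask smaller than `min_size` pixels are
removed (8-connectivity by default; strictly smaller is removed, equal is
kept, reading "under the threshold" literally).  The threshold is
calibrated by pooling component sizes across control-rosette damage masks —
controls are damage-free, so every cluster there is a false detection — and
taking the mean, rounded half-up to an integer; the size-frequency table is
returned alongside for inspection.  Pooling across genotypes is the
default; per-genotype calibration is available through grouping.  The
filter is used in the machine-learning pipeline; the plain threshold
pipeline runs without it (its historical counterparts had no such stage)
and relies on the control correction alone.

## Control correction

For each (genotype, condition, background) group, the mean control damage
fraction x̄_c = Σ(DA_ci/TA_ci)/n is fitted from controls and subtracted
from each treated rosette scaled by its total area: A_i = DA_ti − x̄_c·TA_ti.
The correction is linear in TA and can never raise a value above DA.
Non-positive corrected values — controls apparently "more damaged" than the
treated plant — are retained as explicit missing records with status
`dropped_nonpositive`, so quotient tables and agreement reports can state
their attrition instead of silently shrinking.

## Agreement statistics

Paired differences d_i = x_i − y_i (absolute mode) or
(x_i − y_i)/((x_i + y_i)/2) (percent mode; the pairwise mean is the
denominator).  Bias is the mean difference; limits of agreement are
bias ± 1.96·sd with the sample (n−1) standard deviation; pairs with either
side missing are excluded and counted.  The coefficient of repeatability is
CR = 1.96·sd(d), with a 95% CI obtained from the chi-square distribution of
the variance with n−1 degrees of freedom (the CI method is this package's
choice; published CR tables rarely state theirs).  Lin's CCC uses
population (1/n) moments, matching Lin's original estimator, with a 95% CI
from the Fisher z-transform and Lin's large-sample standard error; the
identity |ccc| ≤ |pearson| holds by construction, with equality only under
zero location and scale shift — a method with a constant bias is penalised
on CCC even at perfect correlation.  Spearman correlation (average ranks
for ties) delegates to scipy.  Damage quotients are ratios of group means
of corrected areas, excluding and counting dropped values.

## Synthetic scans

The generator renders what the downstream stages need to be tested on, not
photorealistic plants:

- **Geometry** — n elliptical leaf blades with thin petiole rectangles
  radiating from a centre, with per-leaf length/width/angle jitter;
  enclosed gaps between petioles are filled as centre tissue (real rosette
  centres are solid).  The scan window is 2.5 × rosette radius.
- **Damage** — irregular elliptical lesions (lognormal areas, mean
  0.8 mm², CV 0.6) are added inside leaf tissue until the damaged pixel
  count reaches `damage_fraction` of rosette pixels; the last lesion is
  trimmed to land on the target, so the truth fraction is exact up to
  rounding.  Lesion colour interpolates 70–100% toward pale yellow-white
  (235, 228, 170).
- **Confounders** — trichome-glint specks (pale yellow, ~4 per cm² of
  rosette, lognormal sizes with median 5 px at 150 dpi), a pale young-leaf
  centre disk, and a 1-px lightened leaf-margin band.  Specks share the
  chlorosis hue; margins and the pale centre are light *green* — pallor in
  lightness, not yellowness.  All are labelled `confounder` in the truth,
  never `damaged`, and controls carry them in full: this is what makes the
  correction stage non-trivial.
- **Rendering** — per-leaf base greens with per-pixel noise; uniform white
  (252) or black (5) background with mild noise.  White and black renders
  of the same seed share the random stream and hence identical geometry
  and truth.
- **Annotation emulation** — sparse training labels are sampled from the
  truth: background, healthy (including margins and pale centres, which a
  rater recognises as tissue — the counterpart of annotating the
  software's uncertain areas), and damaged.  Specks are never labelled;
  they are the ambiguity the classifier genuinely confuses with damage.

What the generator does **not** emulate: leaf venation, mite bodies and
webbing, specular reflection, colour-profile effects, multi-rosette plates
with rulers, or any quantitative lesion-morphology model — lesion size
parameters are free choices documented here, not claims about real mites.
Consequently, passing tests demonstrate that the pipeline machinery
(segmentation, classification, calibration, correction, statistics) is
correct and self-consistent under realistic confounding, not that any
particular accuracy figure transfers to real scans.

## Problem sizes used in validation

Synthetic validation runs use 150 dpi scans (≈ 0.17 mm pixels).  The
reference cohort is three genotypes spanning the susceptibility spectrum
(damage fractions 0.01 / 0.015 / 0.05, rosette radius 14 mm) with eight
treated and eight control replicates each — replicate counts follow common
phenotyping practice — trained on six scans with 400 labels per class.
The correction-utility experiment uses twenty independent single-genotype
cohorts (damage fraction 0.04, radius 12 mm, 8 + 8 replicates) quantified
with the threshold strategy on a white background, where confounding is
strongest.  These sizes keep a full validation run in the tens of seconds
on one CPU while leaving every effect being tested (ordering, quotient
recovery, correction benefit, bias signs) far from its decision boundary.

## Numerical and determinism notes

- All randomness flows through `numpy.random.default_rng` seeds; cohort
  members get child seeds drawn deterministically from the cohort seed.
  The random forest is seeded and single-threaded; repeated runs of a
  pipeline with the same configuration produce byte-identical CSVs.
- Derivative features use float64 intensity; scipy's truncated
  Laplacian-of-Gaussian kernel leaves a ~1.5·10⁻⁴ relative residual on
  uniform regions, which is below any decision threshold used.
- PNG stores pixel density in dots per metre; on read, dpi within 0.05 of
  an integer is snapped back so integer scanner settings round-trip.
- Degenerate inputs are errors, not warnings: empty control lists, masks
  with no clusters to calibrate on, constant inputs to correlation, zero
  variance in CCC, mixed groups in a correction fit.

## Known limitations

- The hue/intensity threshold defaults are tuned to the synthetic palette;
  real scans need their own rules (the two-stage mechanism is general).
- The cluster threshold couples to confounder size: if false-detection
  clusters approach lesion size, the mean-size rule starts eating real
  lesions.  The size-frequency table is exposed so this can be checked.
- Lin's CCC confidence intervals use the large-sample normal theory and
  are unreliable below ~10 pairs.
- The generator's damage model places lesions uniformly over leaf tissue;
  real feeding damage aggregates along veins and leaf bases.
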