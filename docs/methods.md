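# Methods

## Pipeline overview

`hsdetect` classifies unilateral hippocampal sclerosis (HS) from two
imaging signs: subfield atrophy on T1-based volumetry and FLAIR
hyperintensity. The pipeline starts from segmentation outputs — it assumes
FreeSurfer-style hippocampal-subfield segmentation, coregistration of FLAIR
to the T1, and bias-field correction have been done upstream. The stages
run in this order:

1. parse per-hemisphere subfield volume tables and the
   `BrainSegVolNotVent` total brain volume (TBV);
2. head-size correction and reference z-scoring of subfield volumes;
3. (optional) FLAIR resampling to subfield space and cortex-referenced
   voxelwise z-scoring, reduced per subfield to a relative z-score;
4. assembly of the fixed-order 64- or 128-dimensional feature vector;
5. linear SVM classification (three-class, plus per-hemisphere binary);
6. evaluation with exact binomial intervals and exact McNemar paired tests.

## Subfield vocabulary

Sixteen subfields per hemisphere enter the features: CA1, CA3, CA4,
subiculum, molecular layer, and granule-cell/dentate-gyrus layer (head and
body each), the hippocampal tail, and three whole-structure aggregates
(head, body, whole hippocampus). Six further segmentation outputs —
hippocampal fissure, fimbria, HATA, presubiculum head/body, parasubiculum —
are excluded for low cross-group variability and no hypothesized HS
involvement. The *order* of the included list is frozen because it defines
the feature-vector layout; every trained model carries a schema identifier
and refuses mismatched inputs.

An alias table maps upstream naming dialects (e.g. `GC-ML-DG-head`,
`molecular_layer_HP-body`, `Whole_hippocampus`, underscore variants) onto
the canonical names, covering both the split (head/body) and legacy
unsplit table formats. Label codes in label volumes default to the
FreeSurfer hippocampal-subfield numbering with right-hemisphere codes
offset by +1000 (upstream ships one volume per hemisphere; we hold both in
one grid); both are configurable. Aggregate subfields are resolved to
unions of their component label codes; the fissure, a CSF space, never
counts toward an aggregate.

## Volume model

Subfield volumes co-vary with head size. The covariance correction fits,
in a healthy reference cohort, the OLS slope β of each subfield volume on
TBV, then shifts each subject's volume to the reference-mean head size:
`Vol_corr = Vol_orig − β (TBV_orig − TBV_mean)`. Corrected volumes are
z-scored against the reference distribution, `z = (Vol_corr − μ_NC)/σ_NC`.

Choices the upstream description leaves open, fixed here:

- **σ convention**: sample SD (N−1), conventional for z-scoring; used
  consistently for volumes and FLAIR cortex statistics.
- **Per-hemisphere slopes**: β, μ_NC, σ_NC are fitted per subfield *and*
  per hemisphere, since hemispheres are distinct features.
- **Atrophy inversion**: only negative z carries signal; the feature is
  `z_atrophy = max(−z, 0)`. Positive deviations map to exactly 0 rather
  than being dropped, keeping the vector dense and fixed-length.
- **Degenerate denominators**: corrected volumes can go non-positive at
  extreme head sizes. They are allowed in z-scores; in left–right ratios a
  non-positive *denominator* is clamped to 1 mm³ with a logged warning, so
  a pathological input degrades loudly instead of crashing.

Applying a fitted model to its own reference cohort yields z-scores with
mean 0 and SD 1 per subfield (checked to 1e-10), and all features are
invariant under a global rescaling of volumes and TBV.

## FLAIR model

Intensities are comparable across scanners only after within-subject
normalization. The whole-cortex mean and SD (voxels labelled as cortical
ribbon; label set configurable) reference every subfield voxel:
`z = (I − μ_cortex)/σ_cortex`. Cortex statistics are taken on the native
grid — the whole cortex — before the image is resampled to the subfield
analysis grid (0.333-mm isotropic by default, trilinear for intensity,
nearest-neighbour for labels, covering the subfield bounding box plus a
2-mm margin).

The per-subfield burden statistic sums the voxelwise z-scores strictly
greater than a threshold (default 1; configurable because other thresholds
are plausible) and divides by the subfield's *total* voxel count. The sum
is of the z values themselves, not of exceedances over the threshold and
not a count. Non-finite voxels are excluded from numerator and denominator
and logged.

Left–right ratio conventions for a statistic that can be exactly zero:
0/0 → 1.0 (the symmetric neutral value); x/0 with x > 0 → capped at a
configurable maximum (default 10) with a warning. Within these
conventions, features are invariant under any affine intensity map
I → aI + b (a > 0), monotone in any single voxel's intensity, and
non-increasing in the threshold.

2-D FLAIR acquisitions (thick slices) pass through the same pipeline after
resampling; the acquisition kind is recorded in the feature provenance so
models trained on 2-D and 3-D data are never silently mixed.

## Feature schema

Canonical ordering is hemisphere-major (left, right), subfield-middle
(atlas order), kind-minor (volume z-atrophy, volume L/R ratio, FLAIR
relative z, FLAIR L/R ratio) — 128 features with FLAIR, 64 without. The
ordering itself is an artifact decision (only the counts are externally
fixed); it is therefore versioned via the schema id embedded in feature
tables and model files. Class labels (`no_HS`, `left_HS`, `right_HS`) come
from a sidecar CSV, as diagnosis labels originate outside imaging.

## Classifier

Linear-kernel SVM with standard parameters: C = 1, no class weighting,
one-vs-one multiclass. Feature standardization is **off by default** (the
literal "standard parameters" reading) but available as a switch, because
it materially affects linear SVMs; both modes are tested. Models serialize
to versioned JSON (pairwise weights, intercepts, class order, optional
scaler, schema id), and prediction always runs from the serialized weights
— the one-vs-one vote (pairwise margin sign, ties broken by summed
margins) is implemented explicitly and pinned to scikit-learn's own
predictions in a test — so a save/load round-trip is exact by
construction.

## Evaluation

Stratified k-fold cross-validation (stratification avoids empty-class
folds at these class sizes; fold assignment is seeded and deterministic).
The point estimate is the mean of per-fold accuracies; the 95% interval is
the exact Clopper–Pearson interval of the pooled correct/total counts
(this pooled-count convention is what reproduces intervals such as
.939–1.0 for 59/59 and .772–.999 for 21/22). Per-hemisphere binary models
supply ROC-AUC (from continuous margins), sensitivity (recall on HS),
specificity (recall on no-HS), and F1. Intervals for AUC and F1 are not
binomial quantities; they are reported as count-based approximations and
flagged as such in the report structure.

The exact McNemar test compares two classifiers on the same subjects via
their discordant predictions: two-sided p = min(1, 2·P(X ≤ min(b,c))) with
X ~ Binomial(b+c, ½). This convention reproduces the reference p-values
(7–0 → .016, 6–0 → .031); the discordant splits themselves are forced by
the printed paired accuracies, a derivation documented in the test suite.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
the study's conditions by default:

- reference cohort n = 256; patient cohort 36 controls + 18 left + 18
  right HS;
- TBV ~ N(1.15×10⁶ mm³, (1.1×10⁵)²); subfield volume = baseline +
  slope·(TBV − mean) + noise, with baselines at plausible adult subfield
  magnitudes (whole hippocampus ≈ 3.5 cm³), slope = baseline/TBV_mean
  (proportional scaling), and Gaussian noise of 8% of baseline — a
  realistic inter-subject coefficient of variation for subfield volumetry;
- HS effects on the affected side only, in the classic pattern (CA1, CA4,
  granule-cell/dentate, molecular layer; aggregates inherit by summation):
  volume reduced by `atrophy_effect` noise-SDs (default 3, a clear-cut
  sclerosis) and FLAIR voxel z-scores offset by `hyperintensity_effect`
  cortex-SDs (default 2);
- image phantoms are schematic: a spherical cortical shell around two
  blocks of labelled boxes on a 48³ 1-mm grid, intra-tissue intensity
  spread 0.2 cortex-SD. Unlabeled voxels carry baseline tissue intensity
  so resampling blends toward baseline rather than background zero.

What passing synthetic tests shows — and does not. The generator
reproduces the *statistical* couplings (volume–TBV slope, side-specific
effects, cortex-referenced intensity offsets) but none of the hard parts
of real data: segmentation error, partial-volume effects, scanner and
protocol heterogeneity, bilateral or subtle HS, or non-Gaussian artifact
tails. Perfect synthetic cross-validation therefore validates the
machinery (features measure what was implanted; the classifier recovers
implanted classes; the statistics are exact), not clinical performance.

## Numerical and degenerate-input choices

- Zero TBV variance, constant subfield volumes, constant cortex intensity,
  or an empty cortex mask raise degenerate-data errors rather than NaN.
- Strict inequality z > threshold in the burden statistic (measure-zero
  difference in practice).
- Float-typed label volumes with integral values are accepted with a
  warning and cast; truly non-integral labels are rejected.
- Intensity/label grids may live on different voxel grids but must overlap
  in world space; disjoint frames (e.g. unit mismatches) are rejected
  before any computation.
- CSV round-trips use shortest-round-trip float formatting and
  `round_trip` parsing so serialized values are bit-exact.

## Problem sizes used in the checks

The test suite's end-to-end recovery checks use cohorts of 40 subjects per
class (120 total) over 20 seeds at 2-SD effects, 5 seeds at null effects,
and a single 200-subject cohort for the paired FLAIR-added-value
comparison — sizes chosen to make sampling noise negligible relative to
the asserted margins while keeping the suite quick to run.

## Known limitations

- Unilateral HS only; suspected bilateral disease would need a separate
  per-hemisphere model trained on isolated hemispheres, which is out of
  scope here.
- No alternative head-size corrections (proportional or ICV-residual
  variants) and no feature selection beyond the fixed subfield lists.
- The published tool's choices on two points are not documented and are
  surfaced as explicit configuration here: whether slopes pooled
  hemispheres (we fit per hemisphere) and whether features were
  standardized before the SVM (we default to off).
- Whole-structure aggregates amplify implanted atrophy relative to atomic
  subfields (a sum of shifted components has a larger standardized shift);
  this is a property of the aggregate definition, not a bug, but it means
  per-subfield effect sizes are not uniform across the feature vector.
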