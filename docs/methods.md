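# Methods

## Data model

A cohort is a list of subjects over one shared manikin raster
(width × height pixels, default 400×800; origin top-left, x rightward,
y downward, 0-based). Each subject carries a group label; zero or more
concern entries (a polygon outline, concern-type labels, affect labels with
a valence class, and an intensity rating on a 0–100 slider); optional
avatar slider settings over the 13 adjustable regions (neck, shoulders,
torso, bust, bicep, forearm, hands, hips, waist, buttocks, thighs, calves,
feet); optional tape measurements for the seven measured parts (shoulders,
bust, biceps, waist, hips, thighs, calves); demographics; and optional
usability items. JSON is the canonical on-disk format (one cohort per
file, schema shipped in `src/bodymap/schema/`); save∘load is the identity.

Affect labels from the controlled vocabulary carry a fixed valence class
(negative vs neutral/positive). Free-text affects default to
*unclassified* and are excluded from valence tallies unless the caller
flags a class explicitly — assigning a valence to arbitrary text would
inject analyst judgment into a tally that is otherwise mechanical.

Validation is total and itemized: every model invariant (polygon arity and
bounds, intensity and slider ranges, part names, positive measurements,
BMI consistency within 0.1 of weight/(height/100)²) is checked on both
load and save, and all violations are reported at once with subject id and
field name.

## Rasterization

A pixel belongs to an outline iff its center (col+0.5, row+0.5) is inside
the implicitly closed polygon under the even-odd (crossing parity) rule;
centers exactly on an edge are included (tolerance 1e-9 on the
perpendicular distance). Even-odd is orientation-independent and gives the
intuitive two-triangle fill for self-intersecting traces, which freehand
outlining produces in practice. A subject's concern mask is the union of
their entry masks, so a subject contributes at most 1 to any pixel of the
group proportion map regardless of overlapping concerns — proportions are
over participants, not outlines.

## Proportional maps and smoothing

The group proportional map is the arithmetic mean of binary subject masks
(exactly count/n per pixel). Spatial smoothing is isotropic Gaussian
convolution parameterized by FWHM, σ = FWHM/(2√(2 ln 2)) ≈ FWHM/2.3548
(FWHM 6 px → σ 2.5480 px), with reflective boundary padding (avoids
artificial darkening at silhouette edges) and truncation at 4σ (mass error
< 1e-4). Smoothing is applied to group proportion maps *before* z
computation and identically inside every permutation; by linearity this
equals smoothing per-subject masks and averaging, which is how the
permutation engine implements it (one convolution per subject, then every
permutation is a matrix product).

## Pixel-wise inference

The statistic is the pooled two-proportion z. Pixels with pooled
proportion 0 or 1 (no variability under the null) carry z = 0, p = 1 and
never form clusters. The test is two-sided via |z|: group differences run
in both directions across the body, so a one-sided map would have to be
run twice anyway.

Permutation p values use the add-one estimator
p = (1 + #{b : |z_b| ≥ |z_obs|})/(B+1), which is valid (never
anti-conservative in expectation) and bounded below by 1/(B+1).
Relabelings preserve group sizes and are drawn as uniform random subsets
of size min(n₁, n₂); because a subset and its complement induce the same
partition and the same |z|, sampled p maps are exactly invariant to
swapping the group labels.

Cluster correction: supra-threshold pixels (p < α, the cluster-forming
threshold equal to the final level α = 0.05 by default) are labeled with
8-connectivity; the null distribution of the *maximum* cluster extent is
built by applying the identical supra-threshold rule to each permutation's
map, and an observed cluster survives iff its extent reaches the (1−α)
quantile of that null (floored at 1 pixel). Thresholding a permutation's
map uses the same pooled-rank rule as the observed map: map *i* in the
pooled set of B+1 maps is supra at a pixel iff |z_i| strictly exceeds the
K-th largest pooled |z| there, K = ⌈α(B+1)⌉ — an exact restatement of
"p_i < α" that needs only a per-pixel top-K buffer. The engine therefore
runs in two passes over the same seeded permutation stream (p values and
thresholds first, null max extents second) and never stores all B maps;
memory is O(K · pixels).

The generator, seed, B, α and smoothing are recorded in the result, and
cluster correction refuses to run against mismatched provenance.

## Avatar calibration and discrepancy

Slider s ∈ [0, 1] converts to centimeters through two linear segments
through the anchors (0, m0), (0.5, m05), (1, m1), where the anchors are
in-engine measurements of the avatar part; equivalently the anchor ratios
m0/m05 and m1/m05 act as scale factors relative to the 0.5 baseline. The
inverse maps a representable size back to the slider exactly (round-trip
< 1e-9); out-of-range sizes raise with the representable interval in the
message. Anchors must satisfy m0 < m1 (invertibility); monotonicity
m0 < m05 < m1 makes the forward map strictly increasing.

The discrepancy score is perceived − actual cm per measured part
(negative = underestimation). The scaled body average is the mean over the
seven parts of size/reference; the reference defaults to the calibration
baseline (m05, the scanned volunteer's sizes) and is exposed as a
parameter, since any strictly positive per-part reference yields a valid
relative measure. Measured part "biceps" maps to slider region "bicep";
the other six names coincide.

## Synthetic cohorts

The generator emulates the study conditions so that inference can be
validated against known ground truth:

- **Groups.** Default sizes 65 ("model") and 38 ("nonmodel").
- **Concerns.** Named elliptical regions in normalized raster coordinates;
  each subject includes each region independently with the group's
  probability, drawing a 24-vertex ellipse with jittered center (SD 0.02
  of the raster), lognormal axis jitter (SD 0.15) and uniform rotation.
  Default region probabilities put the models' concerns mainly on
  thighs/buttocks and the nonmodels' on abdomen/waist, with expected
  concerns per subject ≈ 1.2 and 1.4 respectively. Concern types and
  affects are weighted draws from the controlled vocabularies; intensity
  is Normal (per-group mean/SD ≈ 27/29 and 38/31), clipped to [0, 100].
- **Sizes and perception.** True part sizes are Normal with per-group
  means/SDs matching the two populations' measured anthropometry;
  perceived size = true + per-group part bias + Normal(0, 4 cm) noise.
  Sliders encode the perceived size through the inverse calibration.
  Default calibration anchors are m0 = 0.5·m05 and m1 = 1.5·m05 around
  baselines near the population mid-range — wide enough that default
  biases (up to ≈ −13 cm on thighs) clip rarely. Clipping is counted and
  logged, never silent; if a part clips for an entire group the generator
  raises and advises widening the calibration range, since silent
  truncation would bias recovery studies.
- **Null and planted configurations.** `null_config` gives both groups one
  shared model (concern probability 0.35, a mid-range rate) and
  `null_cohort` refuses configs whose groups differ; `planted_effect_config`
  plants a single region with probabilities 0.6 vs 0.2 at n = 40 + 40 on a
  64×128 raster.

Everything is reproducible from the config seed (same seed → byte-identical
cohort JSON).

What the generator does *not* model: real manikin artwork and
anatomically-shaped outlines (ellipses only), within-subject correlation
between 2D concerns and 3D biases, measurement error in the tape values,
and free-text annotations. Passing recovery tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model, not robustness to the full messiness of human tracing data.

## Problem sizes and calibration results

Monte-Carlo validation runs at reduced raster (64×128) with B = 500
relabelings — large enough for stable α = 0.05 decisions (p resolution
1/501) while keeping a 200-replicate null study and a 50-replicate
recovery study to a few minutes. The family-wise positive rate on null
cohorts and the planted-effect recovery rate are computed fresh by
`scripts/acceptance.py` and by the acceptance tests; exhaustive-enumeration
agreement of the permutation engine is checked on a 6-subject toy problem
where all C(6,3) = 20 relabelings can be enumerated.

## Known limitations

- Cluster-extent correction controls family-wise error at the cluster
  level; it does not license pixel-level claims inside a surviving cluster.
- With a single concentrated concern region, permutation null maps contain
  large coherent clusters (subject masks are whole ellipses), so the null
  critical extent is itself large; detection of small planted regions
  requires correspondingly strong probability differences.
- The MANCOVA assumes multivariate normal residuals and homogeneous
  covariance across groups; no robust alternative is provided.
- BH adjustment is the standard step-up procedure; it is monotone and
  order-preserving but (like all BH implementations) not idempotent under
  re-application.
- PNG raster export quantizes proportions to 8 bits; CSV exports are exact.
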