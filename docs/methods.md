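# Methods

This note records the models, conventions and design choices behind
`woundtexture`, in the order data flows through the package.

## Thermal frames and formats

A frame is a matrix of absolute skin temperatures in degC with 0-based,
row-major indexing and the origin at the top-left pixel center.  Frames are
validated against the camera envelope of the acquisition device class
(range -20 to +120 degC, nominal 160x120 resolution, emissivity 0.98 for
clean skin); out-of-range or non-finite values are rejected at I/O time.
Three dialects are supported: lossless CSV matrices (`%.17g`, bit-exact
round trip), 16-bit TIFF with a JSON sidecar holding the linear DN-to-degC
scale and offset (lossy only at DN quantization, at most half a scale unit;
re-writing a read file reproduces the same DN matrix), and 8-bit PNG +
sidecar for visual QC (explicitly lossy; it preserves only the rank order
of temperatures).  Radiometric TIFF tags are vendor-specific, which is why
an explicit sidecar is used instead.

Planimetry tracings are simple closed polygons in cm coordinates (x along
columns, y along rows); validity (>= 3 vertices, no self-intersection,
positive area) is checked with shapely, and area is computed by the
shoelace formula -- the continuous limit of the grid-square counting that
digitizing tablets perform.

A wound enters the analysis only if all three analysis weeks (0, 1, 2) are
present; the cohort loader reports every exclusion rather than dropping
rows, so `len(kept) + len(excluded)` always equals the number of distinct
wounds in a manifest.

## Segmentation

The wound bed is segmented from the min-max-normalized frame by Otsu's
between-class-variance threshold, followed by *anomaly-side selection*: the
side of the threshold whose values deviate more (mean absolute deviation)
from the frame median is taken as the wound candidate.  This handles both
inflamed (warm) and hypoxic (cool) wounds symmetrically.  The largest
4-connected component of that side, hole-filled, is the raw mask.

Two rejection rules guard against false detections.  The mask must contain
at least `min_wound_pixels` = 64 pixels (co-occurrence statistics on fewer
pairs are unstable; some floor must exist).  And the largest component must
hold at least `min_component_fraction` = 0.2 of its side's pixels: on a
frame of pure sensor noise Otsu splits the noise distribution near its
median, producing a scattered side whose largest connected fragment holds
only a few percent of it, whereas a genuine wound concentrates its side
into essentially one blob (typically > 85%).  Size alone cannot make this
distinction, because a thresholded white-noise field can percolate into
components larger than any fixed pixel floor.

Refinement applies morphological closing then opening with a **square**
structuring element of side `2*radius + 1` (default radius 2), hole
filling, and largest-component selection.  A square element is used
deliberately: opening with a disc rounds every convex corner, so a disc
would alter even a clean rectangular mask, while the square element leaves
solid rectangles untouched and still removes pepper noise, satellite specks
and holes.  Refinement is idempotent on wound-like masks and cannot grow
the bounding box by more than the radius.

Masking *excludes* background pixels; it never zeroes them.  Zero-filling
would inject an artificial grey level into the co-occurrence statistics.

The whole chain operates on min-max-normalized values, so it is exactly
invariant under affine temperature maps T -> aT + b (a > 0): ambient
temperature shifts between home visits do not change the mask.

## Texture features

In-mask temperatures are binned uniformly into L = 16 levels over the
in-mask min-max range (the maximum maps to level L-1; a constant region
maps to level 0 and is flagged degenerate).  Sixteen levels keep GLCMs
dense on wound regions of a 160x120 frame while retaining thermal texture;
L is a configuration knob.  Pixel distance is 1 (nearest-neighbour
adjacency), also configurable.

Four co-occurrence matrices are accumulated symmetrically (each ordered
in-mask pair increments both P[i,j] and P[j,i]) for the offsets (0,1),
(-1,1), (-1,0), (-1,-1); pairs touching background or the frame edge
contribute nothing.  Unnormalized entries are integers summing to twice the
pair count.  After normalization the four matrices are averaged as
`((P0 + P45) + (P90 + P135)) / 4`; this pairing is what makes the feature
vector *exactly* (to the last bit) invariant under 90-degree rotation of
frame and mask, because rotation swaps the two parenthesized partial sums
and floating-point addition is commutative.

The 12 features (lettered a-l in list order) are computed from the averaged
matrix with 0-based indices, entropies in log base 2 with 0 log 0 = 0, and
correlation defined as 0 when a marginal variance vanishes so degenerate
masks never produce non-finite values.  Inertia is implemented by the same
formula as contrast: the two names are synonyms in most of the GLCM
literature, and the duplication is preserved deliberately to keep the
12-slot vector and the a-l letter convention intact.  The two columns are
therefore perfectly collinear, which the correlation-matrix PCA tolerates
(one zero eigenvalue).

## Longitudinal statistics

Week ratios f(week_num)/f(week_den) are formed per feature and per area
measure for the three contrasts w1/w0, w2/w1, w2/w0.  A wound whose ratio
vector contains a zero denominator or non-finite value is excluded from
that contrast's analysis (with logging), never imputed.

PCA is fitted separately per ratio contrast on the z-scored 12-column ratio
matrix, i.e. on the correlation matrix: the features live on wildly
different scales (entropies in bits, cluster prominence in fourth powers of
grey levels) and a covariance PCA would be dominated by cluster prominence.
Constant columns are dropped with a warning.  Eigenvector signs are
arbitrary, so each retained component is oriented to make the inertia
loading non-negative (falling back to the first non-zero loading if inertia
was dropped), which makes loadings, scores and group orderings
reproducible.  Scores are the z-scored data projected on the loadings.

The normality gate applies the Anderson-Darling test (mean and variance
estimated) per group at alpha = 0.05; if any group rejects, the
nonparametric branch (Kruskal-Wallis) is selected, otherwise one-way ANOVA.
The A2 statistic is computed directly from the sorted standardized sample
and converted to a p-value with the Stephens small-sample correction
`A* = A2 (1 + 0.75/n + 2.25/n^2)` and the standard piecewise-exponential
approximation; the test suite checks this against R's `nortest::ad.test`,
which uses the same formulas.  Both tests are always computed and reported;
the gate only chooses which one a report highlights.

Kruskal-Wallis uses the tie-corrected H with a chi-square(1) reference for
two groups; an all-tied sample returns H = 0, p = 1 (no evidence, not an
error).  The ANOVA F has (1, n-2) degrees of freedom, and the Tukey 95%
simultaneous interval for (unhealed - healed) uses the studentized-range
identity q(0.95, 2, df) = sqrt(2) t(0.975, df), i.e. with two groups it
*is* the pooled-t interval -- computed that way for speed and verified
against `scipy.stats.studentized_range` and statsmodels' Tukey HSD in the
tests.  With zero within-group variance and equal means, F is undefined and
reported as NaN.

`predict_healing` thresholds PCA1 at the midpoint of the two group means
and classifies each wound by which side it falls on, orienting itself from
the group means.  This is an *extension*: the underlying analysis
establishes a group-level difference, not a validated classifier, and the
package labels the prediction accordingly wherever it is reported.

## Synthetic cohort generator

No clinical images were available to this package, so every downstream
stage is exercised on synthetic cohorts with the statistical structure the
analysis assumes.  Per wound:

* **Geometry** -- a star-convex polygon (8-16 vertices, +/-35% radius
  jitter) centred in the frame; baseline radius is log-normal around 2.0 cm
  (sigma_log 0.25).  At the default 14 px/cm -- close-range point-and-shoot
  framing -- the wound occupies roughly 10-20% of the 160x120 frame.  This
  scale matters: at a few percent of the frame, Otsu's threshold settles
  inside the background-noise mode and segmentation collapses, which is a
  property of the method worth knowing about, not a generator artifact.
* **Area trajectory** -- the polygon shrinks geometrically so the
  week2/week0 area ratio is log-normal (sigma_log 0.25) around the group
  median anchor: 0.50 for healed, 0.88 for unhealed wounds.  These anchors,
  the 17 healed / 55 unhealed split across 72 wounds in 60 participants,
  the frame geometry and the emissivity are the study conditions the
  generator reproduces.
* **Thermal field** -- baseline skin at 32 degC; inside the wound a
  temperature offset of +1.5 degC, a *rough* correlated field (smoothed
  white noise, correlation length 2 px, sigma 0.6 degC) carrying the
  wound's textural heterogeneity, and a *persistent smooth* field
  (correlation length 6 px, sigma 0.3 degC) modelling the broad
  physiological temperature profile of the limb; over the whole frame,
  white sensor noise of 0.05 degC.  Per-wound heterogeneity comes from a
  log-normal jitter (sigma_log 0.25) on the rough sigma.
* **Healing dynamics** -- the wound offset and the rough sigma are
  multiplied by decay^week: 0.45/week for healed wounds, 0.97/week for
  unhealed.  The smooth field and sensor noise do not decay.

Because quantization is per-mask min-max, the texture features are
amplitude-invariant: what changes them between weeks is the *mix* of rough,
smooth and white components, not the shrinking amplitude itself.  One
consequence found during calibration and worth stating plainly: in this
generator the healed group's normalized contrast-type ratios end up
*higher* than the unhealed group's (the range-to-sigma statistics of the
smoother week-2 field dominate the adjacency effect), so the healed group
sits at positive PCA1 under the inertia-positive sign convention.  The
group *separation* -- the quantity every test in this package measures --
is strong and two-sided, and the midpoint classifier orients itself from
the data, so no inference depends on the sign.

The decay and noise defaults were calibrated once so that, at the 17 v 55
split, the week2/week0 PCA1 ANOVA has high power while the week1/week0
contrast rejects markedly less often (the cumulative two-week change is the
reliable signal, the one-week change is not), and then frozen.  A `null()`
configuration (equal decays, equal area anchors) makes the healed label
generatively inert, for type-I-error studies.

Reproducibility: wound i draws from `SeedSequence(root_seed, spawn_key=(i,))`,
so cohorts are independent of generation order and manifests are
byte-identical across runs.

### What the generator does not emulate

* Clinical dispersion: the real cohort's area-ratio SDs are far larger and
  heavier-tailed than any moderate log-normal (unhealed w2/w0 SD larger
  than its median); the generator targets stable medians instead.
* Ambient-condition corruption of thermal-image area: in home settings
  thermal-area extraction is unreliable, and the study found that arm
  non-significant.  The synthetic thermal mask tracks the true shrinking
  polygon, so on synthetic cohorts the thermal-area arm *does* separate the
  groups.  Passing tests therefore validate the pipeline's mechanics, not
  the clinical claim that thermal area fails where texture succeeds.
* Wound-bed physiology (no heat-transfer model), cleansing effects,
  multi-wound frames, camera motion and perspective.

## Replicate study sizes

The type-I-error study runs 500 null cohorts of 16 + 16 wounds on 60x80
frames at 6 px/cm (the null property does not depend on cohort or frame
scale, and small cohorts keep the study fast); observed rejection of the
ANOVA-on-PCA1 at alpha = 0.05 is within 0.05 +/- 0.03.  The power study
runs 200 cohorts at the full default conditions (17 v 55 wounds, 160x120
frames); the w2/w0 contrast rejects in well over 80% of replicates and
strictly more often than w1/w0.  `scripts/acceptance.py` reruns reduced
versions (100 power / 200 null replicates) plus one full cohort analysis.

## Known limitations

* Segmentation assumes one wound per frame and a wound occupying a
  non-trivial fraction of it; very small or very low-contrast wounds at
  late healing stages are occasionally rejected (and then excluded with a
  logged reason, which slightly thins the healed group).
* The grey-level count (16) and pixel distance (1) are conventions, not
  fitted quantities; both are exposed as configuration knobs.
* No adjustment for clinical covariates (age, ulcer duration, compression
  level) and no correction for multiple testing across arms or ratio
  contrasts.
* The Anderson-Darling p-value approximation is accurate to a few 1e-4
  over its usual range, which is ample for gating at alpha = 0.05.
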