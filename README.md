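# woundtexture

Texture analysis of thermal images for predicting which chronic wounds will
heal.

Venous leg ulcers (VLUs) are chronic lower-limb wounds; even under best
practice about a third do not heal on the expected trajectory, and current
guidance only flags them after four weeks of area tracking with contact-based
planimetry tracings.  Thermal imaging is contact-free and usable in home
care, but wound *area* extracted from thermal images is unreliable in
uncontrolled settings.  The spatial *texture* of the wound's temperature
field is a different signal: it needs no registration, no wound-edge
detection, and is insensitive to camera distance, rotation and ambient
shifts.  This package implements a longitudinal texture pipeline that asks,
two weeks after baseline, whether the change in thermal texture already
separates wounds that will be healed at week 12 from those that will not --
alongside the planimetry-area gold standard for comparison.

## Method

For each wound, weekly thermal frames (matrices of skin temperature in
degC) at weeks 0, 1, 2 are processed as:

1. **Normalization** -- min-max scaling of the frame to [0, 1].
2. **Segmentation** -- Otsu thresholding, selection of the thermally
   anomalous side (wounds may be warmer or cooler than periwound skin),
   largest connected component, hole filling, morphological refinement.
3. **Quantization** -- in-mask temperatures binned into L = 16 grey levels
   over the in-mask min-max range, making all downstream features invariant
   under affine temperature maps T -> aT + b.
4. **Co-occurrence** -- symmetric grey-level co-occurrence matrices
   (GLCMs) at distance 1 in the four directions (0, 45, 90, 135 degrees),
   counting only pixel pairs that lie entirely inside the wound mask;
   normalized and averaged into a single matrix P.
5. **Features** -- 12 second-order statistics of P, lettered a-l: angular
   second moment, contrast, inverse difference moment, entropy, correlation,
   sum-of-squares variance, sum average, sum entropy, difference entropy,
   inertia, cluster shade, cluster prominence (entropies in bits).
6. **Rate of change** -- per-feature week ratios f(w1)/f(w0), f(w2)/f(w1),
   f(w2)/f(w0), pooling wounds of different absolute texture scale.
7. **PCA** -- the 12 ratios are z-scored and reduced by a correlation-matrix
   PCA; the first two components are retained, with loadings oriented so the
   inertia coefficient is non-negative.
8. **Inference** -- healed vs unhealed groups are compared per measurement
   arm (planimetry area ratio, thermal-mask area ratio, PCA1 of texture
   ratios).  An Anderson-Darling normality gate chooses between the
   Kruskal-Wallis test and one-way ANOVA with a Tukey 95% simultaneous CI
   (which, with two groups, is the pooled-t interval).

Because the study's clinical images were never deposited, the package ships
a synthetic cohort generator (`woundtexture.synthetic`) whose defaults
reproduce the study conditions: 72 wounds in 60 participants, 17 healed at
week 12, planimetry week2/week0 area-ratio medians of 0.50 (healed) and
0.88 (unhealed), and a textural-decay dynamic under which only the
cumulative two-week contrast reliably separates the groups.  See
`docs/methods.md` for the generative model and its limitations.

## Worked example

```python
from woundtexture import SyntheticCohortConfig, HealingTrajectoryModel, generate_cohort

cohort = generate_cohort(SyntheticCohortConfig(seed=1))   # 17 healed, 55 unhealed
model = HealingTrajectoryModel.from_cohort(cohort)
res = model.fit("w2_over_w0")
print(res.summary())
```

prints

```
==============================================================================
Healing trajectory analysis -- ratio w2_over_w0
==============================================================================
arm             test           n(h/u)    healed med unheal med     stat        p
------------------------------------------------------------------------------
planimetry_area kruskal_wallis 17/55          0.426      0.882   31.681   0.0000
thermal_area    kruskal_wallis 17/55          0.278      0.878   33.498   0.0000
pca1_texture    kruskal_wallis 17/55          2.232     -1.211   24.264   0.0000
------------------------------------------------------------------------------
PCA on 12 feature ratios: PC1 64.4%, PC2 15.1% of variance
largest |PC1| loadings: d_entropy (+0.35), i_difference_entropy (+0.35), c_idm (-0.34), j_inertia (+0.34), b_contrast (+0.34)
==============================================================================
```

Reading the table: healed wounds halve their planimetry area by week 2
(median ratio 0.43) while unhealed wounds barely change (0.88); the same
contrast appears in the thermal-mask area and in the first principal
component of the texture-ratio space, where the healed and unhealed score
distributions separate (Kruskal-Wallis H = 24.3, p < 1e-4; the
nonparametric branch was chosen by the normality gate for this cohort).
`res.predict()` additionally thresholds PCA1 at the midpoint of the group
means (1.063 here) -- a per-wound classification that goes beyond the
group-difference inference and is labelled as such.

## Command line

```bash
woundtexture simulate --seed 7 --out cohort/          # frames, traces, manifest
woundtexture run --config cohort/config.yaml          # full report bundle
woundtexture features --config c.yaml --out feats/    # stage 1 only
woundtexture stats --config c.yaml --features feats/features.csv --out rep/
```

`run` writes `report.json` (with the config, seed and version embedded, and
every excluded wound listed with its reason), CSV tables (per-visit
features, group comparisons, PCA loadings and scores) and box-plot summary
JSON; the staged `features` -> `stats` path reproduces the monolithic
report bit-for-bit.

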