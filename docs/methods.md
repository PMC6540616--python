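# Methods

## Growth model and plate simulation

Wells are modelled as logistic growth in linear OD space,

    N(t) = K·A·e^{r·max(0, t − lag)} / (K + A·(e^{r·max(0, t − lag)} − 1)),

with `A = initial_od` (blank-subtracted OD at inoculation), `K =
carrying_capacity`, and `r = rate · ln 2` so that `rate` is the specific
growth rate in log2-OD units (doublings) per hour. Readings are `blank_od +
N(t)` plus additive Gaussian reader noise truncated at zero, independent per
well. The logistic is the minimal standard microplate shape that produces a
log-linear window for the slope fit; diauxic shifts, evaporation and edge
effects are deliberately out of scope.

Defaults mirror the assay design they emulate: inoculation at OD 0.05,
reads every 10 min for 30 h (181 samples; 20 h gives 121), three replicate
wells per strain per media, a positive-control and a negative-control
strain on every plate, and four blank wells (the blank count and placement
are a simulator choice, not a protocol fact). Default rates (DMSO 0.35/h;
MTX 0.30/h for the positive control, 0.08/h for the negative) put the
control MTX/DMSO ratios near 0.86 and 0.23, comfortably separated, and let
every well traverse the fit window within the run. The default carrying
capacity is 1.8 OD, a realistic microplate plateau.

A note on the logistic and the fit window: in the window OD range
(blanked 0.125–0.25) the instantaneous log2 slope is `rate·(1 − N/K)`, so a
fitted slope underestimates `rate` by up to ~10% at K = 1.8. This cancels
in the score: the window is defined in OD units, so MTX and DMSO wells are
fitted over the same OD range and carry the same damping factor, which
divides out of the slope ratio. Tests that assert the fitted slope itself
against the growth rate therefore use a high carrying capacity (the
near-exponential, low-OD regime); the scoring tests use the realistic
default.

## Scoring pipeline

- **Blanking.** The plate blank is the mean of blank-well readings in the
  first hour, falling back to the plate-wide minimum reading when no blank
  wells exist. Points at or below the blank are dropped before the log2
  transform (logged as dropped, since log is undefined there).
- **QC.** The original workflow excluded wells with abrupt OD drops by
  visual inspection; this package automates it as a consecutive-reading
  rule — a well is flagged when any reading falls more than 20% (default)
  below its predecessor. Flags are advisory and reported with reasons; the
  plate driver excludes flagged wells but accepts pre-filtered input.
  Exclusion is per well, and removing a well cannot change any other
  well's slope (no cross-well coupling anywhere in the fit).
- **Slope fit.** Ordinary least squares over the points whose log2 OD lies
  in the closed window [−3, −2] (a [−3, −2.2] variant is selectable).
  Fewer than 3 in-window points (configurable) is an error naming the
  well, never a silent slope.
- **Ratios and scores.** Per MTX well: slope ÷ mean DMSO slope of the same
  strain on the same plate. Control ratios are the plate means over the
  control strains' MTX wells; the score `(ratio_x − ratio_NC)/(ratio_PC −
  ratio_NC)` is computed per MTX well and then averaged (not
  slope-averaged first), pooling across experiments for mean ± SEM
  (sample SD/√n; undefined at n = 1, never reported as 0). Controls are
  matched strictly within a plate; when a plate carries both prey-replaced
  and bait-replaced negative controls the prey-replaced one anchors 0 by
  default, selectable by config. A degeneracy guard rejects experiments
  with |ratio_PC − ratio_NC| < 1e−6.
- **Display transforms.** Raw scores are stored unclipped (values slightly
  below 0 or above 1 are meaningful); clipping to [0, 1] and the five
  lower-inclusive half-open bins ([0, 0.2), …, [0.8, 1]) apply only to
  heatmap rendering. The bin-boundary convention is a documented choice —
  the display legend's notation does not fix it.
- **Specificity.** A mutant is called nonspecific when at least three
  ligands score strictly below 0.3 (both configurable).

## Scene generators

All scenes are 2-D multi-channel images (projection/extended-focus inputs
are assumed; no 3-D support) built from disks, blobs and random-walk
ribbons — minimal geometry that keeps every ROI of the downstream measures
nonempty and analytically known. Noise is additive Gaussian truncated at
zero; an optional linear background gradient exercises rolling-ball
subtraction. All randomness flows from an explicit integer seed.

- **HEK co-clustering.** Non-overlapping cell disks; non-overlapping
  puncta disks fully inside each cell. The puncta (liprin) channel gets
  Gaussian-blurred edges (σ = radius/3) so thresholding behaves as on real
  images; the V5 reporter channels are piecewise constant (base level in
  the cell, base × ratio inside puncta) so the true inside/outside mean
  ratio equals the requested recruitment ratio exactly before noise.
  Background level/gradient are applied to the thresholded channels only,
  for the same reason.
- **Coculture.** One central COS blob (inducer), thin axon ribbons (Tau),
  thicker dendrite ribbons (MAP2). Synapsin puncta counts are Poisson at
  `density × region area` for the contact region (COS ∧ axon ∧ ¬dilated
  MAP2) and the rest of the axons; punctum centers are kept a punctum's
  footprint away from the opposite region so no punctum straddles the
  boundary and the two densities are exact by construction. Measured
  punctate area slightly underestimates `density × punctum area` at high
  density because puncta may overlap (Boolean-model coverage); at the
  default densities (0.02 and 0.002 puncta/px², 10× contrast) the bias is
  a few percent and identical in form on both sides of the contrast.
- **Field morphology.** Tau/MAP2 masks are smooth Gaussian random fields
  thresholded at a quantile, which pins the foreground area fraction to
  the requested value to within pixel rounding; nuclei are disjoint disks.

Scenes round-trip through a float32 multi-page TIFF plus a YAML
channel-role map; ground-truth scalars ride in the YAML and ground-truth
masks in a companion uint8 TIFF.

What passing recovery tests shows — and does not. The generators produce
clean, piecewise-simple scenes; recovering known ratios from them validates
the measurement code (ROI algebra, background subtraction, ratio
arithmetic), not robustness to the segmentation ambiguity, uneven
illumination, or out-of-focus light of real micrographs, where threshold
choice remains the dominant operator-dependent step.

## Image quantification

- **Masks.** Thresholds are lower-inclusive (pixel ≥ threshold) and
  explicit everywhere, mirroring the manual per-image choice of the
  original workflow; an Otsu-based `auto_threshold` is provided as a
  labelled convenience for synthetic data. Dilation is the true Euclidean
  disk (computed from the exact distance transform of the complement),
  matching a brute-force lattice oracle exactly in tests. Mask algebra is
  pixelwise boolean.
- **Rolling ball.** The background is the grayscale opening of the image
  with a non-flat spherical-cap structuring element of the given radius
  (no paraboloid approximation, no pre-shrinking), with edge-replicated
  borders; output = input − background, floored at 0. Anti-extensivity
  (output ≤ input) and idempotence of the background estimate hold
  analytically and are tested to 1e−9 against a per-pixel
  erosion-then-dilation oracle.
- **Co-clustering ratio.** Mean reporter intensity over (cell ∧ puncta) ÷
  mean over (cell ∧ ¬puncta); the reporter channel is never thresholded.
  Empty ROIs and zero-mean denominators are errors, not zeros.
- **Coculture measures.** Contact ROI = COS ∧ Tau ∧ ¬dilate(MAP2, 5 px);
  COS ROI drops the Tau condition. The default synapsin measure is
  punctate area per ROI pixel ("punctate signal per area"); the
  integrated-intensity variant is emitted alongside, and an optional
  punctum size filter is off by default. An empty contact ROI yields an
  absent measure, never 0. Measures are per transfected cell.
- **Surface matching.** Cells are kept when their surface-reporter level
  lies within the 10th–90th percentile band (configurable) of a reference
  group — the band is an explicit package choice, since "high or low"
  excludability has no canonical numeric rule.
- **Per-culture normalization** divides each value by its own culture's
  control-condition mean (control mean = 1 by construction); cultures
  missing the control are flagged, not dropped.
- **Nuclei** are connected components of the thresholded DAPI mask with a
  30-px minimum area (configurable) to suppress specks.

## Statistics

Summaries are mean ± SEM with n. Two-group comparisons use Mann-Whitney;
three or more use Kruskal-Wallis followed by Dunn's pairwise z-tests on
joint ranks with tie correction. The omnibus and two-group tests delegate
to scipy; the Dunn z-statistics are computed from the standard
large-sample formulas (cross-checked in tests against the asymptotic
rank-sum p for two groups and an independent recomputation of the tied
case), with p-value adjustment delegated to statsmodels and defaulting to
"none" beyond Dunn's own two-sided p. A D'Agostino-Pearson normality
pre-check is reported per group but not acted on: the pipeline's measures
are treated as non-normal and the rank route is used throughout.

## Problem sizes in tests

The simulation-recovery suites use plates of 3–5 strains (≈ 22–34 wells,
181 reads each) over 20 seeds, and 256² scenes (20 seeds per condition for
recruitment recovery, 4 ratios × 20 seeds for the HEK sweep); these sizes
give Monte-Carlo error comfortably below the asserted tolerances while
keeping the whole suite around half a minute.

## Known limitations

- The growth model has no lag-phase stochasticity, evaporation, or plate
  position effects; QC is exercised only on injected step artifacts.
- Scene geometry is schematic; segmentation difficulty is not modelled, so
  threshold-sensitivity of the measures on real images is untested here.
- Dunn's procedure uses the large-sample normal approximation; very small
  groups (n < 5) should be interpreted cautiously.
- The interaction score presumes control strains behave consistently
  within a plate; cross-plate control drift is handled only by the strict
  within-plate pairing.
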