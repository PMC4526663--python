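# Methods

## The measurement being modeled

Two-epoch Arc catFISH gives each counted neuron one of four labels —
negative, nuclear (intranuclear transcription foci: active in the epoch
just before sacrifice), cytoplasmic (perinuclear mRNA: active ~25–30 min
earlier), double — and the similarity score reduces the tally to a single
overlap measure.  Writing `e1 = (cyt+dob)/total`, `e2 = (nuc+dob)/total`,
the score is

    SiSc = (dob/total − e1·e2) / (min(e1, e2) − e1·e2),

the excess of doubly active cells over the independence expectation,
scaled by the maximum possible excess.  It is 1 exactly when the doubles
saturate the smaller epoch, 0 at exact independence, and negative when
the two ensembles overlap less than chance; negative values are reported
unclipped, since clipping would bias group means upward.  When
`min(e1,e2) = e1·e2` (an epoch at zero or full activation) the score is
undefined and is returned as NaN with an explanatory flag, never as a
silent number, and such units are excluded from group statistics with a
count in the run manifest.

## Generative model

`simulate_labels` draws per-neuron activation from a bivariate Bernoulli
with marginals `p1`, `p2` and joint probability

    p11 = p1·p2 + κ·(min(p1, p2) − p1·p2),

so the population SiSc equals κ by construction: κ = 0 is independence,
κ = 1 nests the smaller ensemble in the larger.  κ is feasible on
`[κ_min, 1]` with `κ_min = (max(0, p1+p2−1) − p1·p2)/(min(p1,p2) − p1·p2)`
(the Fréchet bounds mapped through the parameterization); infeasible
values raise an error naming the interval.  Glia are never active.

Defaults are the study conditions this simulator stands in for: marginal
activation 0.33 per epoch (the CA1-like figure; CA3-like runs use 0.25),
40 optical sections of 0.3 µm, nuclei of 8 px in-plane radius and 6
planes in z.  `glia_fraction` defaults to 0.2 — the counterstain labels
all nuclei and a minority of them in the pyramidal layer are glial; no
count is available for the original material, so this is a package
choice, not a matched value.  κ has no default-worthy empirical value
(it is the quantity the experiment varies); 0.5 is used as a neutral
mid-range default.

### Estimator bias at equal marginals

The population identity E[SiSc] = κ does not make the *plug-in* score of
a finite tally unbiased.  At `p1 = p2` the denominator term
`min(ê1, ê2)` is biased low by about `sqrt(var(ê1 − ê2)/2π)`, so at
n = 1000 the mean plug-in score overshoots κ by ≈ +0.008 to +0.015 for
κ in 0.25–0.75 (verified against a direct multinomial-sampling oracle);
the bias vanishes at κ = 0 (numerator is exactly centered) and at κ = 1
(the ratio is identically 1) and shrinks as O(1/√n).  The recovery suite
documents this: unit tests compare the generator to the multinomial
oracle (bias-free check of the generative model), while the acceptance
test asserts the raw 3-standard-error recovery band and is expected to
fail at intermediate κ — an honest property of the printed estimator,
not of the generator.

## Stack rendering

Channel 0 (counterstain): neuronal nuclei are ellipsoids filled with
multiplicative speckle (Gaussian field, σ≈1.2 px smoothing, renormalized
to CV 0.25, floored at 0.6× the mean so texture dips never reach the
background class) at mean 100; glia are uniform at 1.8× that mean.  The
floor matters: without it, texture minima fall below the segmentation
threshold and carve bays into mask boundaries, which fragments focus
tracks and locally displaces the perinuclear annulus.  Channel 1 (Arc):
epoch-2-active neurons get two antipodal intranuclear discs (radius 2 px,
7 px apart — far enough that a radius-1 median filter cannot merge them)
spanning `foci_planes` consecutive planes; epoch-1-active neurons get a
perinuclear band (+0.5 to +3.5 px outside the per-plane nucleus
cross-section, following the ellipsoid profile) covering `ring_coverage`
of the perimeter over `ring_planes` planes.  Defaults `foci_planes=4`,
`ring_planes=5` sit above the classification minima (3 and 4) so default
material is unambiguous; boundary fixtures set them at and below the
minima deliberately.  Nuclei are placed by rejection sampling with 6 px
of anisotropy-corrected surface clearance so cross-sections never touch
in any plane (touching blobs would force the watershed to cut through
one nucleus).  Gaussian noise of scale `noise_sd` is added to both
channels and clipped at zero.  All randomness flows through seed
sequences spawned from the single config seed; identical configs are
bit-identical.  No confocal PSF, photobleaching, or tissue deformation
is modeled — passing tests show the pipeline recovers the constructs it
defines, not that it would survive arbitrary real-world aberrations.

## Classification pipeline

* **Median filter** per plane (radius 1 by default, configurable; radius
  0 is the identity) on both channels.
* **Segmentation**: Otsu threshold on the counterstain, 3×3 in-plane
  opening and closing, plane-wise hole filling, then marker-based
  watershed on the (σ=1.5 smoothed) distance transform with a 7 px peak
  separation; components under 200 voxels are dropped.  Segmentation is
  deliberately replaceable plumbing — the original protocol counted by
  eye — and pre-tabulated per-plane evidence can enter at
  `classify_cell`/`tabulate` directly.
* **Neuron/glia rule**: within-mask coefficient of variation ≥ 0.12 AND
  mean ≤ 140.  These defaults are calibrated on the renderer's intensity
  model (neurons: textured around 100; glia: uniform 180); single-voxel
  masks are excluded as glial with a warning, zero-mean masks get CV 0.
* **Optical dissector**: keep cells whose nucleus centroid lies in the
  closed plane window `[ceil(n(1−f)/2), floor(n(1+f)/2)]`, f = 0.30 —
  e.g. planes 14..26 of 40.  Membership is by centroid plane; the kept
  count is monotone in f.
* **Focus evidence**: per plane, connected Arc components ≥ 100 intensity
  inside the nucleus mask with area 2–80 px; components in consecutive
  planes within 3 px are linked into tracks.  *Nuclear* ⇔ ≥ 2 tracks
  each spanning ≥ 3 **consecutive** planes ("across" is read as a
  persistent contiguous track, robust to single-plane noise).
* **Coverage evidence**: per plane, the annulus between the mask dilated
  by 1 px (a guard ring absorbing segmentation raggedness under noise)
  and by 4 px, minus every segmented nucleus (a neighbouring nucleus is
  not cytoplasm), is divided into 72 angular sectors about the centroid;
  a sector is covered when it holds ≥ 1 pixel ≥ 75 intensity.  Empty
  sectors leave the denominator.  At 72 sectors the quantization is
  1/72 ≈ 0.014, and false positives require a ≥ 4.4 σ noise excursion
  after median filtering.  *Cytoplasmic* ⇔ coverage **strictly** > 0.60
  in ≥ 4 planes, **not** necessarily consecutive ("in", not "across");
  a consecutive variant is a config flag.  *Double* ⇔ both criteria in
  full; everything else is negative.  Classification is a pure function
  of the stored per-plane evidence and reproduces bit-exactly.

Against rendered ground truth this pipeline reaches per-class F1 = 1.0
noiseless and ≥ 0.97 at noise 20% of the focus amplitude on the default
20-stack benchmark (the acceptance thresholds are 0.99 and 0.95).

## Densitometry

Thresholds for Map2 and synaptophysin are calibrated once per slide by
Otsu's criterion over the ROI-union pixels of a control image and then
frozen — the rule is fixed rather than the value, preserving the
slide-constancy contract while removing the experimenter's manual
setting.  Within each polygon the ROI mask is the thresholded Map2
region dilated to the first integer radius reaching ≥ 110% of its area
("about 10% enlargement" as an area target, since no radius is stated;
overshoot from integer radii is inherent and logged).  The readout is
100 · (synaptophysin pixels ≥ threshold inside the mask) / mask area.
The mosaic renderer plants a known fraction inside the
measurement-defined mask by calling the same enlargement routine, making
recovery a genuine round trip through calibration, masking and counting;
measured fractions land within ±0.02 percentage points of truth (the
tolerance asserted is ±0.5).  `map2_area_check` runs the per-ROI one-way
ANOVA of Map2 areas across pretreatment groups as a denominator validity
check.  ROI polygons are supplied by file (the real 14-segment
parcellation is hand-drawn anatomy; `default_roi_layout` provides a
named rectangular stand-in), and measurement is 2D pixel counting — the
montage images are 2D.

## Statistics

One-way ANOVA F/p come from the classical decomposition
(`scipy.stats.f_oneway`) with Fisher-LSD post hocs as pairwise t tests
on the pooled within-group MSE (unadjusted, per Fisher's procedure) or
Bonferroni (`p_adj = min(1, m·p_raw)`).  The balanced two-way ANOVA with
interaction is the standard sum-of-squares decomposition implemented
directly (fast enough for 2000-replicate null calibration) and is
cross-checked in the tests against `statsmodels.anova_lm` to 1e-9;
unbalanced or incomplete designs raise rather than silently switching
SS types, and a design whose second factor is constant collapses to the
one-way result.  Pearson and paired t delegate to scipy with explicit
guards (n ≥ 3, non-constant input, non-zero difference variance).
p-values are descriptive; no across-ROI correction is applied by
default, with Benjamini–Hochberg available as `bh_adjust` for callers
who want it.  All four tests hold their 5% type-I rate within [0.03,
0.07] over 2000 simulated null replicates.

## Pipeline and reproducibility

`run(RunConfig)` executes one of three input modes — simulate, TIFF
stacks (+ sidecar JSON, ROI JSON), or a pre-tabulated counts CSV — and
writes per-cell, counts, SiSc and ROI CSVs, a stats JSON, and a manifest
with the full config echo, its SHA-256, the seed, package version and
the excluded-unit log.  Identical config+seed gives byte-identical CSVs.
SiSc is computed on counts pooled per animal/region (one score per
unit); per-stack scoring averaged per animal is possible by tabulating
stacks separately, but pooling is the default since the score of a
pooled tally is better conditioned at moderate counts.
`experiment_3x3` simulates the pretreatment × condition design at the
label level (no rendering — the imaging layer is validated separately,
and the design question is about tallies), one bivariate-Bernoulli
population per animal, then summarizes cell means ± s.e.m. and runs the
two-way ANOVA.  With a water-maze-like profile (AA 0.9, AA' 0.8,
AB 0.1) the simulated design reproduces the AA > AA' > AB ordering of
group means in ≥ 95% of seeded runs at 4 animals × 1000 neurons.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which the checks are sharp: 20 stacks ×
50 nuclei × (40, 256, 256) voxels per noise level for classifier
equivalence; 200 populations × 1000 neurons per κ for recovery; one
mosaic × 14 ROIs plus 2000 ANOVA null replicates for densitometry; 2000
null replicates per statistical test; 60 seeded runs of the 3×3 design.

## Known limitations

* The renderer's appearance model is schematic (no PSF, no depth
  attenuation, no overlapping nuclei); classifier thresholds are
  calibrated to it and would need recalibration for real confocal data.
* The neuron/glia rule is a two-feature proxy for what was originally a
  validated visual/immunohistochemical identification.
* The plug-in SiSc carries the finite-sample bias described above;
  group comparisons of scores computed at similar n are unaffected in
  practice, but absolute small-sample scores are slightly overlap-
  inflated when epoch proportions are close.
* Unbalanced two-way designs and repeated-measures ANOVA are out of
  scope.
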