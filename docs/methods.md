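# Methods

`cfidetect` implements a dual-band chlorophyll-fluorescence image-analysis
pipeline for grading chilling injury (CI) in pickling cucumbers, together
with a synthetic scene generator that stands in for fruit images.  This
note records the models, the parameters that matter, the numerical choices,
and the limits of what the synthetic experiments can show.

## The scene model (`synth`)

Chilled cucumber tissue loses chlorophyll activity and fluoresces weakly,
so injured areas appear as dark spots or patches on an otherwise bright
fruit body when excited with UV-blue light.  The generator renders:

* **Fruit body** — a superellipse (exponent 2.5, semi-axes 200 x 70 px at
  the 512-px reference size, axis ratio ~2.9) in uniform random orientation
  over [0, 180) degrees with a small centre jitter.  Pixels are either
  fully fruit or fully background; no partial-volume edge is simulated.
* **Emission levels** — 750 nm (far-red) fruit emission defaults to 39 000
  counts (~60% of the 16-bit scale, leaving sensor headroom), background
  300 counts ("near-zero" stray light).  The 675 nm (red) image is the same
  spatial structure scaled by `band_ratio_675` = 0.35: chlorophyll
  re-absorbs strongly in the red, so that band is much dimmer.
* **Vignetting** — a multiplicative cos^4-law radial field, normalized to 1
  at the image centre and reaching `1 - vignetting_strength` at the
  corner (default strength 0.25).  cos^4 falloff is the standard optical
  vignetting model and is smooth and low-frequency, which is what the
  correction assumes.  The exact field is stored with each sample.
* **Lesions** — darkened disks wholly inside the fruit, Gaussian-softened
  with sigma = radius/3 so edges fade like water-soaked spots.  Class 1
  (mild) draws 1-4 spots of radius 2-7 px (the "< 5 mm per spot" grading
  bound mapped through ~3.1 px/mm at 512 px); class 2 (severe) draws 3-8
  patches of radius 8-18 px.  `lesion_darkening` (default 0.5) is a free
  parameter: no quantitative lesion-contrast statistics exist to fit it
  to, so it is documented as a choice.  Optionally each lesion can
  be *band-preferential* (`lesion_band_exclusive_frac`), contributing full
  contrast to one band and a residual fraction to the other — symptoms
  whose visibility differs between emission bands.
* **Noise** — additive Gaussian (default SD 200 counts), clipped at zero
  and quantized to uint16.  An EMCCD at 1 s exposure is read-noise
  dominated, and additive noise gives direct variance control; Poisson shot
  noise is not modelled.

All randomness flows from one master seed through `SeedSequence.spawn`, so
datasets are reproducible bit-for-bit and per-class counts are free;
the bundled study configurations use a 60/90/60 imbalance — mild injury
the most common grade, as in post-storage grading campaigns.

What the generator does **not** emulate: warts and spines, surface
curvature optics, fungal growth or yellow discoloration, multi-fruit
scenes, shot noise, and sub-pixel lesion boundaries.  Passing tests
therefore demonstrate the pipeline's internal correctness and its behaviour
under the stated statistical structure — not performance on real fruit.

## Segmentation (`segment`)

The background emits almost nothing, so the 750 nm histogram is unimodal
with its main peak at the low-intensity end.  The Rosin construction is
used: draw the chord from the (smoothed) histogram peak to the last
non-empty bin and take the bin maximizing the perpendicular distance to it.
Numerical choices: 256 equal-width bins over [0, max]; a 3-bin moving
average stabilizes the peak under noise (the raw histogram is kept for
reporting); both axes are normalized to the peak-tail span before the
distance computation, which makes the selected bin exactly invariant to
rescaling intensities or counts; ties break toward the lower intensity
(the more inclusive mask).  Cleanup keeps the largest 8-connected
component and fills interior holes so dark lesions stay inside the fruit
region.  Degenerate histograms (fewer than three non-empty bins, flat, or
mode in the tail) raise errors rather than guessing.

## BEMD and vignetting correction (`bemd`)

The image is decomposed as FI = sum_i IMF_i + R by iterative sifting, and
corrected by the literal reconstruction

    FI_corr = (FI + sum_{i=2..k} IMF_i - IMF_1) / R,  n = 6, k = 3.

The first IMF (noise) is subtracted; mid-scale detail (IMF_2..IMF_3) is
re-added — note this *doubles* mid-scale detail that is already inside FI,
which visibly deepens medium-sized lesions in the ratio image; the formula
is implemented exactly as stated.  The residual is clamped at
1e-6 x max(FI) before division so the near-zero background cannot blow up;
the output is a dimensionless ratio image near 1 over the fruit.

**Envelope design.**  The envelope-mean surface subtracted at each sift is
a *clipped midrange*: Gaussian-smoothed moving max/min midrange (window
2r+1, smoothing sigma = r/2) clipped between an opening-by-reconstruction
floor and a closing-by-reconstruction ceiling built with a disk of radius r
(radius 2 for the first mode, doubling per mode, capped at 32 px and at an
eighth of the shorter image side; large disks are iterated small-disk
erosions/dilations, an octagonal approximation).  The floor is additionally
hole-filled, bounded by the ceiling, so an enclosed dark basin — a lesion —
opens up and is extracted into the first mode whose disk covers it, while
border-connected structure (the fruit silhouette, the background) is never
filled.  The rationale: a plain moving max/min midrange reacts to the sharp
fruit/background step with half-amplitude rings at *every* scale, which
both contaminates the fine IMFs entering FI_corr and drags R far below the
fruit intensity near its boundary — measured on synthetic scenes this makes
the corrected in-mask coefficient of variation *larger* than the raw one.
Pure reconstruction-based envelopes preserve the silhouette but cannot
extract connected oscillation fields (e.g. a periodic texture) at all.  The
clipped midrange does both: on lesion-free scenes with 20-40% vignetting
the in-mask CV drops from 0.019-0.043 to ~0.001-0.005 after correction,
and a fine sinusoid + broad hill composite separates cleanly (fine modes
vs residual).

Sifting stops after 3 iterations or when the envelope-mean energy falls
below 1e-3 of the mode's starting energy; more iterations change the
measured properties only marginally at about twice the cost.  If a
remainder runs out of extrema before n modes, the remaining IMFs are zero
(the completeness identity holds trivially) and a warning is logged.
Completeness is exact by construction — the residual is literally the
input minus the extracted modes.

**Known limitation (mode mixing).**  IMF scale ordering is clean on
noise-plus-trend scenes, but a compact lesion is released into a single
coarse mode as soon as the envelope disk covers it, so extrema-spacing
monotonicity can invert locally around lesions.  Every EMD variant shows
analogous behaviour on impulsive structure.

## Features (`features`)

Extraction runs on the corrected (dimensionless) ratio image inside the
shared fruit mask.  167 features per band, in fixed order:

* **28 Haralick** — GLCMs at distance 1 for 0/45/90/135 degrees,
  symmetrized and normalized, in-mask intensities quantized to 32 levels
  over their range; out-of-mask pixels carry a sentinel level whose
  row/column are dropped, so only pairs with both pixels in the mask count.
  The 14 classical statistics (including the maximal correlation
  coefficient, from the second eigenvalue of the Q matrix) are summarized
  by mean and range over the four offsets: 14 x 2 = 28, the canonical
  arrangement that yields the stated count.  Degenerate guards: a
  single-level GLCM has correlation 0 by convention.
* **59 uniform LBP** — 8 neighbours at radius 1 on the square ring, strict
  `neighbour > centre` comparison (a constant patch maps to the all-zeros
  pattern), 58 uniform patterns ordered by code value plus one pooled
  non-uniform bin; histogram over in-mask interior pixels, normalized to
  sum 1.  P=8, R=1 is the only standard configuration that yields 59 bins.
* **67 Gabor** — 4 geometrically spaced frequencies (0.05-0.4 cycles/px)
  x 8 orientations; kernels are made DC-free by subtracting their mean so
  flat regions give exactly zero response; responses computed with
  reflective padding.  Per filter the in-mask mean and SD of the response
  magnitude (64 values) plus three bank aggregates: pooled mean, pooled SD
  and total energy (sum over filters of the mask-mean squared magnitude).
  The bank composition is a documented reconstruction of the stated count.
* **6 intensity** — mean, population SD, min, max, moment skewness, excess
  kurtosis of in-mask intensities; a constant distribution defines skewness
  and kurtosis as 0.
* **7 Hu moments** of the masked intensity image, reported as
  -sign(h) log10|h| for conditioning (exact zeros stay 0).

Fusion concatenates the 675-band block before the 750-band block (334
features).  Normalization is feature-wise standardization fitted on
training rows only; a zero-variance training feature is centred and left at
0 with a warning.

## Classification and selection (`model`)

Linear soft-margin SVM (hinge loss, one-vs-rest for three classes), with C
tuned by stratified 5-fold cross-validation over 17 log-spaced points
spanning [1e-4, 1e4] (half-decade steps); ties go to the smaller C.  The
evaluation protocol is 30 replicated stratified 6:4 train/test splits, each
replicate re-normalizing and re-tuning on its own training rows;
per-replicate seeds descend from one master seed.  Stratification is added
engineering: it prevents empty classes in folds at desk-scale n.

NCA feature selection maximizes the expected leave-one-out
soft-nearest-neighbour accuracy with weighted L1 distance
d(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr| and an L2 penalty lambda sum w_r^2
(lambda defaults to 1/n_train), optimized by bound-constrained L-BFGS from
uniform weights; the softmax uses a log-sum-exp shift so the sharp
high-dimensional regime stays finite.  Weights are reported normalized to
max 1.  The incremental protocol trains SVMs on the top-m features for
m = 1..100; by default NCA is refit per replicate on that replicate's
training rows (leakage-safe) and the curve averages replicates, while a
precomputed ranking can be supplied for the one-shot view.  The selected
size is the smallest m whose mean accuracy is within one standard error of
the full-feature mean (falling back to the curve argmax); this rule is a
documented choice — several reasonable variants exist.

## Metrics (`metrics`)

TN = % of normal fruit classified correctly; TP (two-class) = % of injured
fruit classified correctly; TP1/TP2 (three-class) = per-class correct
percentages for mild/severe injury; ACC = overall percent correct.  A class
absent from the truth yields NaN for its rate.  Mean accuracies across
image inputs are compared by one-way ANOVA on the per-replicate ACC
vectors; only a significant omnibus test (5%) unlocks pairwise Fisher's
LSD t-tests with the pooled MSE (the *protected* LSD, which is what keeps
the type-I rate near alpha).  Identical group means define p = 1.  Results
are summarized as a compact letter display via maximal cliques of the
"not significantly different" graph, lettered in order of decreasing mean.

## Study conditions (`study`)

Research-scale experiments run at 192 px (scenes geometrically rescaled
from the 512-px reference; this preserves scene statistics while keeping a
210-sample dual-band pipeline run in minutes) with 60/90/60 samples per
class.

* **Moderate contrast** (ordering experiments): every lesion is
  band-preferential — full darkening in its preferred band, 10% of it in
  the other — and the red band darkens lesions more strongly (0.6 vs
  0.35, the re-absorption contrast advantage of 675 nm), so each band has
  genuine blind spots that only the other band resolves.  Mildly injured
  fruit carry 3-8 spots of radius 4-7 px at reference scale: the grading
  being emulated is visual, so a "mild" fruit has noticeable symptoms by
  definition, and sub-pixel lesions at the working resolution would be
  unphysical detection targets.  Severely injured fruit carry 2-6 patches
  of radius 8-14 px, making the mild/severe *total lesion-area*
  distributions overlap — this reproduces the mild-vs-severe
  confusability that dominates three-class grading errors in practice and
  is what makes the three-class task measurably harder than the two-class
  task.
* **Strong contrast** (saturation check): darkening 0.6/0.7, all lesions
  fully visible in both bands.

A deliberate consequence of linear classification at desk scale: feature
fusion (334 dimensions against 126 training rows) costs real variance, and
a linear SVM cannot express the either-band OR-detection that would rescue
a sample whose only symptom is a single barely-visible spot.  The moderate
condition therefore keeps per-band symptom signals solid while the
blind-spot structure gives fusion its information advantage; with
weaker-symptom configurations the fused input measurably *trails* the
single bands, which is a finding about linear fusion, not a bug.

## Problem sizes

Unit tests run at 128 px.  BEMD completeness and vignetting-flattening
checks run at the full 512 px reference (10 and 20 images).  Segmentation
IoU runs at 256 px (20 images).  Classification experiments run at 192 px
with 210 (moderate) and 70 (strong) samples and 30 replicates.  NCA
recovery uses 120 samples x 100 features over 20 seeded runs; LSD
calibration uses 1000 simulated null datasets.  These sizes are the
package's working defaults and are stated here so results can be
reproduced exactly.
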