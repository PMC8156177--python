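# cfidetect

Dual-band chlorophyll-fluorescence image analysis for detecting chilling
injury in pickling cucumbers.

Chilling-sensitive produce stored below its tolerance temperature develops
chilling injury (CI): pitting, water-soaked spots, discoloration, decay.
Injured tissue has impaired chlorophyll and fluoresces weakly under UV-blue
excitation, so CI-affected areas appear as **dark spots or patches** in
chlorophyll-fluorescence images.  This package implements a complete
analysis pipeline for such images at two emission bands — 675 nm (red,
strongly re-absorbed by chlorophyll, dim but contrast-rich) and 750 nm
(far-red, bright, used for segmentation) — and a synthetic scene generator
that emulates the statistical structure of such imaging campaigns, so every
stage is testable without proprietary fruit images.

The pipeline:

1. **Scene generation** (`cfidetect.synth`) — labelled dual-band 16-bit
   image pairs: superellipse fruit, class-dependent lesions, cos⁴
   vignetting, sensor noise.  Injury classes: 0 = normal, 1 = mildly
   injured (few small spots), 2 = severely injured (more/larger patches).
2. **Segmentation** (`cfidetect.segment`) — automatic unimodal-histogram
   (Rosin) thresholding of the 750 nm image, largest component + hole fill.
3. **Vignetting correction** (`cfidetect.bemd`) — bi-dimensional empirical
   mode decomposition FI = Σᵢ IMFᵢ + R and the ratio reconstruction

   FI_corr = (FI + Σ_{i=2..k} IMFᵢ − IMF₁) / R,  with n = 6, k = 3,

   which divides out the slowly varying residual trend R that carries the
   vignetting.
4. **Features** (`cfidetect.features`) — 167 per band: 28 Haralick (14 GLCM
   statistics × mean/range over 4 offsets), 59 uniform LBP, 67 Gabor,
   6 intensity, 7 Hu moments; dual-band fusion concatenates to 334.
5. **Classification** (`cfidetect.model`) — linear soft-margin SVM,
   C tuned by 5-fold CV over [1e-4, 1e4], evaluated over 30 replicated
   stratified 6:4 splits; NCA feature ranking with incremental top-100
   subset evaluation.
6. **Metrics** (`cfidetect.metrics`) — TN/TP (two-class) or TN/TP1/TP2
   (three-class) and overall accuracy, compared across image inputs with
   ANOVA + protected Fisher's LSD and a compact letter display.

## Worked example

```python
import dataclasses
from cfidetect import (SceneParams, generate_sample, segment_fruit,
                       bemd_decompose, correct_vignetting)

params = dataclasses.replace(SceneParams(seed=7).scaled(256),
                             vignetting_strength=0.4)
sample = generate_sample(params, 0)           # lesion-free fruit
mask = segment_fruit(sample.image_750)
result = bemd_decompose(sample.image_750)
corrected = correct_vignetting(result)

raw = sample.image_750.astype_float()
cv = lambda img: img[mask.mask].std() / img[mask.mask].mean()
print(f"threshold {mask.threshold:.0f} counts, "
      f"in-mask CV {cv(raw):.4f} -> {cv(corrected):.4f}")
```

prints (exactly, for this seed):

```
threshold 1158 counts, in-mask CV 0.0436 -> 0.0024
```

The threshold separates the near-zero background from the fruit; the
coefficient of variation of fruit-pixel intensities drops by an order of
magnitude
because the correction divides out the 40% corner falloff, leaving only
sensor noise.  The `examples/` directory has one short script per
capability (scene generation, segmentation + correction, feature
extraction, replicated classification, NCA selection).

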