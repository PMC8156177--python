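"""Replicated SVM classification of a small synthetic dataset.

Builds a 15/22/15-sample dataset at moderate band-complementary contrast,
extracts fused features, runs 10 replicated 6:4 splits for the three image
inputs, and compares their mean accuracies with ANOVA + Fisher's LSD.
(A research-scale run would use more samples and 30 replicates; see
scripts/acceptance.py.)
"""

from cfidetect import compare_inputs, generate_dataset
from cfidetect.pipeline import build_feature_table
from cfidetect.study import band_comparison, moderate_contrast_params

samples = generate_dataset(moderate_contrast_params(seed=5), (15, 22, 15), seed=5)
table = build_feature_table(samples)

summaries = band_comparison(table, task="two", seed=11, replicates=10)
comparison = compare_inputs(list(summaries.values()))

print("two-class (normal vs injured), 10 replicates:")
for label, s in summaries.items():
    print(f"  {label:12s} ACC {s.mean()['ACC']:5.1f} +- {s.se()['ACC']:.1f} %   "
          f"TN {s.mean()['TN']:5.1f}  TP {s.mean()['TP']:5.1f}   "
          f"letter {comparison.letters[label]}")
print(f"ANOVA F = {comparison.anova_f:.2f}, p = {comparison.anova_p:.3g}")
print("Inputs sharing a letter are statistically indistinguishable at the "
      "5% level under the protected-LSD procedure.")
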