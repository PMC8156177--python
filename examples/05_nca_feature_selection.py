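"""NCA feature ranking and incremental top-m evaluation.

Uses a synthetic feature matrix with 10 informative and 90 noise features so
the ground truth of "which features matter" is known, learns NCA weights,
and traces test accuracy as the top-ranked features are added one at a time.
"""

import numpy as np
import pandas as pd

from cfidetect.features import FeatureTable
from cfidetect.model import TrainConfig, incremental_selection, nca_rank

rng = np.random.default_rng(17)
n_per = 60
y = np.array([0] * n_per + [1] * n_per)
X = rng.normal(0, 1, (2 * n_per, 100))
X[:, :10] += 1.6 * y[:, None]  # 10 informative features

cols = [f"f{i:03d}_{'675' if i % 2 else '750'}" for i in range(100)]
ids = [f"s{i:04d}" for i in range(len(X))]
table = FeatureTable(pd.DataFrame(X, index=ids, columns=cols),
                     pd.Series(y, index=ids, name="label"))

weights = nca_rank(X, y, seed=17)
top10 = set(weights.ranking[:10])
print(f"top-10 NCA-ranked features contain {len(top10 & set(range(10)))}/10 "
      f"of the truly informative ones")

cfg = TrainConfig(task="two", replicates=5, seed=3)
res = incremental_selection(table, cfg, top_m=30)
print("mean ACC (%) at m = 1, 5, 10, 20, 30 top features:")
print("  " + "  ".join(f"m={m}: {res.incremental_curve[m - 1]:.1f}"
                       for m in (1, 5, 10, 20, 30)))
print(f"selected subset size (smallest m within 1 SE of full-feature ACC): "
      f"{res.selected_size}")
print("Accuracy climbs while informative features arrive, then plateaus — "
      "noise features add nothing.")
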