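"""Classification rates and replicate-level statistical comparison.

Rates follow the fruit-grading convention: TN is the percentage of normal
(class 0) fruit classified correctly, TP the percentage of injured fruit
classified correctly (two-class task), and TP1 / TP2 the per-class correct
percentages for mildly and severely injured fruit (three-class task); ACC is
the overall percentage correct.  Mean accuracies across image-input types
are compared with a one-way ANOVA followed, when significant, by Fisher's
least-significant-difference pairwise tests at the same level (protected
LSD), summarized as a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "confusion_rates",
    "ReplicateSummary",
    "ComparisonResult",
    "compare_inputs",
    "lsd_threshold",
    "plot_summaries",
]


def confusion_rates(y_true, y_pred, task: str) -> dict:
    """Per-class correct-classification percentages and overall accuracy.

    Two-class labels are {0 = normal, 1 = injured}; three-class labels are
    {0, 1, 2}.  A class absent from the truth has an undefined rate, reported
    as NaN; ACC is always computed over all tested samples.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if task not in ("two", "three"):
        raise ValueError("task must be 'two' or 'three'")
    valid = {0, 1} if task == "two" else {0, 1, 2}
    if not set(np.unique(y_true)) <= valid or not set(np.unique(y_pred)) <= valid:
        raise ValueError(f"labels outside {sorted(valid)} for task {task!r}")

    def rate(cls: int) -> float:
        sel = y_true == cls
        if not sel.any():
            return float("nan")
        return 100.0 * float(np.mean(y_pred[sel] == cls))

    out = {"TN": rate(0)}
    if task == "two":
        out["TP"] = rate(1)
    else:
        out["TP1"] = rate(1)
        out["TP2"] = rate(2)
    out["ACC"] = 100.0 * float(np.mean(y_true == y_pred))
    return out


@dataclass
class ReplicateSummary:
    """Per-replicate rate records for one image-input type and task."""

    records: pd.DataFrame  # one row per replicate; columns include ACC
    input_label: str  # e.g. "FI675", "FI750", "FI675-FI750"
    task: str

    def __post_init__(self) -> None:
        if "ACC" not in self.records.columns:
            raise ValueError("records must contain an ACC column")

    @property
    def acc(self) -> np.ndarray:
        return self.records["ACC"].to_numpy(dtype=float)

    def mean(self) -> pd.Series:
        return self.records.mean(numeric_only=True)

    def se(self) -> pd.Series:
        n = len(self.records)
        if n < 2:
            return self.records.mean(numeric_only=True) * 0.0
        return self.records.std(numeric_only=True, ddof=1) / np.sqrt(n)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean(), "se": self.se()})


def lsd_threshold(mse: float, n_per_group: float, df_error: int, alpha: float = 0.05) -> float:
    """Fisher's least significant difference: t_{1-a/2, df} * sqrt(2 MSE / n)."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, df_error) * np.sqrt(2.0 * mse / n_per_group))


@dataclass
class ComparisonResult:
    """ANOVA + protected-LSD comparison of mean accuracies across inputs."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: a, b, mean_diff, p
    letters: dict[str, str]  # compact letter display per input label
    lsd: float | None  # significance threshold on |mean difference|

    def significant(self, alpha: float = 0.05) -> bool:
        return self.anova_p < alpha


def _letter_display(labels: list[str], means: dict[str, float],
                    differs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups not significantly different share a letter.

    Maximal cliques of the "not different" graph are enumerated (group counts
    here are tiny), ordered by their best mean, and lettered a, b, c, ...
    """
    order = sorted(labels, key=lambda g: -means[g])
    cliques = []
    for size in range(len(order), 0, -1):
        for combo in combinations(order, size):
            if any(set(combo) <= set(c) for c in cliques):
                continue
            pairs = combinations(combo, 2)
            if all((a, b) not in differs and (b, a) not in differs for a, b in pairs):
                cliques.append(frozenset(combo))
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in labels}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for g in order:
            if g in clique:
                letters[g] += ch
    return letters


def compare_inputs(summaries: list[ReplicateSummary], alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA on per-replicate ACC, then protected Fisher's LSD.

    Requires a balanced design (equal replicate counts).  With zero
    between-group variance the ANOVA p-value is 1 by convention and every
    input shares one letter.  Pairwise tests use the pooled MSE with
    N - g error degrees of freedom; only a significant ANOVA unlocks them.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries to compare")
    ns = {len(s.records) for s in summaries}
    if len(ns) != 1:
        raise ValueError("unequal replicate counts: balanced design required")
    n = ns.pop()
    labels = [s.input_label for s in summaries]
    if len(set(labels)) != len(labels):
        raise ValueError("input labels must be unique")
    groups = {s.input_label: s.acc for s in summaries}
    means = {g: float(v.mean()) for g, v in groups.items()}

    mean_vals = np.array([means[g] for g in labels])
    if np.ptp(mean_vals) <= 1e-12 * max(1.0, np.abs(mean_vals).max()):
        # identical (or numerically identical) group means: no evidence of
        # any difference; define p = 1
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*[groups[g] for g in labels])
        f_stat, p_val = float(f_stat), float(p_val)

    g = len(labels)
    df_error = g * n - g
    mse = float(np.mean([groups[lbl].var(ddof=1) for lbl in labels]))  # pooled (balanced)
    rows = []
    differs: set[tuple[str, str]] = set()
    lsd = None
    if p_val < alpha and mse > 0:
        lsd = lsd_threshold(mse, n, df_error, alpha)
        for a, b in combinations(labels, 2):
            diff = means[a] - means[b]
            t = abs(diff) / np.sqrt(2.0 * mse / n)
            p_pair = 2.0 * float(stats.t.sf(t, df_error))
            rows.append({"a": a, "b": b, "mean_diff": diff, "p": p_pair})
            if p_pair < alpha:
                differs.add((a, b))
    else:
        for a, b in combinations(labels, 2):
            rows.append({"a": a, "b": b, "mean_diff": means[a] - means[b], "p": float("nan")})

    letters = _letter_display(labels, means, differs)
    return ComparisonResult(
        anova_f=f_stat, anova_p=p_val,
        pairwise=pd.DataFrame(rows), letters=letters, lsd=lsd,
    )


def plot_summaries(summaries: list[ReplicateSummary], comparison: ComparisonResult | None = None,
                   ax=None):
    """Bar chart of mean rates with standard-error bars, one group per input.

    Letters from a comparison, when given, annotate the ACC bars.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    metric_names = [c for c in summaries[0].records.columns
                    if c in ("TN", "TP", "TP1", "TP2", "ACC")]
    width = 0.8 / len(summaries)
    x = np.arange(len(metric_names))
    for i, s in enumerate(summaries):
        m = s.mean()[metric_names]
        e = s.se()[metric_names]
        pos = x + (i - (len(summaries) - 1) / 2) * width
        ax.bar(pos, m, width=width, yerr=e, capsize=3, label=s.input_label)
        if comparison is not None and "ACC" in metric_names:
            j = metric_names.index("ACC")
            ax.text(pos[j], m.iloc[j] + e.iloc[j] + 1,
                    comparison.letters.get(s.input_label, ""), ha="center")
    ax.set_xticks(x, metric_names)
    ax.set_ylabel("rate (%)")
    ax.set_ylim(0, 105)
    ax.legend()
    return ax
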