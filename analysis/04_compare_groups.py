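#!/usr/bin/env python
"""Compare per-lobe % positive between groups with the KS test.

Reads results/cohort_lobes.csv (from 03_quantify_cohort), runs the
two-sample Kolmogorov-Smirnov comparison with per-group mean, SEM and
5%/95% percentiles, writes results/group_comparison.csv, and saves a
scatter + whisker summary figure under scratch/.
"""

from pathlib import Path

import pandas as pd

from lobequant.stats import comparison_frame, ks_compare

ROOT = Path(__file__).resolve().parents[1]

lobes = pd.read_csv(ROOT / "results" / "cohort_lobes.csv").dropna(
    subset=["percent_positive"]
)
labels = list(dict.fromkeys(lobes["group_label"]))
groups = {lab: lobes.loc[lobes["group_label"] == lab, "percent_positive"] for lab in labels}

comps = [
    ks_compare(groups[labels[i]], groups[labels[j]], labels[i], labels[j])
    for i in range(len(labels))
    for j in range(i + 1, len(labels))
]
comparison_frame(comps).to_csv(ROOT / "results" / "group_comparison.csv", index=False)

for c in comps:
    print(
        f"{c.label_a} (n={c.n_a}, mean {c.mean_a:.1f} +/- {c.sem_a:.2f} SEM, "
        f"5-95% [{c.pct5_a:.1f}, {c.pct95_a:.1f}]) vs "
        f"{c.label_b} (n={c.n_b}, mean {c.mean_b:.1f} +/- {c.sem_b:.2f} SEM, "
        f"5-95% [{c.pct5_b:.1f}, {c.pct95_b:.1f}]): "
        f"D={c.ks_statistic:.3f}, p={c.p_value:.3g}"
    )

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    for i, lab in enumerate(labels):
        vals = groups[lab]
        ax.scatter([i] * len(vals), vals, s=14, alpha=0.7, color="0.3", zorder=2)
        mean, p5, p95 = vals.mean(), vals.quantile(0.05), vals.quantile(0.95)
        ax.hlines(mean, i - 0.2, i + 0.2, color="red", lw=2, zorder=3)
        ax.vlines(i, p5, p95, color="red", lw=1, zorder=1)
    ax.set_xticks(range(len(labels)), labels)
    ax.set_ylabel("% positive / N cells per lobe")
    fig.tight_layout()
    (ROOT / "scratch").mkdir(exist_ok=True)
    fig.savefig(ROOT / "scratch" / "group_comparison.png", dpi=150)
    print("figure -> scratch/group_comparison.png")
except ImportError:
    print("matplotlib unavailable; skipped the figure")

print("comparison table -> results/group_comparison.csv")
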