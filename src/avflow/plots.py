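"""Figure helpers: per-segment metric profiles and ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import ROCResult


def plot_segment_profiles(segment_means: pd.DataFrame, ax=None):
    """Mean metric per 1 cm segment along each limb (anastomosis excluded)."""
    df = segment_means[~segment_means.is_anastomosis]
    metrics = sorted(df.metric.unique())
    if ax is None:
        _, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3), squeeze=False)
        axes = axes[0]
    else:
        axes = [ax] * len(metrics)
    for a, m in zip(axes, metrics):
        sub = df[df.metric == m]
        for limb, g in sub.groupby("limb"):
            a.plot(g.seg_index, g.value, marker="o", label=limb)
        a.set_xlabel("1 cm segment")
        a.set_ylabel(m)
        a.legend(fontsize=7)
    plt.tight_layout()
    return axes[0].figure


def plot_roc(results: list[ROCResult], ax=None):
    """Empirical ROC curves with AUC annotations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for r in results:
        ax.plot(r.curve[:, 0], r.curve[:, 1],
                label=f"{'+'.join(r.variables)} (AUC={r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7, loc="lower right")
    return ax.figure
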