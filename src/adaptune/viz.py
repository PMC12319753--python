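"""Plots: cluster tuning curves with SEM and slope comparison."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clusters import ClusterComparison
from .norms import BIN_LABELS


def plot_tuning_curves(comparison: ClusterComparison, path) -> None:
    """Mean z-scored tuning curve per cluster with SEM bars, plus the
    per-subject slope comparison."""
    z = comparison.z_curves  # (n, k, 4)
    n, k, _ = z.shape
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    x = np.arange(1, 5)
    for c in range(k):
        mean = z[:, c].mean(axis=0)
        sem = z[:, c].std(axis=0, ddof=1) / np.sqrt(n)
        axes[0].errorbar(x, mean, yerr=sem, marker="o", capsize=3, label=f"cluster {c + 1}")
    axes[0].set_xticks(x, BIN_LABELS)
    axes[0].set_xlabel("deviant condition")
    axes[0].set_ylabel("release (z-scored beta)")
    axes[0].legend(frameon=False)

    means = comparison.slopes.mean(axis=0)
    sems = comparison.slopes.std(axis=0, ddof=1) / np.sqrt(n)
    axes[1].bar(np.arange(k) + 1, means, yerr=sems, capsize=4,
                tick_label=[f"cluster {c + 1}" for c in range(k)])
    axes[1].set_ylabel("SC-to-SD slope")
    if k >= 2:
        axes[1].set_title(f"paired t = {comparison.slope_t:.2f}, "
                          f"one-tailed p = {comparison.slope_p_one_tailed:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
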