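"""Minimal matplotlib renderings of the plot-data tables.

The tab-separated data tables are the contract; these figures are a
convenience for quick inspection and are never compared pixel-wise.
"""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_scatter(analysis, ax=None):
    """SNP-exposure vs SNP-outcome effects with error bars and the IVW slope."""
    ax = _ax(ax)
    t = analysis.scatter
    ax.errorbar(t["x"], t["y"], xerr=t["sigma_x"], yerr=t["sigma_y"], fmt="o", ms=4, lw=1)
    xs = np.linspace(0, t["x"].abs().max() * 1.1, 50)
    ax.plot(xs, t["fitted_slope"].iloc[0] * xs, "-", color="C1", label="IVW fit")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("SNP effect on exposure (SD)")
    ax.set_ylabel("SNP effect on outcome (log-odds)")
    ax.set_title(analysis.exposure_id)
    ax.legend()
    return ax


def plot_funnel(analysis, ax=None):
    """Per-SNP Wald ratio against its precision, with the pooled estimate."""
    ax = _ax(ax)
    t = analysis.funnel
    ax.plot(t["ratio"], t["precision"], "o", ms=4)
    ax.axvline(t["pooled_beta"].iloc[0], color="C1", ls="--", label="pooled")
    ax.set_xlabel("Wald ratio (log-odds per SD)")
    ax.set_ylabel("precision (1/SE)")
    ax.set_title(analysis.exposure_id)
    ax.legend()
    return ax


def plot_forest(analysis, ax=None):
    """Per-SNP and pooled odds ratios with confidence bars."""
    ax = _ax(ax)
    t = analysis.forest
    ys = np.arange(len(t))[::-1]
    for y, (_, row) in zip(ys, t.iterrows()):
        marker = "D" if row["kind"] == "pooled" else "s"
        ax.plot([row["ci_low"], row["ci_high"]], [y, y], "-", color="C0", lw=1)
        ax.plot(row["or"], y, marker, color="C0", ms=6)
    ax.axvline(1.0, color="grey", lw=0.5)
    ax.set_yticks(ys)
    ax.set_yticklabels(t["label"])
    ax.set_xlabel("OR (95% CI)")
    ax.set_title(analysis.exposure_id)
    return ax
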