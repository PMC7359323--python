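"""Diagnostic plots: design-space violins and segregation-index traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .params import DESCRIPTOR_NAMES  # noqa: E402


def plot_design_space(table, path=None):
    """Violin plot of the 9 descriptor distributions in a feature table."""
    df = table.frame if hasattr(table, "frame") else table
    fig, axes = plt.subplots(3, 3, figsize=(10, 8))
    for ax, name in zip(axes.ravel(), DESCRIPTOR_NAMES):
        vals = df[name].to_numpy(float)
        if np.ptp(vals) > 0:
            ax.violinplot(vals, showmeans=True, showextrema=True)
        else:
            ax.axhline(vals[0], color="C0")
        ax.set_title(name, fontsize=9)
        ax.set_xticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_series(series, cutoff=None, path=None):
    """psi(t) trace (bulk and, when present, per radial region)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series.times, series.psi_bulk, label="bulk", lw=2)
    if series.psi_by_region is not None:
        for r in range(series.psi_by_region.shape[1]):
            ax.plot(series.times, series.psi_by_region[:, r],
                    lw=1, alpha=0.7, label=f"R{r + 1}")
    if cutoff is not None:
        ax.axhline(cutoff, ls="--", color="k", label=f"cutoff {cutoff}")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("segregation index $\\psi$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
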