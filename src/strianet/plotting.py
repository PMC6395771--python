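"""Diagnostic plots: preservation composites per module and the
reference-vs-case kME scatter of the least preserved module."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .preservation import PreservationStats

__all__ = ["preservation_plot", "kme_scatter"]


def preservation_plot(stats: PreservationStats, selected: int, path=None):
    """Module size vs medianRank and Zsummary; the selected (least
    preserved) module is highlighted.  Low Zsummary / high medianRank mark
    weak preservation; dashed guides at Zsummary 2 and 10."""
    summary = stats.summary
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, col in zip(axes, ["medianRank", "Zsummary"]):
        for m, row in summary.iterrows():
            color = "tab:red" if m == selected else "tab:gray"
            ax.scatter(row.get("size", 0), row[col], c=color, s=40, zorder=3)
            ax.annotate(str(m), (row.get("size", 0), row[col]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
        ax.set_xlabel("module size")
        ax.set_ylabel(col)
    axes[1].axhline(2, ls="--", c="k", lw=0.8)
    axes[1].axhline(10, ls="--", c="k", lw=0.8)
    fig.suptitle("Module preservation (red = least preserved)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def kme_scatter(
    kme_ref: pd.DataFrame, kme_test: pd.DataFrame, module: int, path=None
):
    """Own-module kME in the reference (x) vs the test condition (y)."""
    common = kme_ref.index.intersection(kme_test.index)
    x = kme_ref.loc[common, module]
    y = kme_test.loc[common, module]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, s=8, alpha=0.6)
    ax.axhline(0, c="k", lw=0.5)
    ax.axvline(0, c="k", lw=0.5)
    ax.set_xlabel("kME (control)")
    ax.set_ylabel("kME (case)")
    ax.set_title(f"module {module} kME")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
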