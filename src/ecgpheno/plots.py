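"""Figure helpers: KM curves, Manhattan plots, saliency overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .explain import SaliencyMap
from .survival import KMCurve

__all__ = ["plot_km", "plot_manhattan", "plot_saliency"]


def plot_km(curves: dict[str, KMCurve], path=None, ax=None):
    """Step plot of per-phenogroup survival curves."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, c in curves.items():
        t = np.concatenate([[0.0], c.times])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=f"phenogroup {label}")
    ax.set_xlabel("years")
    ax.set_ylabel("survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_manhattan(table: pd.DataFrame, path=None, ax=None):
    """-log10 p per phenotype with the Bonferroni line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    sig = table.get("significant", pd.Series(False, index=table.index))
    ax.scatter(np.arange(len(table)), table["neglog10_p"],
               s=np.where(sig, 40, 10),
               c=np.where(table["effect_sign"] >= 0, "tab:red", "tab:blue"))
    if "neglog10_threshold" in table.attrs:
        ax.axhline(table.attrs["neglog10_threshold"], color="k", ls="--")
    ax.set_xticks(np.arange(len(table)))
    ax.set_xticklabels(table["phenotype"], rotation=90, fontsize=7)
    ax.set_ylabel(r"$-\log_{10} p$")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_saliency(signal: np.ndarray, saliency: SaliencyMap, fs: float = 400.0,
                  leads=(0, 1, 6), path=None):
    """Lead traces with green-shaded importance underneath."""
    fig, axes = plt.subplots(len(leads), 1, figsize=(9, 2 * len(leads)),
                             sharex=True)
    t = np.arange(signal.shape[1]) / fs
    sal = saliency.values[0]
    sal_norm = sal / sal.max() if sal.max() > 0 else sal
    for ax, li in zip(np.atleast_1d(axes), leads):
        ax.fill_between(t, signal[li].min(), signal[li].max(),
                        where=sal_norm > 0.5, color="green", alpha=0.25)
        ax.plot(t, signal[li], lw=0.7, color="k")
        ax.set_ylabel(f"lead {li}")
    np.atleast_1d(axes)[-1].set_xlabel("time (s)")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
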