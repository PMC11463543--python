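"""Volcano and sequence-logo plots (matplotlib, no interactive backend)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .screen import PositionFrequencyMatrix  # noqa: E402


def volcano(table: pd.DataFrame, lfc_cutoff: float = 1.0, q_cutoff: float = 0.01,
            ax=None):
    """Volcano plot of log2FC vs -log10(q) with the call cutoffs dashed."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ok = table["q"].notna()
    x = table.loc[ok, "log2FC"]
    y = -np.log10(table.loc[ok, "q"].clip(lower=1e-300))
    called = table.loc[ok, "enriched"]
    ax.scatter(x[~called], y[~called], s=6, c="0.7", lw=0)
    ax.scatter(x[called], y[called], s=8, c="tab:green", lw=0)
    ax.axvline(lfc_cutoff, ls="--", c="k", lw=0.8)
    ax.axhline(-np.log10(q_cutoff), ls="--", c="k", lw=0.8)
    ax.set_xlabel("log2 FC (tagged vs control)")
    ax.set_ylabel("-log10(q)")
    return ax


def logo(pfm: PositionFrequencyMatrix, ax=None, max_letters: int = 4):
    """Information-content-scaled letter-stack logo of a PFM."""
    if ax is None:
        _, ax = plt.subplots(figsize=(0.45 * len(pfm.probs), 2.4))
    for i, (pos, row) in enumerate(pfm.probs.iterrows()):
        heights = (row * pfm.information[i]).sort_values(ascending=False)
        y = 0.0
        for aa, h in heights.head(max_letters).items():
            if h <= 0:
                continue
            ax.text(i + 1, y + h / 2, aa, ha="center", va="center",
                    fontsize=8 + 20 * h / np.log2(20), family="monospace")
            y += h
    ax.set_xlim(0.5, len(pfm.probs) + 0.5)
    ax.set_ylim(0, np.log2(20))
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    return ax
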