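"""Plotting helpers: forest plots for pooled odds ratios and surface maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe default
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_plot(table: pd.DataFrame, ax=None, title: str | None = None):
    """Forest plot from a :func:`housemap.assoc.forest_data` table.

    Survey odds ratios with 95% CI error bars, the pooled estimate as a
    diamond, a dashed line at the pooled OR and a solid null line at OR 1.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(table) + 1.5))
    surveys = table[table["kind"] == "survey"].reset_index(drop=True)
    pooled = table[table["kind"] == "pooled"].iloc[0]
    ys = np.arange(len(surveys))[::-1] + 1
    ax.errorbar(surveys["or"], ys,
                xerr=[surveys["or"] - surveys["lower"],
                      surveys["upper"] - surveys["or"]],
                fmt="s", color="black", ms=4, capsize=2, lw=1)
    # pooled diamond at y = 0
    h = 0.25
    ax.fill([pooled["lower"], pooled["or"], pooled["upper"], pooled["or"]],
            [0, h, 0, -h], color="0.3")
    ax.axvline(1.0, color="tab:blue", lw=1)
    ax.axvline(pooled["or"], color="tab:red", lw=1, ls="--")
    ax.set_yticks(list(ys) + [0])
    ax.set_yticklabels(list(surveys["label"]) + ["Pooled"])
    ax.set_xscale("log")
    ax.set_xlabel("Odds ratio (log scale)")
    if title:
        ax.set_title(title)
    return ax


def surface_map(surface: np.ndarray, ax=None, title: str | None = None,
                vmin: float = 0.0, vmax: float = 1.0):
    """Prevalence raster as an image (origin at the grid's south-west)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(surface, origin="lower", vmin=vmin, vmax=vmax,
                   cmap="viridis")
    plt.colorbar(im, ax=ax, shrink=0.8, label="prevalence")
    if title:
        ax.set_title(title)
    return ax
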