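"""Optional plotting conveniences (matplotlib); never part of the tested
analysis surface."""

from __future__ import annotations

import pandas as pd


def plot_km(km_high: pd.DataFrame, km_low: pd.DataFrame, ax=None, title: str = ""):
    """Step plot of two Kaplan-Meier curves (high vs low)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve, label in ((km_high, "high"), (km_low, "low")):
        ax.step([0, *curve["time"]], [1.0, *curve["survival"]], where="post", label=label)
    ax.set_xlabel("time (years)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


def plot_correlation_heatmap(corr: pd.DataFrame, ax=None, title: str = ""):
    """Heatmap of a correlation matrix or gene x metric correlation table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.3 * corr.shape[1]),
                                      max(4, 0.3 * corr.shape[0])))
    im = ax.imshow(corr.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(corr.shape[1]), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(corr.shape[0]), corr.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="correlation")
    if title:
        ax.set_title(title)
    return ax
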