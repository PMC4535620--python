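"""Figure export: landscape grids and MA plots."""

from __future__ import annotations

import numpy as np


def plot_landscape(ls, classified=None, ax=None):
    """Render a metagene landscape as a 2D colour grid.

    Over/under-classified units (from ``classify_metagenes``) are outlined
    when ``classified`` is given.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(ls.grid, cmap="RdBu_r", origin="upper")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if classified is not None:
        for r, c in np.argwhere(classified != 0):
            ax.add_patch(
                Rectangle((c - 0.5, r - 0.5), 1, 1, fill=False, edgecolor="black", lw=0.8)
            )
    ax.set_title(ls.sample)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_ma(results, fdr_threshold: float = 0.01, ax=None):
    """MA plot: log2 fold change against mean normalized count, with
    significant genes (fdr below threshold) highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.log10(results["baseMean"] + 1)
    sig = results["fdr"] < fdr_threshold
    ax.scatter(x[~sig], results.loc[~sig, "log2FC"], s=3, c="0.6", lw=0)
    ax.scatter(x[sig], results.loc[sig, "log2FC"], s=4, c="crimson", lw=0)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("log10 mean normalized count")
    ax.set_ylabel("log2 fold change")
    return ax
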