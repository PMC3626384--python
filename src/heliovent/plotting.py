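"""Quality-control figures: mask overlays and agreement plots."""

from __future__ import annotations

import numpy as np

from .image_io import ImageStack, MaskStack
from .quantification_stats import BlandAltman


def plot_slice_overlay(stack: ImageStack, mask: MaskStack, slice_index: int, ax=None):
    """Grayscale slice with the mask boundary drawn on top."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(stack.slices[slice_index], cmap="gray", interpolation="nearest")
    ax.contour(mask.slices[slice_index], levels=[0.5], colors="r", linewidths=0.8)
    ax.set_title(f"slice {slice_index}")
    ax.axis("off")
    return ax


def plot_label_map(label_map: np.ndarray, slice_index: int, ax=None):
    """Ventilation-class map (0 background, 1..4 negligible..high)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots()
    cmap = ListedColormap(["black", "dimgray", "royalblue", "gold", "firebrick"])
    ax.imshow(label_map[slice_index], cmap=cmap, vmin=0, vmax=4, interpolation="nearest")
    ax.axis("off")
    return ax


def plot_bland_altman(pairs: np.ndarray, ba: BlandAltman, ax=None):
    """Difference-vs-mean scatter with the mean difference and 95% limits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    arr = np.asarray(pairs, dtype=float)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    ax.scatter(means, diffs, s=12)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a - b)")
    return ax
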