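"""Figure helpers: grid fraction maps and polar tuning plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_fraction_maps(comparison, path=None):
    """Control/mutant fraction maps and the classified difference map."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    diff = comparison.fractions_b - comparison.fractions_a
    vmax = max(comparison.fractions_a.max(), comparison.fractions_b.max())
    for ax, data, title in zip(
            axes, [comparison.fractions_a, comparison.fractions_b, diff],
            ["control fraction", "mutant fraction", "difference (mutant - control)"]):
        lim = vmax if title != "difference (mutant - control)" else np.abs(diff).max()
        im = ax.imshow(data.T, origin="lower",
                       cmap="viridis" if "fraction" in title else "coolwarm",
                       vmin=0 if "fraction" in title else -lim, vmax=lim)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    for ix in range(comparison.n):
        for iy in range(comparison.n):
            if comparison.classes[ix, iy] == "decreased":
                axes[2].plot(ix, iy, "k*", ms=8)
            elif comparison.classes[ix, iy] == "increased":
                axes[2].plot(ix, iy, "w*", ms=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_polar_tuning(thetas_deg, radii, path=None, radius_label="DSI"):
    """Scatter of per-cell preferred direction (angle) vs a radial metric."""
    fig = plt.figure(figsize=(4.5, 4.5))
    ax = fig.add_subplot(projection="polar")
    ax.scatter(np.deg2rad(np.asarray(thetas_deg, float)),
               np.asarray(radii, float), s=8, alpha=0.5)
    ax.set_title(radius_label)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
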