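"""Matplotlib figures: DNA-content histograms with gates, intensity surfaces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cytometry import IntensityHistogram, PhaseGates

__all__ = ["plot_histogram", "plot_surface"]


def plot_histogram(
    hist: IntensityHistogram,
    gates: PhaseGates | None = None,
    path: str | Path | None = None,
    title: str = "DNA content histogram",
):
    """Bar histogram of counts vs bin centre, with gate windows shaded."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(hist.bin_centers, hist.counts, width=hist.interval, color="0.4")
    if gates is not None:
        for window, color, name in (
            (gates.g1, "tab:blue", "G1"),
            (gates.s, "tab:orange", "S"),
            (gates.g2m, "tab:green", "G2/M"),
        ):
            ax.axvspan(window.lo, window.hi, alpha=0.2, color=color, label=name)
        ax.legend()
    ax.set_xlabel("integrated intensity (counts)")
    ax.set_ylabel("cell count")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def plot_surface(
    surface: np.ndarray, path: str | Path | None = None, title: str = "intensity surface"
):
    """3-D surface rendering of a (downsampled) field, flat peaks visible."""
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    yy, xx = np.mgrid[: surface.shape[0], : surface.shape[1]]
    ax.plot_surface(xx, yy, surface, cmap="viridis", linewidth=0)
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
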