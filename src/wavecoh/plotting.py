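"""Coherence-map rendering: heatmap with significant patches outlined."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .coherence import CoherenceMap


def plot_coherence(
    cmap: CoherenceMap,
    patches=None,  # accepted for API symmetry; outlines come from the mask
    path: str | Path = "coherence.png",
    title: str | None = None,
) -> Path:
    """Heatmap of the coherence map over 3-30 Hz.

    Colour intensity saturates above 0.9 (anything redder is "high
    coherence"); significant regions are outlined in black.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(8, 4))
    mesh = ax.pcolormesh(
        cmap.times, cmap.freqs, cmap.coh, cmap="jet", vmin=0.0, vmax=0.9,
        shading="nearest", rasterized=True,
    )
    if cmap.sig_mask is not None and cmap.sig_mask.any():
        ax.contour(
            cmap.times, cmap.freqs, cmap.sig_mask.astype(float),
            levels=[0.5], colors="black", linewidths=0.8,
        )
    ax.set_yscale("log")
    ax.set_yticks([3, 5, 10, 20, 30])
    ax.get_yaxis().set_major_formatter(plt.ScalarFormatter())
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    cb = fig.colorbar(mesh, ax=ax, extend="max")
    cb.set_label("coherence")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
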