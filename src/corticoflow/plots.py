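"""Minimal PNG export helpers for density maps and triggered averages."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .events import TriggeredResponse
from .metrics import DensityMap


def save_density_map(density: DensityMap, path: str | Path,
                     title: str = "") -> Path:
    """Smoothed pair-density heatmap with the half-peak contour."""
    fig, ax = plt.subplots(figsize=(4, 3.2))
    extent = (density.d_edges[0], density.d_edges[-1],
              density.r_edges[0], density.r_edges[-1])
    ax.imshow(density.smoothed.T, origin="lower", aspect="auto",
              extent=extent, cmap="magma")
    ax.contour(density.smoothed.T, levels=[density.contour_level],
               extent=extent, colors="w", linewidths=1)
    ax.set_xlabel("pair distance (bregma-lambda units)")
    ax.set_ylabel("correlation coefficient")
    if title:
        ax.set_title(title)
    ax.text(0.98, 0.02, f"peak {density.peak_density:.1f}",
            transform=ax.transAxes, ha="right", va="bottom", color="w")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def save_triggered_average(resp: TriggeredResponse, path: str | Path,
                           rois: list[str] | None = None) -> Path:
    """Mean traces with their uncertainty band, one panel per ROI."""
    rois = rois if rois is not None else resp.roi_ids
    n = len(rois)
    ncol = min(4, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.6 * ncol, 1.8 * nrow),
                             sharex=True, sharey=True, squeeze=False)
    for k, roi in enumerate(rois):
        ax = axes[k // ncol][k % ncol]
        i = resp.roi_ids.index(roi)
        ax.fill_between(resp.time_s, resp.ci_low[i], resp.ci_high[i],
                        alpha=0.3, lw=0)
        ax.plot(resp.time_s, resp.mean[i], lw=1)
        ax.axvline(0, color="k", lw=0.5, ls=":")
        ax.set_title(roi, fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("time from onset (s)")
    axes[0][0].set_ylabel("dF/F")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
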