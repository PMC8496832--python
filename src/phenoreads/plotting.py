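"""Figures: entropy-scaled sequence logos, attention profiles, ordinations.

Logos are drawn as stacked letters whose heights are the entropy-scaled
class frequencies, stacked in descending height order per position, with
the class's smoothed mean attention optionally shown as background
shading.  Letters are rendered by stretching text-path glyphs, so no
dedicated logo library is needed.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .interpret import AttentionSummary, ClassLogo
from .ordination import Projection
from .seqio import BASES

LETTER_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
_FONT = FontProperties(family="DejaVu Sans", weight="bold")


def _draw_letter(ax, base: str, x: float, y: float, width: float, height: float) -> None:
    if height <= 0:
        return
    path = TextPath((0, 0), base, size=1, prop=_FONT)
    bbox = path.get_extents()
    transform = (
        Affine2D()
        .translate(-bbox.x0, -bbox.y0)
        .scale(width / bbox.width, height / bbox.height)
        .translate(x, y)
    )
    ax.add_patch(PathPatch(transform.transform_path(path),
                           facecolor=LETTER_COLORS[base], edgecolor="none"))


def plot_logo(
    logo: ClassLogo,
    attention: AttentionSummary | None = None,
    path: str | None = None,
) -> plt.Figure:
    """One panel per class: stacked entropy-scaled letters, attention shading."""
    n_classes, length, _ = logo.S.shape
    fig, axes = plt.subplots(
        n_classes, 1, figsize=(max(6.0, length / 8.0), 1.8 * n_classes),
        sharex=True, squeeze=False,
    )
    ymax = max(float(logo.H.max()), 1e-3)
    for ci, ax in enumerate(axes[:, 0]):
        if attention is not None and logo.classes[ci] in attention.classes:
            row = attention.smoothed[attention.classes.index(logo.classes[ci])]
            shade = row / max(row.max(), 1e-12)
            for pos, s in enumerate(shade):
                if s > 0.05:
                    ax.axvspan(pos, pos + 1, color="gold", alpha=0.5 * s, lw=0)
        for pos in range(length):
            heights = logo.S[ci, pos]
            order = np.argsort(heights)  # tallest on top
            y = 0.0
            for b in order:
                _draw_letter(ax, BASES[b], pos + 0.05, y, 0.9, float(heights[b]))
                y += float(heights[b])
        ax.set_xlim(0, length)
        ax.set_ylim(0, ymax * 1.05)
        ax.set_ylabel(f"{logo.classes[ci]}\nbits", fontsize=8)
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_attention(summary: AttentionSummary, path: str | None = None) -> plt.Figure:
    """Smoothed class-wise mean attention profiles on one axis."""
    fig, ax = plt.subplots(figsize=(8, 3))
    for ci, cls in enumerate(summary.classes):
        ax.plot(np.arange(1, summary.A.shape[1] + 1), summary.smoothed[ci], label=cls)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("mean attention")
    ax.legend(fontsize=8, title=summary.grouping)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ordination(
    projection: Projection,
    colors: Sequence[str],
    markers: Sequence[str] | None = None,
    path: str | None = None,
) -> plt.Figure:
    """PCA scatter coloured by one label set, marker shape by another."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    colors = np.asarray(colors)
    markers = np.asarray(markers) if markers is not None else np.array(["o"] * len(colors))
    marker_cycle = "o^svDP*X"
    mlabels = {m: marker_cycle[i % len(marker_cycle)]
               for i, m in enumerate(np.unique(markers))}
    cmap = plt.get_cmap("tab10")
    clabels = {c: cmap(i % 10) for i, c in enumerate(np.unique(colors))}
    for c in np.unique(colors):
        for m in np.unique(markers):
            mask = (colors == c) & (markers == m)
            if mask.any():
                ax.scatter(
                    projection.coords[mask, 0], projection.coords[mask, 1],
                    s=8, alpha=0.6, color=clabels[c], marker=mlabels[m],
                    label=f"{c}" + ("" if len(mlabels) == 1 else f" / {m}"),
                )
    ve = projection.variance_explained * 100
    ax.set_xlabel(f"PC1 ({ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ve[1]:.1f}%)")
    ax.legend(fontsize=7, markerscale=1.5)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
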