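"""Overlay and summary figures.

The overlay mirrors the tracing check used during analysis: the flattened
topograph with every detected feature's skeleton drawn on top, so an analyst
can confirm that long axes of fibrils and oligomers are traced correctly.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .features import LabelMap
from .io import HeightMap
from .summarize import ConditionSummary


def save_overlay(
    hmap: HeightMap, labmap: LabelMap, path: str | Path, dpi: int = 150
) -> None:
    """Write a PNG of the topograph with detected-feature skeletons in blue."""
    sk = np.zeros(labmap.labels.shape, dtype=bool)
    objs = ndimage.find_objects(labmap.labels)
    for i, sl in enumerate(objs, start=1):
        if sl is None:
            continue
        sk[sl] |= skeletonize(labmap.labels[sl] == i)
    fig, ax = plt.subplots(figsize=(6, 6))
    extent = (0, hmap.shape[1] * hmap.pixel_size / 1000,
              hmap.shape[0] * hmap.pixel_size / 1000, 0)
    im = ax.imshow(hmap.heights, cmap="afmhot", extent=extent)
    overlay = np.zeros((*sk.shape, 4))
    overlay[sk] = (0.1, 0.3, 1.0, 1.0)
    ax.imshow(overlay, extent=extent)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    fig.colorbar(im, ax=ax, label="height (nm)", shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def save_condition_figure(
    summaries: list[ConditionSummary], path: str | Path, dpi: int = 150
) -> None:
    """Bar (mean +/- SEM) and violin-style (KDE) panels of fibril length,
    height and coverage across the condition grid."""
    times = sorted({s.incubation_time for s in summaries})
    concs = sorted({s.dha_concentration for s in summaries})
    fig, axes = plt.subplots(3, 2, figsize=(10, 10))
    quantities = [
        ("length", "mean_length", "sem_length", "fibril length (nm)"),
        ("height", "mean_height", "sem_height", "fibril height (nm)"),
        ("coverage", "mean_coverage", "sem_coverage", "surface coverage (%)"),
    ]
    width = 0.8 / max(len(concs), 1)
    for row, (_, mean_f, sem_f, ylabel) in enumerate(quantities):
        ax = axes[row, 0]
        for ci, conc in enumerate(concs):
            xs, ys, es = [], [], []
            for ti, t in enumerate(times):
                for s in summaries:
                    if s.dha_concentration == conc and s.incubation_time == t:
                        xs.append(ti + (ci - (len(concs) - 1) / 2) * width)
                        ys.append(getattr(s, mean_f))
                        es.append(getattr(s, sem_f))
            ax.bar(xs, ys, width=width, yerr=es, capsize=2,
                   label=f"{conc:g} μM DHA")
        ax.set_xticks(range(len(times)))
        ax.set_xticklabels([f"{t:g} h" for t in times])
        ax.set_ylabel(ylabel)
        if row == 0:
            ax.legend(fontsize=8)
    # violin-style length distributions from the stored KDEs
    ax = axes[0, 1]
    pos = 0
    labels = []
    for t in times:
        for conc in concs:
            for s in summaries:
                if (
                    s.dha_concentration == conc
                    and s.incubation_time == t
                    and s.length_kde
                ):
                    grid = np.array([p[0] for p in s.length_kde])
                    dens = np.array([p[1] for p in s.length_kde])
                    half = 0.4 * dens / dens.max()
                    ax.fill_betweenx(grid, pos - half, pos + half, alpha=0.6)
                    labels.append(f"{conc:g}μM/{t:g}h")
                    pos += 1
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("fibril length (nm)")
    for ax in (axes[1, 1], axes[2, 1]):
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
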