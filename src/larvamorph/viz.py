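"""Figures: morphospace scatterplots with hull shading, accumulation
curves, and size-scaled morphotype panels.

All functions write a figure file and return its path; they use the Agg
backend so they run headless.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .occupation import AccumulationCurve, GroupOccupation, hull_vertices
from .outlines import OutlineContour

logger = logging.getLogger(__name__)

__all__ = ["plot_morphospace", "plot_accumulation", "plot_size_panels"]

_EPOCH_COLORS = {
    "Cretaceous": "#b2533e",
    "Eocene": "#d9a441",
    "extant": "#3e6fb2",
}


def _color(group: str, idx: int) -> str:
    return _EPOCH_COLORS.get(group, f"C{idx}")


def plot_morphospace(
    scores: np.ndarray,
    labels: list[str],
    occupations: list[GroupOccupation],
    *,
    variance_explained: np.ndarray | None = None,
    pcs: tuple[int, int] = (1, 2),
    path: str | Path = "morphospace.png",
    subset_ids: set[str] | None = None,
    ids: list[str] | None = None,
) -> Path:
    """PC scatterplot with per-group convex hulls shaded.

    With ``subset_ids`` (and matching ``ids``) an "old vs expanded"
    overlay is drawn instead: the subset hull nested inside the full
    hull.  Groups with fewer than 3 specimens are drawn as points only.
    """
    scores = np.asarray(scores)
    i, j = pcs[0] - 1, pcs[1] - 1
    fig, ax = plt.subplots(figsize=(6, 5))
    for idx, occ in enumerate(occupations):
        mask = np.array([lab == occ.group for lab in labels])
        col = _color(occ.group, idx)
        ax.scatter(
            scores[mask, i], scores[mask, j], s=18, color=col,
            label=f"{occ.group} (n={occ.n})", zorder=3,
        )
        if occ.degenerate:
            logger.warning("group %s: fewer than 3 points, hull omitted", occ.group)
            continue
        poly = plt.Polygon(
            occ.hull_vertices, closed=True, facecolor=col, alpha=0.2,
            edgecolor=col, zorder=2,
        )
        ax.add_patch(poly)
    if subset_ids is not None:
        if ids is None:
            raise ValueError("subset overlay needs ids aligned with scores")
        mask = np.array([sid in subset_ids for sid in ids])
        verts = hull_vertices(scores[mask][:, [i, j]])
        if len(verts) >= 3:
            ax.add_patch(
                plt.Polygon(
                    verts, closed=True, fill=False, edgecolor="k",
                    linestyle="--", zorder=4, label="prior subset",
                )
            )
    xlab, ylab = f"PC{pcs[0]}", f"PC{pcs[1]}"
    if variance_explained is not None:
        xlab += f" ({100 * variance_explained[i]:.1f}%)"
        ylab += f" ({100 * variance_explained[j]:.1f}%)"
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_accumulation(
    curves: dict[str, AccumulationCurve], path: str | Path = "accumulation.png"
) -> Path:
    """Mean hull area vs specimens drawn, with percentile CI bands."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for idx, (group, c) in enumerate(curves.items()):
        col = _color(group, idx)
        ax.plot(c.k, c.mean_area, color=col, label=group)
        ax.fill_between(c.k, c.ci_low, c.ci_high, color=col, alpha=0.2)
    ax.set_xlabel("specimens drawn (k)")
    ax.set_ylabel("mean convex-hull area")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_size_panels(
    records: list[dict],
    contours: list[OutlineContour],
    *,
    group_by: str = "morphotype",
    path: str | Path = "size_panels.png",
) -> Path:
    """Outlines grouped by morphotype, drawn at one common physical scale.

    Each record dict needs ``body_length_mm`` (or ``length_mm``); its
    contour is scaled so rendered extents are proportional to real size.
    Specimens without a usable length are omitted with a log warning.
    """
    usable: dict[str, list[tuple[float, OutlineContour]]] = {}
    for rec, c in zip(records, contours):
        length = rec.get("body_length_mm") or rec.get("length_mm")
        if not length or length <= 0:
            logger.warning(
                "specimen %s: no length, omitted from size panels",
                rec.get("specimen_id", "?"),
            )
            continue
        usable.setdefault(str(rec.get(group_by, "unknown")), []).append(
            (float(length), c)
        )
    if not usable:
        raise ValueError("no specimen with a usable length to scale")
    groups = sorted(usable)
    fig, axes = plt.subplots(
        1, len(groups), figsize=(3 * len(groups), 3.2), squeeze=False
    )
    for ax, g in zip(axes[0], groups):
        x_off = 0.0
        for length, c in usable[g]:
            pts = c.points - c.points.mean(axis=0)
            span = pts[:, 0].max() - pts[:, 0].min()
            scale = length / max(pts[:, 1].max() - pts[:, 1].min(), 1e-12)
            pts = pts * scale
            pts[:, 0] += x_off + span * scale / 2
            ax.fill(pts[:, 0], pts[:, 1], alpha=0.6, lw=0.5, ec="k")
            x_off += span * scale * 1.2
        ax.set_title(g, fontsize=9)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
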