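"""Morphospace-occupation statistics in the PC1 x PC2 plane.

"Occupation" is the convex-hull area covered by a group's specimens in
the plane of the first two principal components — the standard disparity
proxy behind shaded-region morphospace scatterplots.  This module also
quantifies how occupied areas relate between groups (convex-polygon
overlap), how much of the present-day occupied area an earlier subset of
specimens already covered, and how occupation accumulates as specimens
are added (rarefaction-style resampling with percentile confidence
bands), whose flattening — or lack of it — is the saturation signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

__all__ = [
    "GroupOccupation",
    "AccumulationCurve",
    "hull_area",
    "hull_vertices",
    "group_occupation",
    "hull_overlap",
    "subset_comparison",
    "accumulation_curve",
    "saturation_slope",
    "SATURATION_SLOPE_THRESHOLD",
]

#: reporting label threshold: a normalized tail slope below this is
#: reported as "saturated" (configurable at call sites; pure labelling).
SATURATION_SLOPE_THRESHOLD = 0.005


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinate")
    return pts


def hull_vertices(points: np.ndarray) -> np.ndarray:
    """CCW-ordered convex-hull vertices; empty array if degenerate."""
    pts = _as_points(points)
    if len(pts) < 3:
        return np.empty((0, 2))
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear or duplicate-degenerate input
        return np.empty((0, 2))
    return pts[hull.vertices]  # scipy orders 2-D hull vertices CCW


def hull_area(points: np.ndarray) -> float:
    """Convex-hull area (shoelace over hull vertices); 0 if degenerate."""
    verts = hull_vertices(points)
    if len(verts) < 3:
        return 0.0
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


@dataclass(frozen=True)
class GroupOccupation:
    """Convex-hull occupation of one group in a PC plane."""

    group: str
    hull_vertices: np.ndarray
    area: float
    n: int
    degenerate: bool = False

    def contains(self, points: np.ndarray, *, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which points lie inside or on the hull."""
        pts = _as_points(points)
        if len(self.hull_vertices) < 3:
            return np.zeros(len(pts), dtype=bool)
        poly = Polygon(self.hull_vertices).buffer(tol)
        from shapely.geometry import Point

        return np.array([poly.covers(Point(p)) for p in pts])


def group_occupation(
    scores: np.ndarray,
    labels: list[str] | np.ndarray,
    pcs: tuple[int, int] = (1, 2),
) -> list[GroupOccupation]:
    """Per-group hulls in the selected PC plane (1-based PC indices).

    Groups with fewer than 3 specimens (or collinear scores) get area 0
    and are flagged ``degenerate``.  Group order follows first appearance
    in ``labels``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if len(labels) != len(scores):
        raise ValueError(
            f"labels ({len(labels)}) and scores ({len(scores)}) length mismatch"
        )
    i, j = pcs[0] - 1, pcs[1] - 1
    plane = scores[:, [i, j]]
    out = []
    for g in dict.fromkeys(labels):
        pts = plane[np.array([lab == g for lab in labels])]
        verts = hull_vertices(pts)
        area = hull_area(pts)
        out.append(
            GroupOccupation(
                group=str(g),
                hull_vertices=verts,
                area=area,
                n=len(pts),
                degenerate=len(verts) < 3,
            )
        )
    return out


def hull_overlap(a: GroupOccupation, b: GroupOccupation) -> float:
    """Area of the convex-polygon intersection of two hulls (0 if disjoint)."""
    if len(a.hull_vertices) < 3 or len(b.hull_vertices) < 3:
        return 0.0
    inter = Polygon(a.hull_vertices).intersection(Polygon(b.hull_vertices))
    return float(inter.area)


def subset_comparison(
    scores: np.ndarray,
    subset_ids: list[str] | set[str],
    all_ids: list[str],
    pcs: tuple[int, int] = (1, 2),
) -> tuple[float, float, float]:
    """Hull area of a specimen subset vs the full set in a PC plane.

    Returns ``(area_subset, area_full, ratio)`` with
    ``ratio = area_subset / area_full`` in [0, 1] (the subset hull is
    contained in the full hull).  Used to measure how much newly added
    specimens expand the previously occupied area.
    """
    scores = np.asarray(scores, dtype=float)
    if len(all_ids) != len(scores):
        raise ValueError("all_ids and scores length mismatch")
    subset = set(subset_ids)
    unknown = subset - set(all_ids)
    if unknown:
        raise KeyError(f"unknown specimen id(s): {sorted(unknown)}")
    i, j = pcs[0] - 1, pcs[1] - 1
    plane = scores[:, [i, j]]
    mask = np.array([sid in subset for sid in all_ids])
    area_subset = hull_area(plane[mask]) if mask.any() else 0.0
    area_full = hull_area(plane)
    ratio = area_subset / area_full if area_full > 0 else 0.0
    return area_subset, area_full, ratio


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean hull area (with percentile CI) vs number of specimens drawn."""

    k: np.ndarray
    mean_area: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_resamples: int
    seed: int
    full_area: float = field(default=float("nan"))


def accumulation_curve(
    points: np.ndarray,
    n_resamples: int = 100,
    seed: int = 0,
    *,
    k_values: np.ndarray | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> AccumulationCurve:
    """Specimen-accumulation curve of hull area for one group.

    For each subset size ``k`` the hull area of ``n_resamples`` uniform
    without-replacement subsets is averaged; at ``k = n`` every resample
    is the full set, so the mean equals the full hull area exactly and
    the CI has zero width.  Reproducible for a fixed ``seed``.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    ks = np.arange(1, n + 1) if k_values is None else np.asarray(k_values, int)
    if np.any(ks < 1) or np.any(ks > n):
        raise ValueError("k values must lie in 1..n")
    rng = np.random.default_rng(seed)
    mean = np.empty(len(ks))
    lo = np.empty(len(ks))
    hi = np.empty(len(ks))
    full = hull_area(pts)
    for idx, k in enumerate(ks):
        if k == n:
            # every size-n subset is the full set: exact, zero-width CI
            mean[idx] = lo[idx] = hi[idx] = full
            continue
        areas = np.array(
            [
                hull_area(pts[rng.choice(n, size=k, replace=False)])
                for _ in range(n_resamples)
            ]
        )
        mean[idx] = areas.mean()
        lo[idx], hi[idx] = np.percentile(areas, ci)
    return AccumulationCurve(
        k=ks,
        mean_area=mean,
        ci_low=lo,
        ci_high=hi,
        n_resamples=n_resamples,
        seed=seed,
        full_area=full,
    )


def saturation_slope(curve: AccumulationCurve, tail_fraction: float = 0.2) -> float:
    """Normalized tail slope of an accumulation curve.

    Least-squares slope of ``mean_area`` over the last ``tail_fraction``
    of k values, divided by the full-sample area — relative area gained
    per additional specimen.  Values near zero mean the curve has
    flattened (sampled diversity approaches the true diversity); clearly
    positive values mean new specimens still expand the occupied area.
    """
    if len(curve.k) < 5:
        raise ValueError("curve needs >= 5 k-values")
    m = max(int(np.ceil(tail_fraction * len(curve.k))), 0)
    if m < 2:
        raise ValueError("tail shorter than 2 points; increase tail_fraction")
    k_tail = curve.k[-m:].astype(float)
    a_tail = curve.mean_area[-m:]
    slope = np.polyfit(k_tail, a_tail, 1)[0]
    ref = curve.mean_area[-1]
    if ref <= 0:
        raise ValueError("degenerate curve: final mean area is zero")
    return float(slope / ref)
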