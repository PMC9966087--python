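"""Closed-outline ingestion, validation, and arc-length resampling.

Outlines are the raw material of the whole pipeline: each specimen view
(head capsule with stylets, head capsule alone, a single stylet, whole body
with or without stylets) is digitised as one closed 2-D polyline.  Three
on-disk dialects are supported:

* CSV — one ``x,y`` pair per line, ``#`` comments, closure implicit;
* SVG — standard SVG 1.1 path data (``M/L/H/V/C/Q/Z``), curves flattened
  to polylines at a configurable chordal tolerance;
* Freeman chain code — line 1 the integer start ``x y``, remaining lines
  whitespace-separated 8-direction codes (the native input of classic
  outline-analysis software).

All ingested contours are validated (>= 3 distinct vertices, positive
perimeter), duplicate consecutive vertices are merged with a warning, and
orientation is normalised to counter-clockwise (positive shoelace area).
SVG's downward y-axis is flipped on ingestion so internal geometry is
right-handed everywhere.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StructureClass",
    "OutlineContour",
    "ChainCode",
    "OutlineError",
    "ClosureError",
    "DegenerateContourError",
    "AmbiguousPathError",
    "read_outline",
    "read_csv_outline",
    "read_svg_outline",
    "read_chain_outline",
    "write_csv_outline",
    "resample_contour",
    "signed_area",
    "perimeter",
]


class StructureClass(str, enum.Enum):
    """The five anatomical outline classes analysed independently."""

    head_with_stylets = "head_with_stylets"
    head_capsule = "head_capsule"
    stylet = "stylet"
    body_with_stylets = "body_with_stylets"
    body_without_stylets = "body_without_stylets"


class OutlineError(ValueError):
    """Base class for outline ingestion/validation failures."""


class ClosureError(OutlineError):
    """Raised when a path or chain code does not close on itself."""


class DegenerateContourError(OutlineError):
    """Raised for contours with < 3 distinct points or zero perimeter."""


class AmbiguousPathError(OutlineError):
    """Raised when an SVG contains several closed subpaths and no selector."""


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (last edge implicit)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(points: np.ndarray) -> float:
    """Total closed-polygon perimeter (last edge implicit)."""
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class OutlineContour:
    """An ordered, closed, counter-clockwise 2-D outline of one structure.

    Parameters
    ----------
    points
        ``(n, 2)`` float array of vertices; the closing edge from the last
        vertex back to the first is implicit.
    closed
        Always ``True`` after ingestion; kept explicit for clarity.
    structure_class
        Which of the five anatomical analyses this outline belongs to.
    specimen_id
        Free-form identifier (e.g. a PED repository number).
    scale
        Optional physical calibration in units (mm) per coordinate unit.
    """

    points: np.ndarray
    closed: bool = True
    structure_class: StructureClass | None = None
    specimen_id: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise OutlineError(f"points must be (n, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise OutlineError("non-finite coordinate in outline")
        pts = _merge_duplicate_vertices(pts)
        if len(np.unique(pts, axis=0)) < 3:
            raise DegenerateContourError(
                f"contour needs >= 3 distinct points, got {len(pts)}"
            )
        if perimeter(pts) <= 0.0:
            raise DegenerateContourError("contour has zero perimeter")
        if signed_area(pts) < 0.0:
            # normalise to CCW, keeping the same starting vertex
            pts = np.vstack([pts[:1], pts[:0:-1]])
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "closed", True)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        return perimeter(self.points)

    @property
    def area(self) -> float:
        return signed_area(self.points)

    def with_points(self, points: np.ndarray) -> "OutlineContour":
        return replace(self, points=points)


def _merge_duplicate_vertices(pts: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Drop consecutive duplicate vertices (incl. a repeated closing vertex)."""
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1], rtol=0.0, atol=tol):
        pts = pts[:-1]
    keep = np.ones(len(pts), dtype=bool)
    d = np.diff(pts, axis=0)
    dup = np.hypot(d[:, 0], d[:, 1]) <= tol
    keep[1:][dup] = False
    if not keep.all():
        logger.warning("merged %d duplicate consecutive point(s)", (~keep).sum())
    return pts[keep]


@dataclass(frozen=True)
class ChainCode:
    """Freeman 8-direction chain code with integer start coordinate."""

    start: tuple[int, int]
    codes: tuple[int, ...] = field(default_factory=tuple)

    #: unit moves for codes 0..7 (E, NE, N, NW, W, SW, S, SE)
    MOVES = np.array(
        [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
    )

    def __post_init__(self) -> None:
        if len(self.codes) < 3:
            raise DegenerateContourError("chain code needs >= 3 steps")
        if any(c < 0 or c > 7 for c in self.codes):
            raise OutlineError("chain codes must lie in 0..7")

    def to_points(self) -> np.ndarray:
        """Replay the moves; verify closure back to the start."""
        steps = self.MOVES[list(self.codes)]
        pts = np.vstack([[self.start], self.start + np.cumsum(steps, axis=0)])
        if not np.array_equal(pts[-1], pts[0]):
            raise ClosureError(
                f"chain code does not close: ends at {tuple(pts[-1])}, "
                f"started at {self.start}"
            )
        return pts[:-1].astype(float)


# ---------------------------------------------------------------------------
# readers


def read_outline(
    path: str | Path,
    fmt: str | None = None,
    *,
    structure_class: StructureClass | None = None,
    specimen_id: str | None = None,
    subpath: int | None = None,
    flatten_tol: float | None = None,
) -> OutlineContour:
    """Read a closed outline from ``path`` in the given or inferred format.

    ``fmt`` is one of ``"csv"``, ``"svg"``, ``"chain"``; when omitted it is
    inferred from the file suffix (``.svg`` → svg, ``.chain``/``.chn`` →
    chain, anything else → csv).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"svg": "svg", "chain": "chain", "chn": "chain"}.get(
            suffix.lstrip("."), "csv"
        )
    if specimen_id is None:
        specimen_id = path.stem
    if fmt == "csv":
        c = read_csv_outline(path)
    elif fmt == "svg":
        c = read_svg_outline(path, subpath=subpath, flatten_tol=flatten_tol)
    elif fmt == "chain":
        c = read_chain_outline(path)
    else:
        raise ValueError(f"unknown outline format: {fmt!r}")
    return replace(c, structure_class=structure_class, specimen_id=specimen_id)


def read_csv_outline(path: str | Path) -> OutlineContour:
    """One "x,y" pair per line; '#' starts a comment; closure implicit."""
    rows: list[tuple[float, float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) != 2:
            raise OutlineError(f"bad CSV outline line: {raw!r}")
        rows.append((float(parts[0]), float(parts[1])))
    return OutlineContour(points=np.asarray(rows, dtype=float))


def write_csv_outline(contour: OutlineContour, path: str | Path) -> None:
    """Write the CSV dialect back out, round-tripping coordinates exactly."""
    lines = [f"{float(x)!r},{float(y)!r}" for x, y in contour.points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_chain_outline(path: str | Path) -> OutlineContour:
    """Line 1: integer "x y" start; remaining lines: codes 0-7."""
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if len(lines) < 2:
        raise OutlineError("chain file needs a start line and codes")
    sx, sy = (int(v) for v in lines[0].split())
    codes = tuple(int(v) for v in " ".join(lines[1:]).split())
    return OutlineContour(points=ChainCode((sx, sy), codes).to_points())


def read_svg_outline(
    path: str | Path,
    *,
    subpath: int | None = None,
    flatten_tol: float | None = None,
) -> OutlineContour:
    """Read the first (or selected) closed subpath of an SVG file.

    Only ``M/m L/l H/h V/v C/c Q/q Z/z`` path commands are supported;
    Bézier segments are flattened to polylines with a chordal tolerance of
    ``flatten_tol`` (default 0.1 % of the subpath bounding-box diagonal).
    The SVG y-axis (downward) is flipped so the internal contour is
    right-handed.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    ns = {"svg": "http://www.w3.org/2000/svg"}
    paths = root.findall(".//svg:path", ns) + root.findall(".//path")
    if not paths:
        raise OutlineError(f"no <path> element in {path}")
    subpaths: list[np.ndarray] = []
    for el in paths:
        subpaths.extend(_parse_path_data(el.get("d", ""), flatten_tol))
    if not subpaths:
        raise ClosureError(f"no closed subpath in {path}")
    if len(subpaths) > 1 and subpath is None:
        raise AmbiguousPathError(
            f"{path} holds {len(subpaths)} closed subpaths; pass subpath="
        )
    pts = subpaths[subpath or 0]
    pts = pts * np.array([1.0, -1.0])  # flip SVG's downward y-axis
    return OutlineContour(points=pts)


_PATH_TOKEN = re.compile(r"([MmLlHhVvCcQqZz])|(-?\d*\.?\d+(?:[eE][+-]?\d+)?)")


def _parse_path_data(d: str, flatten_tol: float | None) -> list[np.ndarray]:
    """Parse SVG path data into a list of closed subpaths (vertex arrays)."""
    tokens: list[str] = [m.group(0) for m in _PATH_TOKEN.finditer(d)]
    pos = 0

    def numbers(k: int) -> list[float]:
        nonlocal pos
        vals = [float(t) for t in tokens[pos : pos + k]]
        if len(vals) < k:
            raise OutlineError("truncated SVG path data")
        pos += k
        return vals

    subpaths: list[np.ndarray] = []
    current: list[np.ndarray] = []
    start = np.zeros(2)
    cur = np.zeros(2)
    cmd = ""
    closed = False
    while pos < len(tokens):
        tok = tokens[pos]
        if tok.isalpha():
            cmd = tok
            pos += 1
            if cmd in "Zz":
                if current:
                    subpaths.append(_finish_subpath(current, flatten_tol))
                    closed = True
                current = []
                cur = start.copy()
                continue
        elif not cmd:
            raise OutlineError("SVG path data must start with a command")
        rel = cmd.islower()
        op = cmd.upper()
        if op == "M":
            (x, y) = numbers(2)
            cur = cur + [x, y] if rel else np.array([x, y])
            if current:  # implicit open subpath: not closed, ignore
                current = []
            start = cur.copy()
            current = [("L", cur.copy())]
            cmd = "l" if rel else "L"  # subsequent pairs are lineto
        elif op == "L":
            (x, y) = numbers(2)
            cur = cur + [x, y] if rel else np.array([x, y])
            current.append(("L", cur.copy()))
        elif op == "H":
            (x,) = numbers(1)
            cur = np.array([cur[0] + x if rel else x, cur[1]])
            current.append(("L", cur.copy()))
        elif op == "V":
            (y,) = numbers(1)
            cur = np.array([cur[0], cur[1] + y if rel else y])
            current.append(("L", cur.copy()))
        elif op == "C":
            vals = np.array(numbers(6)).reshape(3, 2)
            pts = cur + vals if rel else vals
            current.append(("C", np.vstack([cur, pts])))
            cur = pts[-1].copy()
        elif op == "Q":
            vals = np.array(numbers(4)).reshape(2, 2)
            pts = cur + vals if rel else vals
            current.append(("Q", np.vstack([cur, pts])))
            cur = pts[-1].copy()
        else:
            raise OutlineError(f"unsupported SVG path command: {cmd!r}")
    if current and not closed:
        raise ClosureError("SVG subpath not closed (missing Z)")
    return subpaths


def _finish_subpath(
    segments: list, flatten_tol: float | None
) -> np.ndarray:
    """Flatten a parsed subpath's Bézier segments into a vertex array."""
    # first pass: control-point bounding box sets the default tolerance
    all_pts = np.vstack([np.atleast_2d(p) for _, p in segments])
    diag = float(np.hypot(*(all_pts.max(0) - all_pts.min(0))))
    tol = flatten_tol if flatten_tol is not None else 1e-3 * max(diag, 1e-12)
    verts: list[np.ndarray] = []
    for kind, p in segments:
        if kind == "L":
            verts.append(np.atleast_2d(p))
        else:
            verts.append(_flatten_bezier(np.asarray(p), tol)[1:])
    return np.vstack(verts)


def _flatten_bezier(ctrl: np.ndarray, tol: float) -> np.ndarray:
    """Adaptively flatten a quadratic/cubic Bézier to within chordal tol."""
    n = 8
    while n < 4096:
        t = np.linspace(0.0, 1.0, n + 1)
        pts = _bezier_eval(ctrl, t)
        mid = _bezier_eval(ctrl, (t[:-1] + t[1:]) / 2.0)
        chord_mid = (pts[:-1] + pts[1:]) / 2.0
        if np.hypot(*(mid - chord_mid).T).max() <= tol:
            return pts
        n *= 2
    return pts


def _bezier_eval(ctrl: np.ndarray, t: np.ndarray) -> np.ndarray:
    """De Casteljau evaluation for arbitrary-degree Bézier control polygons."""
    pts = np.repeat(ctrl[None, :, :], len(t), axis=0)
    tt = t[:, None, None]
    while pts.shape[1] > 1:
        pts = (1.0 - tt) * pts[:, :-1, :] + tt * pts[:, 1:, :]
    return pts[:, 0, :]


# ---------------------------------------------------------------------------
# resampling


def resample_contour(contour: OutlineContour, n_points: int) -> OutlineContour:
    """Resample to ``n_points`` vertices equally spaced by arc length.

    The first resampled vertex coincides with the contour's first vertex;
    the perimeter is preserved to ~1e-9 relative (vertices of the original
    polygon are interpolated exactly because spacing lands on straight
    edges).
    """
    if n_points < 8:
        raise ValueError(f"n_points must be >= 8, got {n_points}")
    pts = np.vstack([contour.points, contour.points[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    s = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(s, t, pts[:, 0])
    y = np.interp(s, t, pts[:, 1])
    return contour.with_points(np.column_stack([x, y]))
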