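"""Midline extraction: blob silhouette -> ordered head-to-tail dorsal path
-> four equidistributed body points A, B, C, D.

The silhouette is thinned to a 1-px skeleton with the Zhang-Suen parallel
thinning algorithm, reduced to its longest endpoint-to-endpoint geodesic
(which prunes fin spurs), oriented head-first (fish heads are thicker than
caudal peduncles), and resampled at arc-length fractions 0, 1/3, 2/3, 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage

from .segmentation import Blob


class CyclicSkeletonError(ValueError):
    """Skeleton has no degree-1 endpoint (a closed loop): frame invalid."""


@dataclass
class SkeletonPath:
    """Ordered 8-connected pixel path with its arc length.

    ``points`` is an (n, 2) float array of (x, y) pixel coordinates;
    consecutive points are 8-adjacent, so each step contributes 1 (axial) or
    sqrt(2) (diagonal) to ``arc_length_px``.
    """

    points: np.ndarray
    arc_length_px: float

    @staticmethod
    def from_points(points: np.ndarray) -> "SkeletonPath":
        pts = np.asarray(points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("path needs >= 2 (x, y) points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return SkeletonPath(points=pts, arc_length_px=float(steps.sum()))

    def reversed(self) -> "SkeletonPath":
        return SkeletonPath(self.points[::-1].copy(), self.arc_length_px)


@dataclass(frozen=True)
class MidlinePoints:
    """The four points dividing the dorsal path into three equal-arc segments.

    A is the head end, D the end of the caudal peduncle; B and C sit at arc
    fractions 1/3 and 2/3.  Coordinates are subpixel (linear interpolation
    along the path polyline).
    """

    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]
    D: tuple[float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D], dtype=np.float64)


# ---------------------------------------------------------------------------
# Zhang-Suen thinning
# ---------------------------------------------------------------------------

def _zhang_suen_pass(img: np.ndarray, first_subiteration: bool) -> np.ndarray:
    """One parallel deletion sub-iteration; returns the boolean delete mask.

    Neighbours are labelled P2..P9 clockwise from north.  A pixel is deleted
    when (a) its neighbour count B is in [2, 6], (b) the number A of 0->1
    transitions around it is exactly 1, and (c, d) the sub-iteration's two
    products of three neighbours are zero (P2*P4*P6 = P4*P6*P8 = 0 in the
    first sub-iteration, P2*P4*P8 = P2*P6*P8 = 0 in the second).
    """
    p = np.pad(img, 1, mode="constant").astype(np.uint8)
    c = p[1:-1, 1:-1]
    P2 = p[:-2, 1:-1]
    P3 = p[:-2, 2:]
    P4 = p[1:-1, 2:]
    P5 = p[2:, 2:]
    P6 = p[2:, 1:-1]
    P7 = p[2:, :-2]
    P8 = p[1:-1, :-2]
    P9 = p[:-2, :-2]
    ring = [P2, P3, P4, P5, P6, P7, P8, P9, P2]
    B = P2 + P3 + P4 + P5 + P6 + P7 + P8 + P9
    A = np.zeros_like(B)
    for a, b in zip(ring[:-1], ring[1:]):
        A += (a == 0) & (b == 1)
    if first_subiteration:
        cond_c = P2 * P4 * P6 == 0
        cond_d = P4 * P6 * P8 == 0
    else:
        cond_c = P2 * P4 * P8 == 0
        cond_d = P2 * P6 * P8 == 0
    return (c == 1) & (B >= 2) & (B <= 6) & (A == 1) & cond_c & cond_d


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Zhang-Suen thinning of a boolean mask to a 1-px-wide skeleton.

    The two sub-iterations are applied alternately until neither deletes a
    pixel.  The output is a subset of the input foreground (a property the
    pipeline also uses as a per-frame validity check).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("empty mask")
    img = mask.astype(np.uint8)
    while True:
        d1 = _zhang_suen_pass(img, first_subiteration=True)
        img[d1] = 0
        d2 = _zhang_suen_pass(img, first_subiteration=False)
        img[d2] = 0
        if not d1.any() and not d2.any():
            break
    return img.astype(bool)


# ---------------------------------------------------------------------------
# Skeleton -> ordered path
# ---------------------------------------------------------------------------

def _skeleton_graph(skeleton: np.ndarray) -> nx.Graph:
    rows, cols = np.nonzero(skeleton)
    g = nx.Graph()
    pixels = set(zip(cols.tolist(), rows.tolist()))  # (x, y)
    g.add_nodes_from(pixels)
    for (x, y) in pixels:
        for dx, dy in ((1, 0), (0, 1), (1, 1), (1, -1)):
            nb = (x + dx, y + dy)
            if nb in pixels:
                g.add_edge((x, y), nb, weight=float(np.hypot(dx, dy)))
    return g


def longest_path(skeleton: np.ndarray) -> SkeletonPath:
    """Longest endpoint-to-endpoint geodesic through the skeleton.

    The skeleton pixels form an 8-adjacency graph with step weights 1 and
    sqrt(2).  Fish skeletons are trees (a spine with short fin spurs); the
    pair of degree-1 endpoints whose geodesic is longest spans the dorsal
    line, and spurs are pruned implicitly.  A disconnected skeleton falls
    back to its largest component with a warning; a skeleton with no
    endpoint at all (a closed cycle) is unusable.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        raise ValueError("empty skeleton")
    g = _skeleton_graph(skeleton)
    components = list(nx.connected_components(g))
    if len(components) > 1:
        warnings.warn(f"skeleton has {len(components)} components; "
                      "using the largest")
        g = g.subgraph(max(components, key=len)).copy()
    endpoints = [n for n, d in g.degree() if d == 1]
    if not endpoints:
        raise CyclicSkeletonError("skeleton is a closed cycle")
    best: tuple[float, list] = (-1.0, [])
    for src in endpoints:
        dist, paths = nx.single_source_dijkstra(g, src, weight="weight")
        for dst in endpoints:
            if dst in dist and dist[dst] > best[0]:
                best = (dist[dst], paths[dst])
    if len(best[1]) < 2:
        raise ValueError("skeleton path degenerate (single pixel)")
    return SkeletonPath.from_points(np.array(best[1], dtype=np.float64))


def orient_path(path: SkeletonPath, blob: Blob, policy: str = "thickness",
                x_sign: int = -1) -> SkeletonPath:
    """Return the path head-first.

    ``thickness`` policy: the endpoint whose first 10% of arc length sits on
    thicker body (larger mean distance-transform value inside the blob) is
    the head; exact ties fall back to ``fixed_direction``.  ``fixed_direction``
    uses the tunnel geometry: with ``x_sign = -1`` the head is the endpoint
    with the smaller x (fish face upstream), with ``+1`` the larger x.
    """
    if policy not in ("thickness", "fixed_direction"):
        raise ValueError(f"unknown orientation policy {policy!r}")
    pts = path.points
    if policy == "thickness":
        dt = ndimage.distance_transform_edt(blob.mask)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        frac = cum / cum[-1]
        h, w = blob.mask.shape
        cols = np.clip(np.rint(pts[:, 0]).astype(int), 0, w - 1)
        rows = np.clip(np.rint(pts[:, 1]).astype(int), 0, h - 1)
        vals = dt[rows, cols]
        head_score = vals[frac <= 0.10].mean()
        tail_score = vals[frac >= 0.90].mean()
        if head_score > tail_score:
            return path
        if tail_score > head_score:
            return path.reversed()
        warnings.warn("thickness tie at both ends; falling back to "
                      "fixed_direction")
    # fixed_direction
    first_x, last_x = pts[0, 0], pts[-1, 0]
    if x_sign < 0:
        return path if first_x <= last_x else path.reversed()
    return path if first_x >= last_x else path.reversed()


def refine_path(path: SkeletonPath, blob: Blob,
                smooth_window: int = 9, tangent_samples: int = 6
                ) -> SkeletonPath:
    """Subpixel refinement of a raw pixel path for body measurements.

    Two corrections, both in the blob's local coordinate frame:

    * the staircase pixel path is smoothed with a moving average of
      ``smooth_window`` points (reflected at the ends), removing the
      digital-line arc-length inflation that would shift the equidistant
      body points;
    * thinning stops roughly one local half-width short of the true body
      ends, so each end is extended along its local tangent (estimated over
      ``tangent_samples`` steps) by the blob's distance-transform value at
      that endpoint, recovering the head tip and caudal-peduncle end.

    Orientation is preserved (head stays first).
    """
    pts = path.points
    n = len(pts)
    if n >= smooth_window + 2:
        pad = smooth_window // 2
        ext = np.vstack([2 * pts[0] - pts[pad:0:-1], pts,
                         2 * pts[-1] - pts[-2:-2 - pad:-1]])
        ker = np.full(smooth_window, 1.0 / smooth_window)
        pts = np.column_stack([np.convolve(ext[:, 0], ker, mode="valid"),
                               np.convolve(ext[:, 1], ker, mode="valid")])
    dt = ndimage.distance_transform_edt(blob.mask)
    h, w = blob.mask.shape
    m = min(tangent_samples, len(pts) - 1)
    for end in (0, -1):
        p = pts[0] if end == 0 else pts[-1]
        nbr = pts[m] if end == 0 else pts[-1 - m]
        tang = p - nbr
        norm = np.linalg.norm(tang)
        if norm == 0:
            continue
        iy = int(np.clip(round(p[1]), 0, h - 1))
        ix = int(np.clip(round(p[0]), 0, w - 1))
        newp = p + tang / norm * dt[iy, ix]
        pts = np.vstack([newp, pts]) if end == 0 else np.vstack([pts, newp])
    return SkeletonPath.from_points(pts)


def resample_polyline(points: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Points at given arc-length fractions of a polyline, interpolated."""
    pts = np.asarray(points, dtype=np.float64)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    if cum[-1] <= 0:
        raise ValueError("polyline has zero arc length")
    targets = np.asarray(fractions, dtype=np.float64) * cum[-1]
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    return np.column_stack([x, y])


def equidistant_points(path: SkeletonPath | np.ndarray,
                       k: int = 4) -> np.ndarray:
    """k points at arc-length fractions i/(k-1) along the path (subpixel)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    pts = path.points if isinstance(path, SkeletonPath) else np.asarray(path)
    return resample_polyline(pts, np.arange(k) / (k - 1))


def midline_points(path: SkeletonPath | np.ndarray) -> MidlinePoints:
    """The A, B, C, D body points of an oriented head-first path."""
    a, b, c, d = equidistant_points(path, 4)
    return MidlinePoints(A=tuple(a), B=tuple(b), C=tuple(c), D=tuple(d))
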