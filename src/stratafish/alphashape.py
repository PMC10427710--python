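"""Alpha-shape construction from cell centroids.

A point ``p`` of a planar point set is *alpha-extreme* when an open ball of
radius ``alpha`` exists with ``p`` on its boundary that covers no other point
of the set.  The alpha-shape is the set of segments joining neighboring
alpha-extreme points; a pair ``(p, q)`` forms an edge exactly when some open
ball of radius ``alpha`` has both points on its boundary and covers no other
point (the *witness* ball).  As ``alpha`` grows the construction converges to
the convex hull; as it shrinks below half the minimum point spacing every
point becomes extreme and no edges remain.

The extreme-point test used here is exact: the locus of candidate ball
centers for ``p`` is the circle of radius ``alpha`` around ``p``, and a second
point ``q`` at distance ``d < 2*alpha`` excludes the open arc of centers
within angular half-width ``arccos(d / (2*alpha))`` of the direction of
``q``.  ``p`` is extreme iff the union of the excluded arcs does not cover
the full candidate circle.  A k-d tree restricts the arc union to points
within ``2*alpha``; the result is identical to the all-pairs computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AlphaShape",
    "AlphaShapeError",
    "alpha_extreme_points",
    "build_alpha_shape",
]

# Relative slack applied to open-ball strict inequalities so that points lying
# exactly on a witness-ball boundary (the defining points, and exact-tie
# constructions such as co-circular inputs) are never counted as covered.
_REL_TOL = 1e-9


class AlphaShapeError(ValueError):
    """Raised when no closed alpha-shape boundary exists for the given alpha."""


def _validate_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    if len(pts) < 3:
        raise ValueError("at least 3 points are required")
    # collinearity check via the rank of the centered coordinates
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise ValueError("points are collinear")
    return pts


def _arcs_cover_circle(phi: np.ndarray, width: np.ndarray) -> bool:
    """True when the union of open arcs (phi - width, phi + width) covers the circle.

    Arcs wrapping the 0/2*pi seam are split into two plain intervals; the
    circle is covered iff the merged intervals cover [0, 2*pi] without a gap.
    """
    if len(phi) == 0:
        return False
    two_pi = 2.0 * np.pi
    start = np.mod(phi - width, two_pi)
    end = start + 2.0 * width
    wraps = end > two_pi
    starts = np.concatenate([start, np.zeros(wraps.sum())])
    ends = np.concatenate([np.minimum(end, two_pi), end[wraps] - two_pi])
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    if starts[0] > 1e-12:
        return False
    reach = 0.0
    for s, e in zip(starts, ends):
        if s > reach + 1e-12:
            return False
        reach = max(reach, e)
        if reach >= two_pi - 1e-12:
            return True
    return False


def alpha_extreme_points(points: np.ndarray, alpha: float) -> np.ndarray:
    """Indices of the alpha-extreme points of a planar point set.

    Parameters
    ----------
    points : (n, 2) array of centroid coordinates in µm.
    alpha : ball radius in µm; must be positive.

    Returns
    -------
    ndarray of int
        Sorted indices of points admitting an empty open ball of radius
        ``alpha`` with the point on its boundary.
    """
    pts = _validate_points(points)
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    tree = cKDTree(pts)
    cutoff = 2.0 * alpha * (1.0 - _REL_TOL)
    extreme = []
    for i, p in enumerate(pts):
        idx = tree.query_ball_point(p, 2.0 * alpha)
        idx = [j for j in idx if j != i]
        if not idx:
            extreme.append(i)
            continue
        vec = pts[idx] - p
        dist = np.hypot(vec[:, 0], vec[:, 1])
        near = dist < cutoff
        if not near.any():
            extreme.append(i)
            continue
        phi = np.arctan2(vec[near, 1], vec[near, 0])
        width = np.arccos(np.clip(dist[near] / (2.0 * alpha), -1.0, 1.0))
        if not _arcs_cover_circle(phi, width):
            extreme.append(i)
    return np.asarray(extreme, dtype=int)


def _witness_centers(p: np.ndarray, q: np.ndarray, alpha: float) -> np.ndarray:
    """The two centers of balls of radius alpha through both p and q."""
    mid = 0.5 * (p + q)
    d = np.linalg.norm(q - p)
    h = np.sqrt(max(alpha * alpha - 0.25 * d * d, 0.0))
    n = np.array([-(q - p)[1], (q - p)[0]]) / d
    return np.stack([mid + h * n, mid - h * n])


@dataclass
class AlphaShape:
    """Largest closed boundary component of the alpha-shape of a point set.

    Attributes
    ----------
    alpha : ball radius (µm).
    points : the full input point set.
    extreme_idx : indices of all alpha-extreme points of the input.
    edges : (m, 2) int array of point indices; each row is one boundary
        segment of the retained component.
    witnesses : (m, 2) float array; per edge, the center of an empty witness
        ball of radius ``alpha`` through both endpoints.
    witness_both_empty : (m,) bool; True when both candidate balls of the
        edge were empty (thin or lateral regions).
    """

    alpha: float
    points: np.ndarray
    extreme_idx: np.ndarray
    edges: np.ndarray
    witnesses: np.ndarray
    witness_both_empty: np.ndarray = field(repr=False)

    def ordered_edges(self) -> np.ndarray:
        """Edge indices (rows of ``edges``) ordered along the boundary chain.

        For the common degree-2 cycle the edges are returned in walking
        order; otherwise edges are ordered by the angle of their midpoints
        around the centroid of the extreme points.
        """
        g = nx.MultiGraph()
        for k, (a, b) in enumerate(self.edges):
            g.add_edge(int(a), int(b), key=k)
        degrees = dict(g.degree())
        if degrees and all(d == 2 for d in degrees.values()):
            start = min(degrees)
            order: list[int] = []
            prev_key = None
            node = start
            for _ in range(len(self.edges)):
                nbrs = [
                    (v, k)
                    for _, v, k in g.edges(node, keys=True)
                    if k != prev_key
                ]
                if not nbrs:
                    break
                nxt, key = nbrs[0]
                order.append(key)
                prev_key = key
                node = nxt
            if len(order) == len(self.edges):
                return np.asarray(order, dtype=int)
        mids = 0.5 * (self.points[self.edges[:, 0]] + self.points[self.edges[:, 1]])
        center = self.points[self.extreme_idx].mean(axis=0)
        ang = np.arctan2(mids[:, 1] - center[1], mids[:, 0] - center[0])
        return np.argsort(ang, kind="stable")


def build_alpha_shape(points: np.ndarray, alpha: float) -> AlphaShape:
    """Build the alpha-shape boundary of a point set and keep the largest
    closed component.

    Raises
    ------
    AlphaShapeError
        When no connected component of the edge graph contains a cycle
        (the points are too sparse for the given alpha).
    """
    pts = _validate_points(points)
    extreme = alpha_extreme_points(pts, alpha)
    tree = cKDTree(pts)
    ext_pts = pts[extreme]
    ext_tree = cKDTree(ext_pts)
    pairs = ext_tree.query_pairs(2.0 * alpha * (1.0 - _REL_TOL), output_type="ndarray")
    strict = alpha * (1.0 - _REL_TOL)
    edges: list[tuple[int, int]] = []
    witnesses: list[np.ndarray] = []
    both_flags: list[bool] = []
    cloud_center = pts.mean(axis=0)
    for a_loc, b_loc in pairs:
        i, j = int(extreme[a_loc]), int(extreme[b_loc])
        centers = _witness_centers(pts[i], pts[j], alpha)
        empties = []
        for c in centers:
            idx = tree.query_ball_point(c, alpha)
            covered = any(
                k not in (i, j)
                and np.linalg.norm(pts[k] - c) < strict
                for k in idx
            )
            if not covered:
                empties.append(c)
        if not empties:
            continue
        if len(empties) == 2:
            # deterministic pick: the center farther from the cloud centroid,
            # i.e. the outward-facing witness
            d0 = np.linalg.norm(empties[0] - cloud_center)
            d1 = np.linalg.norm(empties[1] - cloud_center)
            chosen = empties[0] if d0 >= d1 else empties[1]
        else:
            chosen = empties[0]
        edges.append((i, j))
        witnesses.append(chosen)
        both_flags.append(len(empties) == 2)

    if not edges:
        raise AlphaShapeError(
            f"no alpha-shape edges at alpha={alpha}; points too sparse"
        )
    edge_arr = np.asarray(edges, dtype=int)
    wit_arr = np.asarray(witnesses, dtype=float)
    both_arr = np.asarray(both_flags, dtype=bool)

    g = nx.Graph()
    g.add_nodes_from(np.unique(edge_arr))
    for k, (a, b) in enumerate(edge_arr):
        g.add_edge(int(a), int(b))
    best_nodes: set[int] | None = None
    best_n_edges = -1
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() < len(comp):
            continue  # a tree: no cycle, not a closed boundary
        if sub.number_of_edges() > best_n_edges:
            best_n_edges = sub.number_of_edges()
            best_nodes = set(comp)
    if best_nodes is None:
        raise AlphaShapeError(
            f"no closed alpha-shape component at alpha={alpha}; "
            "increase alpha or point density"
        )
    keep = np.array(
        [a in best_nodes and b in best_nodes for a, b in edge_arr], dtype=bool
    )
    return AlphaShape(
        alpha=float(alpha),
        points=pts,
        extreme_idx=extreme,
        edges=edge_arr[keep],
        witnesses=wit_arr[keep],
        witness_both_empty=both_arr[keep],
    )
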