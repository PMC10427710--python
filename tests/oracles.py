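"""Independent brute-force oracles used only by the test suite.

These re-derive the same geometric definitions as the package through a
different route (all-pairs scans, explicit interval bookkeeping, O(n^4)
enumeration) so that agreement is a real check, not a tautology.
"""

import numpy as np

TWO_PI = 2.0 * np.pi


def _merge_intervals(intervals):
    """Union length bookkeeping for intervals inside [0, 2*pi]."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return merged


def oracle_extreme_points(points, alpha):
    """All-pairs arc-coverage test for alpha-extreme points.

    For point p, every neighbor q (distance d < 2*alpha) excludes an open
    arc of candidate ball centers; p is extreme iff the union of excluded
    arcs, split at the 0/2*pi seam and merged, does not cover the circle.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    out = []
    for i in range(n):
        intervals = []
        for j in range(n):
            if j == i:
                continue
            d = float(np.linalg.norm(pts[j] - pts[i]))
            if d >= 2.0 * alpha * (1.0 - 1e-9):
                continue
            phi = float(np.arctan2(pts[j, 1] - pts[i, 1], pts[j, 0] - pts[i, 0]))
            w = float(np.arccos(min(max(d / (2.0 * alpha), -1.0), 1.0)))
            a, b = phi - w, phi + w
            a = a % TWO_PI
            b = a + 2.0 * w
            if b <= TWO_PI:
                intervals.append((a, b))
            else:  # split at the seam
                intervals.append((a, TWO_PI))
                intervals.append((0.0, b - TWO_PI))
        merged = _merge_intervals(intervals)
        covered = sum(b - a for a, b in merged)
        if covered < TWO_PI - 1e-9:
            out.append(i)
    return np.asarray(out, dtype=int)


def oracle_alpha_edges(points, alpha):
    """All-pairs empty-witness-ball test; returns a set of index pairs."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = set()
    strict = alpha * (1.0 - 1e-9)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(pts[j] - pts[i]))
            if d >= 2.0 * alpha * (1.0 - 1e-9) or d == 0.0:
                continue
            mid = 0.5 * (pts[i] + pts[j])
            h = np.sqrt(max(alpha * alpha - 0.25 * d * d, 0.0))
            nvec = np.array([-(pts[j] - pts[i])[1], (pts[j] - pts[i])[0]]) / d
            for c in (mid + h * nvec, mid - h * nvec):
                dists = np.linalg.norm(pts - c, axis=1)
                dists[[i, j]] = np.inf
                if dists.min() >= strict:
                    edges.add((i, j))
                    break
    return edges


def oracle_min_enclosing_circle(points):
    """O(n^4) enumeration: the MEC is determined by two points (diameter) or
    three points (circumcircle); return the smallest enclosing radius."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    best = np.inf
    tol = 1e-9

    def covers(c, r):
        return (np.linalg.norm(pts - c, axis=1) <= r * (1 + tol) + tol).all()

    for i in range(n):
        for j in range(i + 1, n):
            c = 0.5 * (pts[i] + pts[j])
            r = 0.5 * np.linalg.norm(pts[i] - pts[j])
            if r < best and covers(c, r):
                best = r
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                ax, ay = pts[i]
                bx, by = pts[j]
                cx, cy = pts[k]
                dd = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(dd) < 1e-12:
                    continue
                ux = (
                    (ax**2 + ay**2) * (by - cy)
                    + (bx**2 + by**2) * (cy - ay)
                    + (cx**2 + cy**2) * (ay - by)
                ) / dd
                uy = (
                    (ax**2 + ay**2) * (cx - bx)
                    + (bx**2 + by**2) * (ax - cx)
                    + (cx**2 + cy**2) * (bx - ax)
                ) / dd
                c = np.array([ux, uy])
                r = float(np.linalg.norm(pts[i] - c))
                if r < best and covers(c, r):
                    best = r
    return best


def oracle_chain_distance(point, chain, n_samples=200_000):
    """Dense-sampling distance to a polyline (discretized oracle)."""
    chain = np.asarray(chain, dtype=float)
    segs = np.stack([chain[:-1], chain[1:]], axis=1)
    lengths = np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1)
    total = lengths.sum()
    best = np.inf
    for (a, b), ell in zip(segs, lengths):
        k = max(int(np.ceil(n_samples * ell / total)), 2)
        t = np.linspace(0.0, 1.0, k)[:, None]
        samples = a + t * (b - a)
        best = min(best, float(np.linalg.norm(samples - point, axis=1).min()))
    return best
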