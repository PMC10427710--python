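"""Dual-segmentation fusion, transcript assignment, and cell QC.

Two segmenters are run over the same tissue: a primary one that performs
well in the nuclear layers and a rescue one that recovers cells the primary
misses (typically in the ganglion cell layer but over-splits elsewhere).
Rescue polygons are kept only when their overlap with the primary
segmentation is negligible — strictly below 0.1% of the rescue polygon's own
area by default.  Decoded transcript spots are then assigned to cells
(containing polygon first, else nearest polygon boundary via a k-d tree over
polygon centroids with a certified candidate pool), and cells are filtered
on five quality metrics: mean DAPI intensity, minimum-enclosing-circle
radius, polygon area, polygon perimeter, and total assigned transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

__all__ = [
    "SegmentationSet",
    "QCThresholds",
    "QCResult",
    "minimum_enclosing_circle",
    "merge_segmentations",
    "polygon_metrics",
    "compute_metrics",
    "assign_transcripts",
    "qc_filter",
]


def _check_ring(cell_id: str, poly: Polygon) -> None:
    if len(poly.exterior.coords) - 1 < 3:
        raise ValueError(f"polygon {cell_id!r}: fewer than 3 vertices")
    if not poly.is_valid:
        raise ValueError(f"polygon {cell_id!r}: ring is not simple/valid")
    if poly.area <= 0:
        raise ValueError(f"polygon {cell_id!r}: zero area")


@dataclass
class SegmentationSet:
    """A collection of cell polygons from one segmenter (or a merge)."""

    cell_ids: list[str]
    polygons: list[Polygon]
    source: str = "primary"

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.polygons):
            raise ValueError("cell_ids and polygons length mismatch")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        for cid, poly in zip(self.cell_ids, self.polygons):
            _check_ring(cid, poly)

    def __len__(self) -> int:
        return len(self.cell_ids)


def minimum_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact minimum enclosing circle (center, radius) of a planar point set.

    Handles the degenerate one- and two-point cases directly (radius 0 and
    half the separation).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    if len(pts) == 2:
        return 0.5 * (pts[0] + pts[1]), 0.5 * float(np.linalg.norm(pts[1] - pts[0]))
    mp = shapely.multipoints(pts)
    circle = shapely.minimum_bounding_circle(mp)
    radius = float(shapely.minimum_bounding_radius(mp))
    center = np.asarray(circle.centroid.coords[0]) if radius > 0 else pts.mean(axis=0)
    return center, radius


def merge_segmentations(
    primary: SegmentationSet,
    rescue: SegmentationSet,
    overlap_threshold: float = 0.001,
    denominator: str = "rescue",
) -> SegmentationSet:
    """Fuse two segmentations: keep all primary polygons plus the rescue
    polygons whose overlap fraction with the primary set is strictly below
    ``overlap_threshold`` (default 0.1%).

    ``denominator`` selects what normalizes the intersection area:
    ``"rescue"`` (default) divides by the rescue polygon's own area — the
    rule decides that polygon's fate; ``"primary"`` divides by the area of
    the union of intersecting primary polygons instead.
    """
    if not 0.0 <= overlap_threshold <= 1.0:
        raise ValueError(f"overlap_threshold must be in [0, 1], got {overlap_threshold}")
    if denominator not in ("rescue", "primary"):
        raise ValueError("denominator must be 'rescue' or 'primary'")
    dup = set(primary.cell_ids) & set(rescue.cell_ids)
    if dup:
        raise ValueError(f"duplicate cell_ids across sets: {sorted(dup)[:5]}")
    tree = shapely.STRtree(primary.polygons)
    keep_ids: list[str] = []
    keep_polys: list[Polygon] = []
    for cid, poly in zip(rescue.cell_ids, rescue.polygons):
        cand = tree.query(poly, predicate="intersects")
        if len(cand) == 0:
            frac = 0.0
        else:
            overlap_region = shapely.union_all([primary.polygons[i] for i in cand])
            inter = poly.intersection(overlap_region).area
            denom = poly.area if denominator == "rescue" else overlap_region.area
            frac = inter / denom
        if frac < overlap_threshold:
            keep_ids.append(cid)
            keep_polys.append(poly)
    return SegmentationSet(
        cell_ids=list(primary.cell_ids) + keep_ids,
        polygons=list(primary.polygons) + keep_polys,
        source="merged",
    )


def polygon_metrics(
    polygon: Polygon,
    spots: pd.DataFrame | None = None,
    dapi_mean: float = np.nan,
    cell_id: str | None = None,
) -> dict:
    """Per-cell QC metrics: area, perimeter, minimum-enclosing-circle radius,
    mean DAPI intensity (supplied externally), and total assigned transcripts.

    ``spots`` is an assigned transcript table; when given together with
    ``cell_id``, transcripts with that assignment are counted.
    """
    _check_ring(cell_id or "<anonymous>", polygon)
    verts = np.asarray(polygon.exterior.coords)[:-1]
    _, mec_radius = minimum_enclosing_circle(verts)
    total = 0
    if spots is not None and cell_id is not None and "cell_id" in spots.columns:
        total = int((spots["cell_id"] == cell_id).sum())
    return {
        "area": float(polygon.area),
        "perimeter": float(polygon.length),
        "mec_radius": mec_radius,
        "dapi_mean": float(dapi_mean),
        "total_transcripts": total,
    }


def compute_metrics(
    segset: SegmentationSet,
    spots: pd.DataFrame | None = None,
    dapi: dict | pd.Series | None = None,
) -> pd.DataFrame:
    """Vector of :func:`polygon_metrics` over a segmentation set."""
    counts: dict[str, int] = {}
    if spots is not None and "cell_id" in spots.columns:
        counts = spots["cell_id"].value_counts().to_dict()
    rows = []
    for cid, poly in zip(segset.cell_ids, segset.polygons):
        m = polygon_metrics(poly, dapi_mean=np.nan, cell_id=cid)
        m["cell_id"] = cid
        m["total_transcripts"] = int(counts.get(cid, 0))
        if dapi is not None:
            m["dapi_mean"] = float(dapi.get(cid, np.nan))
        rows.append(m)
    cols = ["cell_id", "area", "perimeter", "mec_radius", "dapi_mean", "total_transcripts"]
    return pd.DataFrame(rows)[cols]


def assign_transcripts(
    spots: pd.DataFrame,
    segset: SegmentationSet,
    pool_size: int = 10,
    max_distance: float | None = None,
) -> pd.DataFrame:
    """Assign each transcript spot to exactly one cell.

    A spot inside a polygon belongs to it (ties across overlapping polygons
    broken by smallest ``cell_id``).  Spots outside every polygon are
    assigned to the polygon with minimum boundary distance; candidates come
    from a k-d tree over polygon centroids, and the pool (initially
    ``pool_size``) is doubled until the best candidate distance is certified
    minimal against a bound on all excluded polygons (centroid distance minus
    the maximum centroid-to-vertex radius).  ``max_distance`` optionally
    leaves far spots unassigned (NaN) — off by default.
    """
    if len(segset) == 0:
        raise ValueError("polygon set is empty")
    for col in ("gene", "x", "y"):
        if col not in spots.columns:
            raise ValueError(f"spots table missing column {col!r}")
    out = spots.copy()
    xy = out[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("spot coordinates must be finite")
    pts = shapely.points(xy)
    ids = np.asarray(segset.cell_ids, dtype=object)

    tree = shapely.STRtree(segset.polygons)
    inside_pairs = tree.query(pts, predicate="covers").T  # (n_pairs, 2): spot, poly
    assigned = np.full(len(out), None, dtype=object)
    if len(inside_pairs):
        order = np.lexsort((ids[inside_pairs[:, 1]], inside_pairs[:, 0]))
        sp = inside_pairs[order]
        first = np.unique(sp[:, 0], return_index=True)[1]
        assigned[sp[first, 0]] = ids[sp[first, 1]]

    missing = np.flatnonzero([a is None for a in assigned])
    if len(missing):
        centroids = np.array(
            [np.asarray(p.centroid.coords[0]) for p in segset.polygons]
        )
        radii = np.array(
            [
                np.linalg.norm(
                    np.asarray(p.exterior.coords)[:-1] - np.asarray(p.centroid.coords[0]),
                    axis=1,
                ).max()
                for p in segset.polygons
            ]
        )
        r_max = radii.max()
        ctree = cKDTree(centroids)
        n_poly = len(segset)
        for si in missing:
            k = min(pool_size, n_poly)
            best_id = None
            while True:
                dists, cand = ctree.query(xy[si], k=k)
                dists, cand = np.atleast_1d(dists), np.atleast_1d(cand)
                bdists = shapely.distance(
                    shapely.points(xy[si]),
                    np.array([segset.polygons[c] for c in cand], dtype=object),
                )
                best = np.min(bdists)
                # any polygon outside the pool has boundary distance
                # >= (its centroid distance) - r_max >= dists[-1] - r_max
                certified = k >= n_poly or best <= dists[-1] - r_max
                if certified:
                    tie = np.abs(bdists - best) <= 1e-9
                    best_id = min(ids[cand[tie]])
                    best_d = best
                    break
                k = min(2 * k, n_poly)
            if max_distance is not None and best_d > max_distance:
                continue
            assigned[si] = best_id
    out["cell_id"] = assigned
    return out


@dataclass
class QCThresholds:
    """The five cell-quality filters; bounds are inclusive."""

    dapi_min: float = 80.0
    mec_radius_min: float = 10.0
    mec_radius_max: float = 80.0
    area_min: float = 500.0
    area_max: float = 10_000.0
    perimeter_min: float = 50.0
    perimeter_max: float = 400.0
    transcripts_min: int = 10


@dataclass
class QCResult:
    retained: list[str]
    missing: pd.DataFrame = field(repr=False)


def qc_filter(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> QCResult:
    """Retain cells passing all five inclusive interval tests.

    Cells with any missing (NaN) metric are excluded from ``retained`` but
    reported in ``missing`` rather than silently dropped.
    """
    t = thresholds or QCThresholds()
    required = ["cell_id", "dapi_mean", "mec_radius", "area", "perimeter", "total_transcripts"]
    for col in required:
        if col not in metrics.columns:
            raise ValueError(f"metrics table missing column {col!r}")
    vals = metrics[required[1:]]
    has_missing = vals.isna().any(axis=1)
    ok = (
        (metrics["dapi_mean"] >= t.dapi_min)
        & metrics["mec_radius"].between(t.mec_radius_min, t.mec_radius_max)
        & metrics["area"].between(t.area_min, t.area_max)
        & metrics["perimeter"].between(t.perimeter_min, t.perimeter_max)
        & (metrics["total_transcripts"] >= t.transcripts_min)
        & ~has_missing
    )
    return QCResult(
        retained=metrics.loc[ok, "cell_id"].tolist(),
        missing=metrics.loc[has_missing].copy(),
    )
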