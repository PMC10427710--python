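"""Polygon fusion, transcript assignment, metrics, and QC filtering."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from stratafish.segmentation import (
    QCThresholds,
    SegmentationSet,
    assign_transcripts,
    compute_metrics,
    merge_segmentations,
    minimum_enclosing_circle,
    polygon_metrics,
    qc_filter,
)

from oracles import oracle_min_enclosing_circle


def square(x0, y0, side=10.0):
    return Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])


def segset(polys, source="primary", prefix="c"):
    return SegmentationSet([f"{prefix}{i}" for i in range(len(polys))], list(polys), source)


class TestMerge:
    def test_disjoint_rescue_retained(self):
        primary = segset([square(0, 0)])
        rescue = segset([square(20, 20)], "rescue", "r")
        merged = merge_segmentations(primary, rescue)
        assert set(merged.cell_ids) == {"c0", "r0"}

    def test_contained_rescue_dropped(self):
        primary = segset([square(0, 0, 30)])
        rescue = segset([square(5, 5, 5)], "rescue", "r")
        merged = merge_segmentations(primary, rescue)
        assert merged.cell_ids == ["c0"]

    def test_exact_threshold_boundary_strictly_less(self):
        """A rescue polygon overlapping exactly the threshold fraction is
        dropped (strict <); half that overlap is retained.  Power-of-two
        coordinates keep the fractions float-exact."""
        thr = 1.0 / 1024.0
        rescue = segset([square(0, 0, 8.0)], "rescue", "r")  # area 64
        w = 8.0 / 1024.0  # overlap strip width -> fraction exactly 1/1024
        at_threshold = segset([square(8.0 - w, 0, 8.0)])
        merged = merge_segmentations(at_threshold, rescue, overlap_threshold=thr)
        assert "r0" not in merged.cell_ids
        below = segset([square(8.0 - w / 2, 0, 8.0)])  # fraction 1/2048
        merged = merge_segmentations(below, rescue, overlap_threshold=thr)
        assert "r0" in merged.cell_ids

    def test_merge_idempotent(self):
        primary = segset([square(0, 0), square(30, 0)])
        rescue = segset(
            [square(20, 20), square(2, 2, 4), square(60, 60)], "rescue", "r"
        )
        merged = merge_segmentations(primary, rescue)
        # merging the merged set with the same rescue polygons again (fresh
        # ids: duplicates are rejected by design) must change nothing: every
        # copy either overlaps its retained twin completely or was already
        # over the threshold
        rescue2 = SegmentationSet(
            [f"s{i}" for i in range(len(rescue))], rescue.polygons, "rescue"
        )
        again = merge_segmentations(merged, rescue2)
        assert again.cell_ids == merged.cell_ids
        assert [p.wkt for p in again.polygons] == [p.wkt for p in merged.polygons]

    def test_no_retained_rescue_exceeds_threshold_exactly(self):
        """Clipping audit: every retained rescue polygon overlaps the primary
        union by strictly less than the threshold."""
        rng = np.random.default_rng(0)
        primary = segset([square(x, y, 8) for x, y in rng.uniform(0, 60, (12, 2))])
        rescue_polys = [square(x, y, 8) for x, y in rng.uniform(0, 60, (12, 2))]
        rescue = segset(rescue_polys, "rescue", "r")
        thr = 0.05
        merged = merge_segmentations(primary, rescue, overlap_threshold=thr)
        import shapely

        union = shapely.union_all(primary.polygons)
        for cid, poly in zip(rescue.cell_ids, rescue.polygons):
            frac = poly.intersection(union).area / poly.area
            assert (cid in merged.cell_ids) == (frac < thr)

    def test_threshold_validation(self):
        primary, rescue = segset([square(0, 0)]), segset([square(20, 0)], "rescue", "r")
        with pytest.raises(ValueError, match="overlap_threshold"):
            merge_segmentations(primary, rescue, overlap_threshold=1.5)

    def test_invalid_ring_rejected_with_id(self):
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(ValueError, match="bt"):
            SegmentationSet(["bt"], [bowtie])


class TestMetrics:
    def test_equilateral_triangle_closed_forms(self):
        tri = Polygon([(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)])
        m = polygon_metrics(tri, dapi_mean=100.0)
        assert m["mec_radius"] == pytest.approx(1 / np.sqrt(3), rel=1e-9)
        assert m["perimeter"] == pytest.approx(3.0, rel=1e-9)
        assert m["area"] == pytest.approx(np.sqrt(3) / 4, rel=1e-9)

    def test_two_point_circle_is_half_distance(self):
        center, r = minimum_enclosing_circle(np.array([[0.0, 0.0], [6.0, 8.0]]))
        assert r == pytest.approx(5.0)
        np.testing.assert_allclose(center, [3.0, 4.0])

    def test_single_point_circle_is_degenerate(self):
        _, r = minimum_enclosing_circle(np.array([[2.0, 3.0]]))
        assert r == 0.0

    def test_random_polygons_match_enumeration_oracle(self):
        """The minimum enclosing circle must equal the brute-force minimum
        over all diameter-pairs and circumcircle-triples."""
        rng = np.random.default_rng(1)
        for _ in range(8):
            pts = rng.uniform(0, 50, size=(20, 2))
            _, got = minimum_enclosing_circle(pts)
            want = oracle_min_enclosing_circle(pts)
            assert got == pytest.approx(want, rel=1e-7)

    def test_isoperimetric_and_circle_bounds_hold(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(3, 10, n)
            poly = Polygon(np.c_[rad * np.cos(ang), rad * np.sin(ang)])
            if not poly.is_valid or poly.area <= 0:
                continue
            m = polygon_metrics(poly, dapi_mean=1.0)
            assert m["area"] <= np.pi * m["mec_radius"] ** 2 + 1e-9
            assert m["perimeter"] ** 2 >= 4 * np.pi * m["area"] - 1e-9

    def test_degenerate_ring_rejected(self):
        with pytest.raises(Exception):
            polygon_metrics(Polygon([(0, 0), (1, 1), (2, 2)]), dapi_mean=1.0)


class TestAssignTranscripts:
    def test_interior_spot_goes_to_containing_polygon(self):
        polys = segset([square(0, 0), square(20, 0)])
        spots = pd.DataFrame({"gene": ["g"], "x": [5.0], "y": [5.0]})
        out = assign_transcripts(spots, polys)
        assert out["cell_id"][0] == "c0"

    def test_exterior_spot_goes_to_nearest_boundary_brute_force(self):
        rng = np.random.default_rng(3)
        centers = rng.uniform(0, 200, size=(30, 2))
        polys = segset([square(x, y, 6) for x, y in centers])
        spots = pd.DataFrame(
            {"gene": "g", "x": rng.uniform(0, 200, 40), "y": rng.uniform(0, 200, 40)}
        )
        out = assign_transcripts(spots, polys, pool_size=3)
        import shapely

        for _, row in out.iterrows():
            p = shapely.points([[row.x, row.y]])[0]
            dists = np.array([p.distance(poly) for poly in polys.polygons])
            best = dists.min()
            winners = {polys.cell_ids[i] for i in np.flatnonzero(np.abs(dists - best) < 1e-9)}
            assert row.cell_id in winners

    def test_equidistant_tie_breaks_to_smaller_cell_id(self):
        polys = SegmentationSet(["b", "a"], [square(0, 0), square(20, 0)], "primary")
        spots = pd.DataFrame({"gene": ["g"], "x": [15.0], "y": [5.0]})
        out = assign_transcripts(spots, polys)
        assert out["cell_id"][0] == "a"

    def test_conservation_every_spot_assigned_once(self):
        rng = np.random.default_rng(4)
        polys = segset([square(x, y, 8) for x, y in rng.uniform(0, 100, (15, 2))])
        spots = pd.DataFrame(
            {"gene": "g", "x": rng.uniform(0, 100, 300), "y": rng.uniform(0, 100, 300)}
        )
        out = assign_transcripts(spots, polys)
        assert out["cell_id"].notna().all()
        assert out["cell_id"].map(len).gt(0).all()
        totals = out["cell_id"].value_counts().sum()
        assert totals == len(spots)

    def test_max_distance_cap_leaves_far_spots_unassigned(self):
        polys = segset([square(0, 0)])
        spots = pd.DataFrame({"gene": ["g"], "x": [500.0], "y": [500.0]})
        out = assign_transcripts(spots, polys, max_distance=10.0)
        assert out["cell_id"].isna().all()

    def test_empty_polygon_set_rejected(self):
        spots = pd.DataFrame({"gene": ["g"], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError, match="empty"):
            assign_transcripts(spots, SegmentationSet([], [], "primary"))


def _metrics_row(cell_id="c", dapi=100.0, radius=20.0, area=1000.0, perim=100.0, n=50):
    return {
        "cell_id": cell_id, "dapi_mean": dapi, "mec_radius": radius,
        "area": area, "perimeter": perim, "total_transcripts": n,
    }


class TestQCFilter:
    def test_dapi_just_below_threshold_removed(self):
        df = pd.DataFrame([_metrics_row(dapi=79.99)])
        assert qc_filter(df).retained == []

    def test_exactly_at_all_thresholds_retained(self):
        """The printed bounds are inclusive: a cell exactly at every lower
        bound survives."""
        df = pd.DataFrame(
            [_metrics_row(dapi=80.0, radius=10.0, area=500.0, perim=50.0, n=10)]
        )
        assert qc_filter(df).retained == ["c"]

    def test_tightening_any_threshold_never_grows_retained_set(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            [
                _metrics_row(
                    f"c{i}",
                    dapi=rng.uniform(40, 160),
                    radius=rng.uniform(5, 100),
                    area=rng.uniform(100, 12000),
                    perim=rng.uniform(20, 500),
                    n=int(rng.integers(0, 60)),
                )
                for i in range(200)
            ]
        )
        base = set(qc_filter(df).retained)
        tighter = [
            QCThresholds(dapi_min=90),
            QCThresholds(mec_radius_min=15),
            QCThresholds(mec_radius_max=60),
            QCThresholds(area_min=800),
            QCThresholds(area_max=8000),
            QCThresholds(perimeter_min=80),
            QCThresholds(perimeter_max=300),
            QCThresholds(transcripts_min=20),
        ]
        for t in tighter:
            assert set(qc_filter(df, t).retained) <= base

    def test_equals_naive_conjunction_of_interval_tests(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            [
                _metrics_row(
                    f"c{i}",
                    dapi=rng.uniform(40, 160),
                    radius=rng.uniform(5, 100),
                    area=rng.uniform(100, 12000),
                    perim=rng.uniform(20, 500),
                    n=int(rng.integers(0, 60)),
                )
                for i in range(300)
            ]
        )
        got = set(qc_filter(df).retained)
        naive = {
            r.cell_id
            for r in df.itertuples()
            if r.dapi_mean >= 80
            and 10 <= r.mec_radius <= 80
            and 500 <= r.area <= 10000
            and 50 <= r.perimeter <= 400
            and r.total_transcripts >= 10
        }
        assert got == naive

    def test_missing_metric_reported_not_silently_dropped(self):
        df = pd.DataFrame([_metrics_row("ok"), _metrics_row("bad", dapi=np.nan)])
        res = qc_filter(df)
        assert res.retained == ["ok"]
        assert res.missing["cell_id"].tolist() == ["bad"]


def test_compute_metrics_counts_assigned_transcripts():
    polys = segset([square(0, 0), square(20, 0)])
    spots = pd.DataFrame(
        {"gene": list("ggg"), "x": [1.0, 2.0, 21.0], "y": [1.0, 2.0, 1.0]}
    )
    assigned = assign_transcripts(spots, polys)
    dapi = pd.Series({"c0": 120.0, "c1": 90.0})
    met = compute_metrics(polys, assigned, dapi)
    assert met.set_index("cell_id")["total_transcripts"].to_dict() == {"c0": 2, "c1": 1}
    assert met.set_index("cell_id")["dapi_mean"]["c0"] == 120.0
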