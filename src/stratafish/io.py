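"""File formats: cell tables, spot tables, polygons, counts, latents, chains.

All coordinates are micrometres, 2D, with no global origin convention.
Polygons and boundary chains travel as GeoJSON (a documented dialect: plain
µm coordinates, not geographic).  Counts travel as Matrix Market with
``genes.tsv``/``cells.tsv`` index files (1-based mtx indices per the
standard).  CSV is UTF-8 with a header row and "." decimals.  Writers emit a
canonical field order and float format so that ``write(read(x))`` is
byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from shapely.geometry import Polygon

from .boundaries import BoundaryChains
from .segmentation import SegmentationSet

__all__ = [
    "read_cells", "write_cells",
    "read_spots", "write_spots",
    "read_polygons", "write_polygons",
    "read_counts", "write_counts",
    "read_latents", "write_latents",
    "write_chains", "read_chains",
    "write_depths", "read_depths",
]

_FLOAT_FMT = "%.10g"

CELL_COLUMNS = ["cell_id", "section_id", "x", "y"]
SPOT_COLUMNS = ["gene", "x", "y"]


def _require_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric value in column {c!r} near line {line}")
        df[c] = vals


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str})
    missing = [c for c in ("cell_id", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cells table missing columns {missing}")
    _require_numeric(df, ["x", "y"], path)
    return df


def write_cells(df: pd.DataFrame, path) -> None:
    cols = [c for c in CELL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_spots(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: spots table missing columns {missing}")
    _require_numeric(df, ["x", "y"], path)
    return df


def write_spots(df: pd.DataFrame, path) -> None:
    cols = [c for c in SPOT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_polygons(path, source: str = "primary") -> SegmentationSet:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    ids, polys = [], []
    for k, feat in enumerate(gj.get("features", [])):
        cid = feat.get("properties", {}).get("cell_id")
        label = cid if cid is not None else f"feature #{k}"
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"{path}: {label}: geometry is not a Polygon")
        rings = geom.get("coordinates", [])
        if not rings:
            raise ValueError(f"{path}: {label}: empty polygon")
        ring = rings[0]
        if len(ring) < 4 or ring[0] != ring[-1]:
            raise ValueError(f"{path}: {label}: ring is not closed")
        if cid is None:
            raise ValueError(f"{path}: feature #{k} missing property 'cell_id'")
        ids.append(str(cid))
        polys.append(Polygon(ring))
    return SegmentationSet(ids, polys, source=source)


def write_polygons(segset: SegmentationSet, path) -> None:
    feats = []
    for cid, poly in zip(segset.cell_ids, segset.polygons):
        coords = [[float(x), float(y)] for x, y in poly.exterior.coords]
        feats.append(
            {
                "type": "Feature",
                "properties": {"cell_id": cid, "source": segset.source},
                "geometry": {"type": "Polygon", "coordinates": [coords]},
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
        fh.write("\n")


def read_counts(prefix) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Read ``<prefix>.mtx`` plus ``<prefix>.genes.tsv`` and
    ``<prefix>.cells.tsv``; returns (cells x genes, genes, cell ids)."""
    prefix = Path(prefix)
    mtx_path = Path(f"{prefix}.mtx")
    mat = spio.mmread(mtx_path).tocsr()
    genes = Path(f"{prefix}.genes.tsv").read_text(encoding="utf-8").splitlines()
    cells = Path(f"{prefix}.cells.tsv").read_text(encoding="utf-8").splitlines()
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"{mtx_path}: dimensions {mat.shape} do not match index files "
            f"({len(cells)} cells, {len(genes)} genes)"
        )
    return mat, genes, cells


def write_counts(mat, genes: list[str], cells: list[str], prefix) -> None:
    prefix = Path(prefix)
    m = sparse.coo_matrix(mat)
    if m.shape != (len(cells), len(genes)):
        raise ValueError("matrix shape does not match index lists")
    spio.mmwrite(f"{prefix}.mtx", m)
    Path(f"{prefix}.genes.tsv").write_text("\n".join(genes) + "\n", encoding="utf-8")
    Path(f"{prefix}.cells.tsv").write_text("\n".join(cells) + "\n", encoding="utf-8")


def read_latents(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: latents table missing 'cell_id'")
    zcols = [c for c in df.columns if c.startswith("z")]
    if not zcols:
        raise ValueError(f"{path}: no latent columns (z1..zd) found")
    _require_numeric(df, zcols, path)
    return df[zcols].to_numpy(dtype=float), df["cell_id"].tolist()


def write_latents(latents: np.ndarray, cell_ids: list[str], path) -> None:
    d = latents.shape[1]
    df = pd.DataFrame(latents, columns=[f"z{i}" for i in range(1, d + 1)])
    df.insert(0, "cell_id", cell_ids)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def write_chains(chains: BoundaryChains, path) -> None:
    feats = []
    for role in ("apical", "basal", "lateral"):
        for run in chains.chain(role):
            if len(run) < 2:
                continue
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"role": role},
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [[float(x), float(y)] for x, y in run],
                    },
                }
            )
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "tissue_center": [float(v) for v in chains.tissue_center]
        },
        "features": feats,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_chains(path) -> BoundaryChains:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    runs: dict[str, list[np.ndarray]] = {"apical": [], "basal": [], "lateral": []}
    for feat in gj.get("features", []):
        role = feat.get("properties", {}).get("role")
        if role not in runs:
            raise ValueError(f"{path}: unknown chain role {role!r}")
        coords = np.asarray(feat["geometry"]["coordinates"], dtype=float)
        runs[role].append(coords)
    center = np.asarray(gj.get("properties", {}).get("tissue_center"), dtype=float)
    labels = np.concatenate(
        [np.repeat(role, max(len(r) - 1, 0)) for role in runs for r in runs[role]]
    ) if any(runs.values()) else np.array([], dtype=object)
    return BoundaryChains(
        apical=runs["apical"],
        basal=runs["basal"],
        lateral=runs["lateral"],
        tissue_center=center,
        edge_labels=labels,
    )


def write_depths(df: pd.DataFrame, path) -> None:
    cols = ["cell_id", "d_apical", "d_basal", "depth_ratio"]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(
        path, index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )


def read_depths(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str})
    for c in ("cell_id", "d_apical", "d_basal", "depth_ratio"):
        if c not in df.columns:
            raise ValueError(f"{path}: depth table missing column {c!r}")
    _require_numeric(df, ["d_apical", "d_basal", "depth_ratio"], path)
    return df
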