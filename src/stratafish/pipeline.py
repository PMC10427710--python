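"""End-to-end orchestration: simulate → segment → QC → geometry → statistics
→ integration, with a deterministic run manifest.

Stage order mirrors how the measurements are produced and consumed: polygon
fusion and transcript assignment come first, QC second, then laminar
geometry, the displacement test, reference integration, and regional
composition.  Every stage reads only the configured run directory, never
mutates its inputs, and logs the parameters it applied; the manifest records
a config hash and per-output SHA-256 checksums, so identical configs and
seeds yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io as sfio
from .alphashape import build_alpha_shape
from .boundaries import classify_boundary_edges, estimate_tissue_center, normalized_depth
from .config import PipelineConfig
from .integration import (
    annotate_major_types,
    evaluate_imputation,
    impute_expression,
    train_reference_classifier,
    transfer_labels,
)
from .segmentation import (
    QCThresholds,
    assign_transcripts,
    compute_metrics,
    merge_segmentations,
    qc_filter,
)
from .stats import (
    compare_regional_composition,
    displacement_permutation_test,
    assign_layer,
)
from .synthetic import (
    SegmentationFixtureParams,
    default_genes,
    default_section_spec,
    default_subtypes,
    generate_reference,
    generate_section,
    generate_segmentation_fixture,
)

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

#: QC bounds matched to the µm-scale synthetic polygons (soma-sized hexagons);
#: the defaults in :class:`QCThresholds` suit pixel-scale imaging inputs.
SYNTHETIC_QC = dict(
    dapi_min=80.0, mec_radius_min=1.0, mec_radius_max=20.0,
    area_min=5.0, area_max=2000.0, perimeter_min=5.0, perimeter_max=200.0,
    transcripts_min=10,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, synthetic_qc: bool = True) -> dict:
    """Execute the configured stages and return the run manifest (also
    written to ``<out_dir>/manifest.json``).

    ``synthetic_qc`` applies µm-scale QC bounds suited to the generator's
    polygons instead of the pixel-scale defaults.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = list(config.stages)
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    state: dict = {}

    def finish_stage(name: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "wall_clock_s": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }

    for stage in enabled:
        t0 = time.perf_counter()
        try:
            outputs = _STAGES[stage](config, state, out, manifest, synthetic_qc)
        except Exception as exc:  # noqa: BLE001 - halt with the stage name
            raise PipelineError(stage, str(exc)) from exc
        finish_stage(stage, t0, outputs)
        logger.info("stage %s done in %.1fs", stage, manifest["stages"][stage]["wall_clock_s"])

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# --- stages ----------------------------------------------------------------


def _stage_simulate(config, state, out, manifest, synthetic_qc):
    sim = config.simulate
    genes = default_genes(n_genes=sim.n_genes, n_panel=sim.n_panel, seed=config.seed)
    subtypes = default_subtypes(genes, seed=config.seed)
    sections = []
    fixtures = []
    outputs = []
    for i in range(sim.n_sections):
        spec = default_section_spec(
            seed=config.seed + 101 * i,
            section_id=f"S{i + 1}",
            orientation=sim.orientation,
            target_total=sim.target_total,
        )
        spec.densities = {k: v * sim.density_scale for k, v in spec.densities.items()}
        sec = generate_section(spec, subtypes, genes)
        fix = generate_segmentation_fixture(
            sec, SegmentationFixtureParams(), seed=config.seed + 7001 + i
        )
        sections.append(sec)
        fixtures.append(fix)
        tag = spec.section_id
        sfio.write_cells(sec.cells, out / f"{tag}.cells.csv")
        sec.truth.to_csv(out / f"{tag}.truth.csv", index=False, lineterminator="\n")
        sfio.write_counts(
            sec.counts, genes.names, sec.cells["cell_id"].tolist(), out / f"{tag}.counts"
        )
        sfio.write_latents(sec.latents, sec.cells["cell_id"].tolist(), out / f"{tag}.latents.csv")
        sfio.write_polygons(fix.primary, out / f"{tag}.primary.geojson")
        sfio.write_polygons(fix.rescue, out / f"{tag}.rescue.geojson")
        sfio.write_spots(fix.spots, out / f"{tag}.spots.csv")
        fix.dapi.rename_axis("cell_id").reset_index().to_csv(
            out / f"{tag}.dapi.csv", index=False, float_format="%.10g", lineterminator="\n"
        )
        outputs += [
            out / f"{tag}.cells.csv", out / f"{tag}.truth.csv",
            out / f"{tag}.counts.mtx", out / f"{tag}.counts.genes.tsv",
            out / f"{tag}.counts.cells.tsv", out / f"{tag}.latents.csv",
            out / f"{tag}.primary.geojson", out / f"{tag}.rescue.geojson",
            out / f"{tag}.spots.csv", out / f"{tag}.dapi.csv",
        ]
    ref = generate_reference(
        subtypes, n_cells=sim.reference_cells, seed=config.seed + 9001, genes=genes
    )
    sfio.write_counts(ref.counts, ref.genes, ref.cell_ids, out / "reference.counts")
    sfio.write_latents(ref.latents, ref.cell_ids, out / "reference.latents.csv")
    pd.DataFrame(
        {"cell_id": ref.cell_ids, "label": ref.labels, "major_type": ref.major_type}
    ).to_csv(out / "reference.labels.csv", index=False, lineterminator="\n")
    outputs += [
        out / "reference.counts.mtx", out / "reference.counts.genes.tsv",
        out / "reference.counts.cells.tsv", out / "reference.latents.csv",
        out / "reference.labels.csv",
    ]
    state.update(genes=genes, subtypes=subtypes, sections=sections,
                 fixtures=fixtures, reference=ref)
    return outputs


def _stage_segment_merge(config, state, out, manifest, synthetic_qc):
    outputs = []
    merged_all, assigned_all, metrics_all = [], [], []
    for sec, fix in zip(state["sections"], state["fixtures"]):
        tag = sec.spec.section_id
        merged = merge_segmentations(
            fix.primary, fix.rescue,
            overlap_threshold=config.segmentation.overlap_threshold,
        )
        assigned = assign_transcripts(
            fix.spots[["gene", "x", "y"]], merged,
            pool_size=config.segmentation.pool_size,
        )
        metrics = compute_metrics(merged, assigned, fix.dapi)
        sfio.write_polygons(merged, out / f"{tag}.merged.geojson")
        sfio.write_spots(assigned, out / f"{tag}.spots_assigned.csv")
        metrics.to_csv(out / f"{tag}.metrics.csv", index=False,
                       float_format="%.10g", lineterminator="\n")
        outputs += [out / f"{tag}.merged.geojson", out / f"{tag}.spots_assigned.csv",
                    out / f"{tag}.metrics.csv"]
        merged_all.append(merged)
        assigned_all.append(assigned)
        metrics_all.append(metrics)
    state.update(merged=merged_all, assigned=assigned_all, metrics=metrics_all)
    return outputs


def _stage_qc(config, state, out, manifest, synthetic_qc):
    qc_kwargs = SYNTHETIC_QC if synthetic_qc else config.qc.model_dump()
    thresholds = QCThresholds(**qc_kwargs)
    manifest.setdefault("applied_defaults", {})["qc_thresholds"] = qc_kwargs
    outputs = []
    retained_all = []
    for sec, metrics in zip(state["sections"], state["metrics"]):
        tag = sec.spec.section_id
        res = qc_filter(metrics, thresholds)
        pd.DataFrame({"cell_id": res.retained}).to_csv(
            out / f"{tag}.qc_retained.csv", index=False, lineterminator="\n"
        )
        if len(res.missing):
            manifest["warnings"].append(
                f"{tag}: {len(res.missing)} cells with missing QC metrics"
            )
        outputs.append(out / f"{tag}.qc_retained.csv")
        retained_all.append(set(res.retained))
    state["qc_retained"] = retained_all
    return outputs


def _inl_boundary_cells(sec, retained):
    """Cells anchoring the INL boundary: non-displaceable INL residents."""
    cells = sec.cells
    mask = cells["major_type"].isin(["BC", "HC", "MG"])
    if retained is not None:
        mask &= cells["cell_id"].isin(retained)
    return cells[mask]


def estimate_inl_chains(
    anchor: pd.DataFrame,
    amacrines: pd.DataFrame,
    alpha: float,
    lateral_fraction: float = 0.025,
    fringe_margin: float = 15.0,
):
    """Two-pass INL boundary estimation.

    Pass 1 anchors the alpha-shape on non-displaceable INL residents
    (bipolar, horizontal, Mueller cells).  Because amacrine somata are the
    basal-most INL cells, the pass-1 basal chain sits slightly apical of the
    true band edge; pass 2 re-anchors after adding amacrines within
    ``fringe_margin`` (µm, about half the inner plexiform gap) below the
    provisional basal chain — an automated surrogate for interactive
    boundary curation.  Displaced amacrines in the ganglion cell layer lie a
    full plexiform gap below and never enter the anchor set.
    """
    from .boundaries import distance_to_chain  # local: avoid cycle at import

    pts1 = anchor[["x", "y"]].to_numpy()
    shape1 = build_alpha_shape(pts1, alpha)
    center1 = estimate_tissue_center(pts1)
    chains1 = classify_boundary_edges(shape1, center1, lateral_fraction=lateral_fraction)
    if amacrines is None or len(amacrines) == 0 or not chains1.basal:
        return chains1
    ac_pts = amacrines[["x", "y"]].to_numpy()
    r_ac = np.linalg.norm(ac_pts - center1, axis=1)
    basal = chains1.as_multilinestring("basal")
    import shapely

    lines = shapely.shortest_line(basal, shapely.points(ac_pts))
    near = shapely.get_coordinates(lines)[::2]
    r_b = np.linalg.norm(near - center1, axis=1)
    fringe = r_ac > r_b - fringe_margin
    if not fringe.any():
        return chains1
    pts2 = np.vstack([pts1, ac_pts[fringe]])
    shape2 = build_alpha_shape(pts2, alpha)
    center2 = estimate_tissue_center(pts2)
    return classify_boundary_edges(shape2, center2, lateral_fraction=lateral_fraction)


def _stage_boundaries(config, state, out, manifest, synthetic_qc):
    outputs = []
    chains_all = []
    for sec, retained in zip(state["sections"], state["qc_retained"]):
        tag = sec.spec.section_id
        anchor = _inl_boundary_cells(sec, retained)
        acs = sec.cells[
            (sec.cells["major_type"] == "AC")
            & sec.cells["cell_id"].isin(retained)
        ]
        chains = estimate_inl_chains(
            anchor, acs, config.boundaries.alpha,
            lateral_fraction=config.boundaries.lateral_fraction,
            fringe_margin=config.boundaries.fringe_margin,
        )
        sfio.write_chains(chains, out / f"{tag}.chains.geojson")
        outputs.append(out / f"{tag}.chains.geojson")
        chains_all.append(chains)
    state["chains"] = chains_all
    return outputs


def _stage_depth(config, state, out, manifest, synthetic_qc):
    outputs = []
    depths_all = []
    for sec, chains, retained in zip(
        state["sections"], state["chains"], state["qc_retained"]
    ):
        tag = sec.spec.section_id
        inl = sec.cells[
            sec.cells["major_type"].isin(["BC", "AC", "HC", "MG"])
            & sec.cells["cell_id"].isin(retained)
        ]
        depths = normalized_depth(
            inl, chains, apical_reference=config.boundaries.apical_reference
        )
        sfio.write_depths(depths, out / f"{tag}.depths.csv")
        outputs.append(out / f"{tag}.depths.csv")
        depths_all.append(depths)
    state["depths"] = depths_all
    return outputs


def _stage_layers(config, state, out, manifest, synthetic_qc):
    outputs = []
    layers_all = []
    for sec, chains in zip(state["sections"], state["chains"]):
        tag = sec.spec.section_id
        acs = sec.cells[sec.cells["major_type"] == "AC"].reset_index(drop=True)
        layer = assign_layer(acs, chains)
        df = pd.DataFrame({"cell_id": acs["cell_id"], "layer": layer})
        df.to_csv(out / f"{tag}.layers.csv", index=False, lineterminator="\n")
        outputs.append(out / f"{tag}.layers.csv")
        layers_all.append(df.assign(section=tag, subtype=acs["subtype"].to_numpy()))
    state["ac_layers"] = layers_all
    return outputs


def _stage_displacement(config, state, out, manifest, synthetic_qc):
    pooled = pd.concat(state["ac_layers"], ignore_index=True)
    pooled = pooled[pooled["layer"].isin(["INL", "GCL"])]
    results = displacement_permutation_test(
        pooled[["section", "subtype", "layer"]],
        n_perm=config.displacement.n_perm,
        alpha=config.displacement.alpha_level,
        min_cells=config.displacement.min_cells,
        seed=config.seed + 31,
    )
    table = pd.DataFrame([r.to_row() for r in results])
    table.to_csv(out / "displacement.csv", index=False,
                 float_format="%.10g", lineterminator="\n")
    with open(out / "displacement.params.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"n_perm": config.displacement.n_perm,
             "alpha_level": config.displacement.alpha_level,
             "min_cells": config.displacement.min_cells,
             "seed": config.seed + 31},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    state["displacement"] = results
    return [out / "displacement.csv", out / "displacement.params.json"]


def _stage_transfer(config, state, out, manifest, synthetic_qc):
    ref = state["reference"]
    genes = state["genes"]
    outputs = []
    transfers = []
    for sec in state["sections"]:
        tag = sec.spec.section_id
        panel_idx = genes.index_of(genes.panel)
        majors = annotate_major_types(
            sec.counts[:, panel_idx], genes.panel, genes.marker_sets
        )
        rows = []
        for major in ("BC", "AC", "RGC"):
            q_mask = majors == major
            r_mask = ref.major_type == major
            if q_mask.sum() == 0 or r_mask.sum() == 0:
                continue
            sub_ref = _subset_reference(ref, r_mask)
            clf = train_reference_classifier(sub_ref, seed=config.seed + 71)
            res = transfer_labels(
                sec.latents[q_mask], sub_ref, classifier=clf,
                k=config.transfer.k,
                query_ids=sec.cells.loc[q_mask, "cell_id"].tolist(),
            )
            rows.append(res[["cell_id", "assigned_label", "probability", "neighbor_ids"]])
        res_all = pd.concat(rows, ignore_index=True)
        res_all.to_csv(out / f"{tag}.transfer.csv", index=False,
                       float_format="%.10g", lineterminator="\n")
        outputs.append(out / f"{tag}.transfer.csv")
        transfers.append(res_all.assign(section=tag))
        state.setdefault("query_majors", {})[tag] = majors
    state["transfer"] = transfers
    return outputs


def _subset_reference(ref, mask):
    from .integration import ReferenceSet

    idx = np.flatnonzero(mask)
    return ReferenceSet(
        cell_ids=[ref.cell_ids[i] for i in idx],
        counts=ref.counts[idx],
        genes=ref.genes,
        labels=ref.labels[idx],
        major_type=ref.major_type[idx],
        latents=ref.latents[idx],
    )


def _stage_impute(config, state, out, manifest, synthetic_qc):
    ref = state["reference"]
    genes = state["genes"]
    outputs = []
    for sec in state["sections"]:
        tag = sec.spec.section_id
        majors = state.get("query_majors", {}).get(tag)
        if majors is None:
            panel_idx = genes.index_of(genes.panel)
            majors = annotate_major_types(
                sec.counts[:, panel_idx], genes.panel, genes.marker_sets
            )
        panel_idx = genes.index_of(genes.panel)
        result = impute_expression(
            sec.latents, majors, ref,
            mode=config.impute.mode, k=config.impute.k, restrict="major",
            measured=sec.counts[:, panel_idx], panel=genes.panel,
            query_ids=sec.cells["cell_id"].tolist(),
        )
        table, summary = evaluate_imputation(
            result.imputed, sec.counts[:, panel_idx], result.genes,
            measured_genes=genes.panel,
        )
        table.to_csv(out / f"{tag}.imputation_pcc.csv", index=False,
                     float_format="%.10g", lineterminator="\n")
        with open(out / f"{tag}.imputation_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        if result.flagged:
            manifest["warnings"].append(
                f"{tag}: {len(result.flagged)} cells not imputed (type missing in reference)"
            )
        outputs += [out / f"{tag}.imputation_pcc.csv", out / f"{tag}.imputation_summary.json"]
    return outputs


def _stage_regions(config, state, out, manifest, synthetic_qc):
    labeled = []
    for sec in state["sections"]:
        spec = sec.spec
        from .stats import assign_quadrants

        region = assign_quadrants(
            sec.cells, spec.orientation,
            rotation=config.regions.rotation, left_region=spec.left_region,
        )
        labeled.append(
            sec.cells.assign(region=region.to_numpy())[
                ["cell_id", "section_id", "major_type", "subtype", "region"]
            ]
        )
    pd.concat(labeled, ignore_index=True).to_csv(
        out / "regions.cells.csv", index=False, lineterminator="\n"
    )
    outputs = [out / "regions.cells.csv"]
    if len(labeled) >= 2:
        comp = compare_regional_composition(
            labeled, unit="subtype", normalization=config.regions.normalization
        )
        comp.to_csv(out / "regions.comparison.csv", index=False,
                    float_format="%.10g", lineterminator="\n")
        outputs.append(out / "regions.comparison.csv")
    else:
        manifest["warnings"].append(
            "regions: <2 sections; wrote per-cell regions, skipped the t-test"
        )
    return outputs


_STAGES = {
    "simulate": _stage_simulate,
    "segment-merge": _stage_segment_merge,
    "qc": _stage_qc,
    "boundaries": _stage_boundaries,
    "depth": _stage_depth,
    "layers": _stage_layers,
    "displacement": _stage_displacement,
    "transfer": _stage_transfer,
    "impute": _stage_impute,
    "regions": _stage_regions,
}
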