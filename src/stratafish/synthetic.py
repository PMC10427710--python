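"""Synthetic layered-retina sections with known ground truth.

The generator emulates the measured data downstream stages consume: an
arc-shaped cross-section with three nuclear layers (GCL innermost, then INL,
then ONL), per-subtype laminar depth distributions (Beta on the normalized
band depth — bounded on [0,1], two parameters reproduce apical/basal skew),
amacrine displacement into the GCL at a per-subtype rate, marker-structured
Poisson counts at a ~80 transcripts/cell scale, a paired deeper "reference"
dataset over a larger gene set sharing each subtype's latent-space Gaussian
(emulating a successful co-embedding), two overlapping segmentation polygon
sets with per-cell DAPI intensities, and quadrant-asymmetric subtype
abundances.  Every cell carries a truth record (layer, subtype, normalized
depth, region), so recovery can be scored exactly.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seeds give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import sparse
from shapely.geometry import Polygon

from .integration import ReferenceSet
from .segmentation import SegmentationSet

__all__ = [
    "GeneUniverse",
    "SectionSpec",
    "SubtypeSpec",
    "SyntheticSection",
    "SegmentationFixtureParams",
    "SegmentationFixture",
    "default_genes",
    "default_subtypes",
    "default_section_spec",
    "generate_section",
    "generate_reference",
    "generate_segmentation_fixture",
]

LAYERS = ("GCL", "INL", "ONL")
MAJOR_TYPES = ("Rod", "Cone", "BC", "AC", "RGC", "HC", "MG")

#: major-type mixture within each layer of a cross-section
LAYER_COMPOSITION: dict[str, dict[str, float]] = {
    "ONL": {"Rod": 0.92, "Cone": 0.08},
    "INL": {"BC": 0.45, "AC": 0.33, "HC": 0.06, "MG": 0.16},
    "GCL": {"RGC": 1.0},
}

#: major-type mixture of the dissociated reference (interneuron-enriched)
REFERENCE_COMPOSITION: dict[str, float] = {
    "Rod": 0.30, "Cone": 0.05, "BC": 0.22, "AC": 0.22,
    "RGC": 0.10, "HC": 0.04, "MG": 0.07,
}

ORIENTATION_REGIONS = {
    "dorsal-ventral": ("dorsal", "ventral"),
    "temporal-nasal": ("temporal", "nasal"),
}

LATENT_DIM = 15


@dataclass
class GeneUniverse:
    """Gene names, the imaging-panel subset, and major-type marker sets."""

    names: list[str]
    panel: list[str]
    marker_sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("gene names must be unique")
        missing = set(self.panel) - set(self.names)
        if missing:
            raise ValueError(f"panel genes absent from universe: {sorted(missing)[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.names)

    def index_of(self, genes: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.names)}
        return np.array([pos[g] for g in genes], dtype=int)


@dataclass
class SubtypeSpec:
    """One molecular subtype: abundance, laminar depth law, displacement
    rate, expression profile, and latent-space Gaussian."""

    name: str
    major_type: str
    abundance: float
    depth_params: tuple[float, float] = (1.0, 1.0)
    displacement_ratio: float = 0.0
    expression_profile: np.ndarray | None = None
    latent_mean: np.ndarray | None = None
    latent_sd: float = 1.0
    region_abundance: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.major_type not in MAJOR_TYPES:
            raise ValueError(f"unknown major type {self.major_type!r}")
        if not 0.0 < self.abundance <= 1.0:
            raise ValueError(f"{self.name}: abundance must be in (0, 1]")
        a, b = self.depth_params
        if a <= 0 or b <= 0:
            raise ValueError(f"{self.name}: Beta depth parameters must be positive")
        if not 0.0 <= self.displacement_ratio <= 1.0:
            raise ValueError(f"{self.name}: displacement_ratio must be in [0, 1]")
        if self.latent_sd <= 0:
            raise ValueError(f"{self.name}: latent_sd must be positive")
        if self.expression_profile is not None:
            prof = np.asarray(self.expression_profile, dtype=float)
            if not np.isfinite(prof).all() or (prof < 0).any():
                raise ValueError(f"{self.name}: expression profile must be finite and nonnegative")
            self.expression_profile = prof


@dataclass
class SectionSpec:
    """Geometry and sampling parameters of one arc-shaped cross-section."""

    center: tuple[float, float] = (0.0, 0.0)
    #: radial bands; the gaps between them are the cell-free plexiform layers
    #: (IPL between GCL and INL, OPL between INL and ONL)
    layer_radii: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "GCL": (790.0, 840.0),
            "INL": (870.0, 940.0),
            "ONL": (945.0, 1045.0),
        }
    )
    angular_span: tuple[float, float] = (math.pi / 2 - 0.9, math.pi / 2 + 0.9)
    densities: dict[str, float] = field(
        default_factory=lambda: {"GCL": 0.012, "INL": 0.035, "ONL": 0.07}
    )
    orientation: str = "dorsal-ventral"
    seed: int = 0
    section_id: str = "S1"
    target_total: float = 80.0
    left_region: str | None = None  # region mapped to smaller-x half

    def __post_init__(self) -> None:
        if set(self.layer_radii) != set(LAYERS):
            raise ValueError(f"layer_radii must define exactly {LAYERS}")
        prev_hi = -np.inf
        for layer in LAYERS:  # GCL innermost, ONL outermost
            lo, hi = self.layer_radii[layer]
            if not lo < hi:
                raise ValueError(f"{layer}: radial interval must be increasing")
            if lo < prev_hi:
                raise ValueError("layer radial intervals overlap or are out of order")
            prev_hi = hi
        t0, t1 = self.angular_span
        if not t0 < t1:
            raise ValueError("angular_span must satisfy theta_min < theta_max")
        for layer, d in self.densities.items():
            if d <= 0:
                raise ValueError(f"{layer}: density must be positive")
        if self.orientation not in ORIENTATION_REGIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.left_region is None:
            self.left_region = ORIENTATION_REGIONS[self.orientation][0]
        if self.left_region not in ORIENTATION_REGIONS[self.orientation]:
            raise ValueError(
                f"left_region {self.left_region!r} not valid for {self.orientation}"
            )

    @property
    def regions(self) -> tuple[str, str]:
        return ORIENTATION_REGIONS[self.orientation]

    @property
    def right_region(self) -> str:
        a, b = self.regions
        return b if self.left_region == a else a


@dataclass
class SyntheticSection:
    """Bundle of everything one generated section provides downstream."""

    spec: SectionSpec
    cells: pd.DataFrame  # cell_id, x, y, section_id, major_type, subtype
    counts: sparse.csr_matrix  # cells x genes, full universe
    genes: GeneUniverse
    latents: np.ndarray  # cells x LATENT_DIM, shared with the reference
    truth: pd.DataFrame  # cell_id, true_layer, true_subtype, true_depth, true_region
    requested_displacement: dict[str, float]


def default_genes(n_genes: int = 400, n_panel: int = 200, seed: int = 0) -> GeneUniverse:
    """A gene universe with major-type marker blocks inside the panel.

    The first ``n_panel`` genes form the imaging panel (marker blocks first);
    the remainder are panel-absent genes used to score imputation.
    """
    if n_panel > n_genes:
        raise ValueError("panel cannot exceed the gene universe")
    marker_sets = {
        major: [f"mk_{major}_{i}" for i in range(1, 6)] for major in MAJOR_TYPES
    }
    marker_names = [g for major in MAJOR_TYPES for g in marker_sets[major]]
    if len(marker_names) > n_panel:
        raise ValueError("panel too small for the marker blocks")
    n_rest = n_genes - len(marker_names)
    rest = [f"g{i:04d}" for i in range(1, n_rest + 1)]
    names = marker_names + rest
    return GeneUniverse(names=names, panel=names[:n_panel], marker_sets=marker_sets)


def _depth(a: float, b: float) -> tuple[float, float]:
    return (a, b)


# (name, major, abundance within major, depth Beta, displacement)
_DEFAULT_ROSTER: list[tuple[str, str, float, tuple[float, float], float]] = [
    ("Rod", "Rod", 1.0, _depth(1, 1), 0.0),
    ("Cone_S", "Cone", 0.4, _depth(1, 1), 0.0),
    ("Cone_M", "Cone", 0.6, _depth(1, 1), 0.0),
    # bipolar subtypes: RBC most apical, BC1B central-basal
    ("RBC", "BC", 0.35, _depth(2, 8), 0.0),
    ("BC1A", "BC", 0.12, _depth(6.5, 3.5), 0.0),
    ("BC1B", "BC", 0.05, _depth(6, 5), 0.0),
    ("BC5C", "BC", 0.18, _depth(6, 4), 0.0),
    ("BC6", "BC", 0.15, _depth(3.5, 6.5), 0.0),
    ("BC9", "BC", 0.15, _depth(3, 7), 0.0),
    # amacrine subtypes: AC1-AC3 preferentially displaced into the GCL,
    # the rest at a 5% background rate; GABAergic-like basal (first six),
    # glycinergic-like apical (last six)
    ("AC1", "AC", 1 / 12, _depth(6, 3), 0.20),
    ("AC2", "AC", 1 / 12, _depth(6, 3), 0.50),
    ("AC3", "AC", 1 / 12, _depth(6, 3), 0.80),
    ("AC4", "AC", 1 / 12, _depth(6, 3), 0.05),
    ("AC5", "AC", 1 / 12, _depth(6.5, 3), 0.05),
    ("AC6", "AC", 1 / 12, _depth(5.5, 3), 0.05),
    ("AC7", "AC", 1 / 12, _depth(3, 6), 0.05),
    ("AC8", "AC", 1 / 12, _depth(3, 6.5), 0.05),
    ("AC9", "AC", 1 / 12, _depth(3, 5.5), 0.05),
    ("AC10", "AC", 1 / 12, _depth(2.5, 6), 0.05),
    ("AC11", "AC", 1 / 12, _depth(3.5, 6), 0.05),
    ("AC12", "AC", 1 / 12, _depth(3, 7), 0.05),
    ("RGC1", "RGC", 0.5, _depth(1, 1), 0.0),
    ("RGC2", "RGC", 0.3, _depth(1, 1), 0.0),
    ("RGC3", "RGC", 0.2, _depth(1, 1), 0.0),
    ("HC1", "HC", 1.0, _depth(1.2, 8), 0.0),
    ("MG1", "MG", 1.0, _depth(4, 4), 0.0),
]

#: expression-profile structure: every non-marker gene is "on" (strongly
#: expressed, marker-like) in a small random subset of subtypes and near-off
#: elsewhere, emulating a cell-type-informative probe panel
BG_ON_PROB = 0.03  # per-subtype probability a gene is on
BG_ON_LEVEL = 3.0  # on level relative to the gene's baseline scale
BG_OFF_LEVEL = 0.02  # off level (leaky background)
MAJOR_MARKER_LEVEL = 4.0  # each of the 5 major-type markers, own type
LATENT_SEPARATION = 6.0  # minimum pairwise latent-mean distance, in latent_sd units


def default_subtypes(
    genes: GeneUniverse | None = None,
    seed: int = 0,
    rbc_ventral_factor: float = 30.0 / 35.0,
) -> list[SubtypeSpec]:
    """The default subtype roster with expression profiles and latents.

    ``rbc_ventral_factor`` scales the RBC abundance in the ventral region,
    seeding the dorsal/ventral asymmetry (~35% vs ~30% of bipolar cells).
    """
    genes = genes or default_genes()
    rng = np.random.default_rng(seed)
    n = len(_DEFAULT_ROSTER)
    # latent means: rejection-sample a Gaussian cloud until well separated
    for scale in (3.0, 4.0, 5.0, 6.0, 8.0):
        means = rng.normal(0.0, scale, size=(n, LATENT_DIM))
        dists = np.linalg.norm(means[:, None] - means[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= LATENT_SEPARATION:
            break
    else:  # pragma: no cover - the widest scale essentially always separates
        raise RuntimeError("could not separate latent means")

    base = rng.lognormal(mean=0.0, sigma=0.3, size=genes.n_genes)
    all_marker_idx = np.concatenate(
        [genes.index_of(genes.marker_sets[m]) for m in MAJOR_TYPES]
    )
    is_marker = np.zeros(genes.n_genes, dtype=bool)
    is_marker[all_marker_idx] = True
    # per-gene on-sets over subtypes; every non-marker gene is on somewhere
    on = rng.random((n, genes.n_genes)) < BG_ON_PROB
    dead = ~on.any(axis=0) & ~is_marker
    on[rng.integers(0, n, size=int(dead.sum())), np.flatnonzero(dead)] = True

    subtypes: list[SubtypeSpec] = []
    for k, (name, major, abund, depth, disp) in enumerate(_DEFAULT_ROSTER):
        profile = base * np.where(on[k], BG_ON_LEVEL, BG_OFF_LEVEL)
        marker_idx = genes.index_of(genes.marker_sets[major])
        profile[marker_idx] = MAJOR_MARKER_LEVEL
        # marker blocks are disjoint: other majors' markers are silent
        other_idx = all_marker_idx[~np.isin(all_marker_idx, marker_idx)]
        profile[other_idx] = 0.0
        region_ab = None
        if name == "RBC" and rbc_ventral_factor != 1.0:
            region_ab = {"dorsal": 1.0, "ventral": rbc_ventral_factor}
        subtypes.append(
            SubtypeSpec(
                name=name,
                major_type=major,
                abundance=abund,
                depth_params=depth,
                displacement_ratio=disp,
                expression_profile=profile,
                latent_mean=means[k],
                latent_sd=1.0,
                region_abundance=region_ab,
            )
        )
    _validate_roster(subtypes)
    return subtypes


def default_section_spec(
    seed: int, section_id: str = "S1", orientation: str = "dorsal-ventral", **kw
) -> SectionSpec:
    return SectionSpec(seed=seed, section_id=section_id, orientation=orientation, **kw)


def _validate_roster(subtypes: list[SubtypeSpec]) -> None:
    if not subtypes:
        raise ValueError("subtype list is empty")
    names = [s.name for s in subtypes]
    if len(set(names)) != len(names):
        raise ValueError("subtype names must be unique")
    by_major: dict[str, float] = {}
    for s in subtypes:
        by_major[s.major_type] = by_major.get(s.major_type, 0.0) + s.abundance
    for major, total in by_major.items():
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"abundances within major type {major} sum to {total:.4f}, not 1"
            )


def generate_section(
    spec: SectionSpec,
    subtypes: list[SubtypeSpec],
    genes: GeneUniverse | None = None,
    with_expression: bool = True,
) -> SyntheticSection:
    """Generate one arc-shaped section: cells, counts, latents, and truth.

    Cell centroids are placed uniformly in angle within the section span and
    area-uniformly in radius at the subtype's sampled normalized depth;
    amacrine cells move to the GCL band with probability
    ``displacement_ratio``.  Counts are Poisson around the subtype profile
    scaled to ``spec.target_total`` (~80 transcripts per cell); latents are
    drawn from the subtype's Gaussian, shared with the paired reference.
    ``with_expression=False`` skips counts and latents (geometry/label-only
    studies); the positional stream is unchanged.
    """
    _validate_roster(subtypes)
    genes = genes or default_genes()
    for s in subtypes:
        if with_expression and (s.expression_profile is None or s.latent_mean is None):
            raise ValueError(f"{s.name}: profile and latent mean are required")
        if (
            with_expression
            and len(s.expression_profile) != genes.n_genes
        ):
            raise ValueError(f"{s.name}: profile length != gene universe size")
    rng = np.random.default_rng(spec.seed)
    t0, t1 = spec.angular_span
    cx, cy = spec.center
    name_to_idx = {s.name: k for k, s in enumerate(subtypes)}
    gcl_lo, gcl_hi = spec.layer_radii["GCL"]

    chunks: list[pd.DataFrame] = []
    for layer in LAYERS:
        lo, hi = spec.layer_radii[layer]
        area = 0.5 * (t1 - t0) * (hi * hi - lo * lo)
        if area <= 0:
            raise ValueError(f"{layer}: zero-area band")
        n_cells = int(rng.poisson(spec.densities[layer] * area))
        if n_cells == 0:
            continue
        theta = rng.uniform(t0, t1, n_cells)
        mid = 0.5 * (t0 + t1)
        # smaller angle -> larger x for an arc around pi/2; region from x sign
        regions = np.where(theta < mid, spec.right_region, spec.left_region)
        comp = LAYER_COMPOSITION.get(layer, {})
        candidates = [s for s in subtypes if s.major_type in comp]
        if not candidates:
            continue
        base_w = np.array(
            [comp[s.major_type] * s.abundance for s in candidates], dtype=float
        )
        for reg in spec.regions:
            sel = np.flatnonzero(regions == reg)
            if len(sel) == 0:
                continue
            w = base_w.copy()
            for j, s in enumerate(candidates):
                if s.region_abundance:
                    w[j] *= s.region_abundance.get(reg, 1.0)
            w = w / w.sum()
            choice = rng.choice(len(candidates), size=len(sel), p=w)
            for ci, s in enumerate(candidates):
                rows = sel[choice == ci]
                if len(rows) == 0:
                    continue
                a, b = s.depth_params
                depth = rng.beta(a, b, size=len(rows))
                cell_layer = np.full(len(rows), layer, dtype=object)
                blo = np.full(len(rows), lo)
                bhi = np.full(len(rows), hi)
                if s.major_type == "AC" and s.displacement_ratio > 0:
                    disp = rng.random(len(rows)) < s.displacement_ratio
                    if disp.any():
                        depth[disp] = rng.beta(1.0, 1.0, size=int(disp.sum()))
                        cell_layer[disp] = "GCL"
                        blo[disp] = gcl_lo
                        bhi[disp] = gcl_hi
                r = bhi - depth * (bhi - blo)
                th = theta[rows]
                chunks.append(
                    pd.DataFrame(
                        {
                            "x": cx + r * np.cos(th),
                            "y": cy + r * np.sin(th),
                            "subtype": s.name,
                            "major_type": s.major_type,
                            "true_layer": cell_layer,
                            "true_depth": depth,
                            "true_region": reg,
                        }
                    )
                )
    if not chunks:
        raise ValueError("section spec produced no cells")
    df = pd.concat(chunks, ignore_index=True)
    # deterministic cell order: sort by angle then radius for stable ids
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    n = len(df)
    cell_ids = [f"{spec.section_id}_c{i:06d}" for i in range(n)]
    df.insert(0, "cell_id", cell_ids)

    # counts: Poisson around the subtype profile scaled to the target total
    sub_codes = df["subtype"].map(name_to_idx).to_numpy()
    if with_expression:
        counts = sparse.lil_matrix((n, genes.n_genes), dtype=np.int64)
        latents = np.empty((n, LATENT_DIM))
        for k, s in enumerate(subtypes):
            rows = np.flatnonzero(sub_codes == k)
            if len(rows) == 0:
                continue
            lam = s.expression_profile / s.expression_profile.sum() * spec.target_total
            block = rng.poisson(lam, size=(len(rows), genes.n_genes))
            counts[rows] = block
            latents[rows] = rng.normal(
                s.latent_mean, s.latent_sd, size=(len(rows), LATENT_DIM)
            )
        counts = counts.tocsr()
    else:
        counts = sparse.csr_matrix((n, genes.n_genes), dtype=np.int64)
        latents = np.zeros((n, LATENT_DIM))

    cells = df[["cell_id", "x", "y", "major_type", "subtype"]].copy()
    cells.insert(1, "section_id", spec.section_id)
    truth = df[
        ["cell_id", "true_layer", "true_depth", "true_region"]
    ].copy()
    truth.insert(1, "true_subtype", df["subtype"])
    return SyntheticSection(
        spec=spec,
        cells=cells,
        counts=counts,
        genes=genes,
        latents=latents,
        truth=truth,
        requested_displacement={
            s.name: s.displacement_ratio for s in subtypes if s.major_type == "AC"
        },
    )


def generate_reference(
    subtypes: list[SubtypeSpec],
    n_cells: int,
    n_genes: int | None = None,
    seed: int = 0,
    genes: GeneUniverse | None = None,
    target_total: float = 1000.0,
) -> ReferenceSet:
    """A dissociated reference: labeled counts over the (larger) gene set
    plus latents drawn from the same per-subtype Gaussians as the sections.
    """
    _validate_roster(subtypes)
    genes = genes or default_genes()
    n_genes = genes.n_genes if n_genes is None else n_genes
    if n_genes < len(genes.panel):
        raise ValueError("reference gene set must cover the panel")
    if n_genes > genes.n_genes:
        raise ValueError("reference gene set exceeds the gene universe")
    if n_cells < len(subtypes):
        raise ValueError("n_cells smaller than the number of subtypes")
    means = np.array([s.latent_mean for s in subtypes])
    d = np.linalg.norm(means[:, None] - means[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 0:
        raise ValueError("subtype latent means must be pairwise distinct")
    rng = np.random.default_rng(seed)
    w = np.array(
        [REFERENCE_COMPOSITION[s.major_type] * s.abundance for s in subtypes]
    )
    w = w / w.sum()
    alloc = np.ones(len(subtypes), dtype=int)
    extra = rng.multinomial(n_cells - len(subtypes), w)
    alloc += extra

    labels, majors, lat_rows, count_rows = [], [], [], []
    for s, m in zip(subtypes, alloc):
        labels += [s.name] * m
        majors += [s.major_type] * m
        lat_rows.append(rng.normal(s.latent_mean, s.latent_sd, size=(m, LATENT_DIM)))
        prof = s.expression_profile[:n_genes]
        lam = prof / prof.sum() * target_total
        count_rows.append(rng.poisson(lam, size=(m, n_genes)))
    latents = np.vstack(lat_rows)
    counts = sparse.csr_matrix(np.vstack(count_rows))
    order = rng.permutation(len(labels))
    cell_ids = [f"ref_c{i:06d}" for i in range(len(labels))]
    return ReferenceSet(
        cell_ids=cell_ids,
        counts=counts[order],
        genes=list(genes.names[:n_genes]),
        labels=np.asarray(labels, dtype=object)[order],
        major_type=np.asarray(majors, dtype=object)[order],
        latents=latents[order],
    )


@dataclass
class SegmentationFixtureParams:
    """Controls for the two-segmenter polygon fixture."""

    polygon_radius: float = 3.2  # hexagon circumradius, µm (~7 µm soma)
    primary_layers: tuple[str, ...] = ("ONL", "INL")
    rescue_layers: tuple[str, ...] = ("GCL",)
    overlap_fractions: tuple[float, ...] = ()  # extra rescue polygons at set overlaps
    dapi_mean: float = 150.0
    dapi_sd: float = 25.0
    dapi_low_fraction: float = 0.03  # fraction drawn dim so the DAPI filter bites

    def __post_init__(self) -> None:
        for f in self.overlap_fractions:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"overlap fraction {f} outside [0, 1]")
        if self.polygon_radius <= 0:
            raise ValueError("polygon_radius must be positive")


@dataclass
class SegmentationFixture:
    primary: SegmentationSet
    rescue: SegmentationSet
    spots: pd.DataFrame  # gene, x, y, true_cell
    dapi: pd.Series  # per-cell mean intensity
    overlap_truth: pd.DataFrame  # rescue cell_id, requested, actual fraction


def _hexagon(center: np.ndarray, radius: float, phase: float = 0.0) -> Polygon:
    ang = phase + np.arange(6) * np.pi / 3.0
    return Polygon(np.c_[center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)])


def place_overlapping_polygon(
    base: Polygon, target_fraction: float, radius: float, direction: np.ndarray
) -> Polygon:
    """A hexagon whose intersection with ``base`` is ``target_fraction`` of
    its own area, found by bisection on the center offset along ``direction``."""
    c = np.asarray(base.centroid.coords[0])
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)

    def frac(offset: float) -> float:
        hexp = _hexagon(c + offset * u, radius)
        return hexp.intersection(base).area / hexp.area

    if target_fraction >= 1.0:
        return _hexagon(c, radius)
    lo, hi = 0.0, 4.0 * radius  # frac(lo)~1, frac(hi)=0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target_fraction:
            lo = mid
        else:
            hi = mid
    return _hexagon(c + 0.5 * (lo + hi) * u, radius)


def _scatter_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        batch = max(2 * (n - len(out)), 8)
        cand = np.c_[
            rng.uniform(minx, maxx, batch), rng.uniform(miny, maxy, batch)
        ]
        keep = shapely.covers(poly, shapely.points(cand))
        out = np.vstack([out, cand[keep]])
    return out[:n]


def generate_segmentation_fixture(
    section: SyntheticSection,
    params: SegmentationFixtureParams | None = None,
    seed: int = 0,
) -> SegmentationFixture:
    """Two overlapping polygon sets, transcript spots, and DAPI intensities.

    Primary polygons cover cells of ``primary_layers``; rescue polygons cover
    ``rescue_layers`` plus optional extras with controlled overlap against a
    primary polygon (the requested fraction is recorded in the truth table
    together with the realized clipping fraction).  Each cell's transcripts
    are scattered uniformly inside its polygon; the spot total equals the
    count matrix total exactly.
    """
    params = params or SegmentationFixtureParams()
    if len(section.cells) == 0:
        raise ValueError("section has no cells")
    rng = np.random.default_rng(seed)
    cells = section.cells
    truth_layer = section.truth.set_index("cell_id")["true_layer"]
    xy = cells[["x", "y"]].to_numpy()

    prim_ids, prim_polys = [], []
    resc_ids, resc_polys = [], []
    requested: dict[str, float] = {}
    for cid, pos in zip(cells["cell_id"], xy):
        layer = truth_layer[cid]
        phase = rng.uniform(0, np.pi / 3)
        hexp = _hexagon(pos, params.polygon_radius, phase)
        if layer in params.primary_layers:
            prim_ids.append(cid)
            prim_polys.append(hexp)
        elif layer in params.rescue_layers:
            resc_ids.append(cid)
            resc_polys.append(hexp)
    if not prim_polys:
        raise ValueError("no primary polygons; check primary_layers")

    # extra rescue polygons with controlled overlap, placed against outer-rim
    # primary polygons along the outward radial so only the base (and the
    # primary union near it) is ever intersected; bisection is against the
    # full primary union, so the recorded fraction is the realized one
    center = np.asarray(section.spec.center, dtype=float)
    prim_centroids = np.array([np.asarray(p.centroid.coords[0]) for p in prim_polys])
    rim_order = np.argsort(-np.linalg.norm(prim_centroids - center, axis=1))
    prim_tree = shapely.STRtree(prim_polys)

    def union_fraction(poly: Polygon) -> float:
        cand = prim_tree.query(poly, predicate="intersects")
        if len(cand) == 0:
            return 0.0
        region = shapely.union_all([prim_polys[i] for i in cand])
        return poly.intersection(region).area / poly.area

    for j, f in enumerate(params.overlap_fractions):
        base_idx = int(rim_order[j % len(rim_order)])
        c = prim_centroids[base_idx]
        u = c - center
        u = u / np.linalg.norm(u)
        if f >= 1.0:
            poly = _hexagon(c, params.polygon_radius)
        else:
            lo, hi = 0.0, 4.0 * params.polygon_radius
            for _ in range(60):
                mid_off = 0.5 * (lo + hi)
                if union_fraction(_hexagon(c + mid_off * u, params.polygon_radius)) > f:
                    lo = mid_off
                else:
                    hi = mid_off
            poly = _hexagon(c + 0.5 * (lo + hi) * u, params.polygon_radius)
        cid = f"{section.spec.section_id}_rescue_extra{j:03d}"
        resc_ids.append(cid)
        resc_polys.append(poly)
        requested[cid] = f

    primary = SegmentationSet(prim_ids, prim_polys, source="primary")
    rescue = SegmentationSet(resc_ids, resc_polys, source="rescue")

    # realized overlap fractions against the primary union, by exact clipping
    tree = shapely.STRtree(prim_polys)
    rows = []
    for cid, poly in zip(resc_ids, resc_polys):
        cand = tree.query(poly, predicate="intersects")
        inter = 0.0
        if len(cand):
            inter = poly.intersection(
                shapely.union_all([prim_polys[i] for i in cand])
            ).area
        rows.append(
            {
                "cell_id": cid,
                "requested_fraction": requested.get(cid, np.nan),
                "actual_fraction": inter / poly.area,
            }
        )
    overlap_truth = pd.DataFrame(rows)

    # scatter each cell's transcripts inside its polygon (or a soma-sized
    # hexagon around the centroid when neither segmenter produced one)
    poly_by_id = dict(zip(prim_ids, prim_polys)) | dict(zip(resc_ids, resc_polys))
    totals = np.asarray(section.counts.sum(axis=1)).ravel().astype(int)
    gene_arr = np.asarray(section.genes.names, dtype=object)
    spot_genes: list[np.ndarray] = []
    spot_xy: list[np.ndarray] = []
    spot_cell: list[np.ndarray] = []
    csr = section.counts.tocsr()
    for i, cid in enumerate(cells["cell_id"]):
        n_i = totals[i]
        if n_i == 0:
            continue
        poly = poly_by_id.get(cid) or _hexagon(xy[i], params.polygon_radius)
        pts = _scatter_in_polygon(poly, n_i, rng)
        row = csr.getrow(i)
        g = np.repeat(gene_arr[row.indices], row.data)
        spot_genes.append(g)
        spot_xy.append(pts)
        spot_cell.append(np.repeat(cid, n_i))
    spots = pd.DataFrame(
        {
            "gene": np.concatenate(spot_genes),
            "x": np.concatenate(spot_xy)[:, 0],
            "y": np.concatenate(spot_xy)[:, 1],
            "true_cell": np.concatenate(spot_cell),
        }
    )

    all_ids = prim_ids + resc_ids
    dapi_vals = rng.normal(params.dapi_mean, params.dapi_sd, len(all_ids))
    dim = rng.random(len(all_ids)) < params.dapi_low_fraction
    dapi_vals[dim] = rng.normal(40.0, 10.0, dim.sum())
    dapi = pd.Series(np.clip(dapi_vals, 0, None), index=all_ids, name="dapi_mean")
    return SegmentationFixture(
        primary=primary,
        rescue=rescue,
        spots=spots,
        dapi=dapi,
        overlap_truth=overlap_truth,
    )
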