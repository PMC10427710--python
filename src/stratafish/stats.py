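"""Laminar-position summaries, displacement testing, and regional composition.

The displacement test asks whether an amacrine subtype sits in the ganglion
cell layer (GCL) more often than chance, given how many amacrine cells of
each section are in the GCL at all.  The null is built by shuffling subtype
labels among amacrine cells *within each section* (layer labels fixed),
which preserves per-section subtype multisets and global layer counts; the
p-value is the fraction of permutations whose GCL proportion strictly
exceeds the observed one.  A subtype is called displaced at p < 0.05 when it
has at least ``min_cells`` cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .boundaries import BoundaryChains

__all__ = [
    "DisplacementResult",
    "assign_layer",
    "summarize_laminar_positions",
    "displacement_permutation_test",
    "assign_quadrants",
    "compare_regional_composition",
]


def assign_layer(
    cells: pd.DataFrame,
    inl_chains: BoundaryChains,
    outside_margin: float = np.inf,
) -> pd.Series:
    """Layer label (INL or GCL) per cell from the INL boundary geometry.

    A cell on the INL side of the basal INL chain — radially outward of it
    with respect to the tissue center — is INL; otherwise GCL.  The chain
    passes through INL cell centroids, so cells lying exactly on it count as
    INL (a small radial tolerance absorbs float error).  Cells radially
    farther than ``outside_margin`` beyond the apical INL chain are flagged
    ``"outside"``.
    """
    if not inl_chains.basal:
        raise ValueError("INL basal chain is missing")
    center = inl_chains.tissue_center
    pts = cells[["x", "y"]].to_numpy(dtype=float)
    r_cell = np.linalg.norm(pts - center, axis=1)

    basal = inl_chains.as_multilinestring("basal")
    geoms = shapely.points(pts)
    lines = shapely.shortest_line(basal, geoms)
    nearest = shapely.get_coordinates(lines)[::2]  # first point of each line is on the chain
    r_basal = np.linalg.norm(nearest - center, axis=1)
    tol = 1e-6 * max(1.0, float(np.abs(r_basal).max()))
    labels = np.where(r_cell >= r_basal - tol, "INL", "GCL").astype(object)

    if np.isfinite(outside_margin) and inl_chains.apical:
        apical = inl_chains.as_multilinestring("apical")
        lines_a = shapely.shortest_line(apical, geoms)
        nearest_a = shapely.get_coordinates(lines_a)[::2]
        r_apical = np.linalg.norm(nearest_a - center, axis=1)
        labels[r_cell > r_apical + outside_margin] = "outside"
    return pd.Series(labels, index=cells.index, name="layer")


def summarize_laminar_positions(
    depths: pd.DataFrame,
    subtypes: pd.Series,
    sections: pd.Series | None = None,
    min_cells: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subtype depth quantiles and pairwise position tests.

    Box statistics follow the 1.5*IQR whisker convention.  Pairwise
    two-sided t-tests are run on per-section mean depths (each section is
    one observation) and Benjamini-Hochberg adjusted.  Subtypes with fewer
    than ``min_cells`` cells are excluded and reported with NaN statistics.
    """
    df = depths.copy()
    df["subtype"] = np.asarray(subtypes)
    df["section"] = "S0" if sections is None else np.asarray(sections)
    df = df.dropna(subset=["depth_ratio"])

    rows = []
    kept: list[str] = []
    for name, grp in df.groupby("subtype", sort=True):
        v = grp["depth_ratio"].to_numpy()
        if len(v) < min_cells:
            rows.append({"subtype": name, "n": len(v), "median": np.nan,
                         "q1": np.nan, "q3": np.nan, "lo_whisker": np.nan,
                         "hi_whisker": np.nan, "excluded": True})
            continue
        kept.append(name)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        rows.append({"subtype": name, "n": len(v), "median": med, "q1": q1,
                     "q3": q3, "lo_whisker": lo, "hi_whisker": hi,
                     "excluded": False})
    summary = pd.DataFrame(rows)

    if len(kept) < 2:
        raise ValueError("need at least two subtypes with enough cells")
    sec_means = (
        df[df["subtype"].isin(kept)]
        .groupby(["subtype", "section"])["depth_ratio"]
        .mean()
    )
    pair_rows = []
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            va = sec_means.loc[a].to_numpy()
            vb = sec_means.loc[b].to_numpy()
            if np.allclose(va.mean(), vb.mean()) and np.allclose(
                np.concatenate([va, vb]).std(), 0
            ):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(va, vb)
            pair_rows.append({"subtype_a": a, "subtype_b": b,
                              "t_statistic": float(t), "p_value": float(p)})
    pairwise = pd.DataFrame(pair_rows)
    if len(pairwise):
        pairwise["p_adjusted"] = multipletests(
            pairwise["p_value"], method="fdr_bh"
        )[1]
    return summary, pairwise


@dataclass
class DisplacementResult:
    """Per-subtype displacement call against the within-section shuffle null."""

    subtype: str
    n_inl: int
    n_gcl: int
    observed_prop: float
    null_props: np.ndarray
    p_value: float
    significant: bool

    def to_row(self) -> dict:
        return {
            "subtype": self.subtype,
            "n_inl": self.n_inl,
            "n_gcl": self.n_gcl,
            "observed_prop": self.observed_prop,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def displacement_permutation_test(
    ac_cells: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_cells: int = 10,
    seed: int = 0,
    estimator: str = "plain",
) -> list[DisplacementResult]:
    """Within-section label-permutation test for preferential displacement.

    ``ac_cells`` needs columns ``section``, ``subtype``, ``layer`` (INL or
    GCL) over amacrine cells only.  Subtype labels are shuffled within each
    section independently, ``n_perm`` times; per subtype,
    ``p = #{perm : null GCL proportion > observed} / n_perm`` (strictly
    greater).  ``estimator="conservative"`` uses ``(#greater + 1) /
    (n_perm + 1)`` instead, which cannot return 0.  A subtype is significant
    iff ``p < alpha`` and it has at least ``min_cells`` cells.

    A uniform shuffle of the labels within a section makes the vector of
    per-subtype GCL counts exactly multivariate hypergeometric (colors = the
    section's subtype totals, draws = its GCL cell count), so the null is
    sampled directly from that law — identical in distribution to
    materializing each permutation, at a fraction of the cost.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if estimator not in ("plain", "conservative"):
        raise ValueError("estimator must be 'plain' or 'conservative'")
    for col in ("section", "subtype", "layer"):
        if col not in ac_cells.columns:
            raise ValueError(f"ac_cells missing column {col!r}")
    layers = set(ac_cells["layer"].unique())
    if not layers <= {"INL", "GCL"}:
        raise ValueError(f"unknown layer labels: {sorted(layers - {'INL', 'GCL'})}")

    rng = np.random.default_rng(seed)
    subs = np.asarray(sorted(ac_cells["subtype"].unique()))
    sub_code = {s: i for i, s in enumerate(subs)}
    codes = ac_cells["subtype"].map(sub_code).to_numpy()
    in_gcl = (ac_cells["layer"] == "GCL").to_numpy()
    section = ac_cells["section"].to_numpy()

    total = np.bincount(codes, minlength=len(subs))
    obs_gcl = np.bincount(codes[in_gcl], minlength=len(subs))
    null_gcl = np.zeros((n_perm, len(subs)), dtype=np.int64)
    for sec in pd.unique(section):
        sel = section == sec
        colors = np.bincount(codes[sel], minlength=len(subs))
        n_gcl_sec = int(in_gcl[sel].sum())
        if n_gcl_sec == 0:
            continue
        null_gcl += rng.multivariate_hypergeometric(
            colors, n_gcl_sec, size=n_perm
        )

    results: list[DisplacementResult] = []
    for s_i, name in enumerate(subs):
        n_tot = int(total[s_i])
        n_gcl = int(obs_gcl[s_i])
        obs_prop = n_gcl / n_tot if n_tot else np.nan
        null_props = null_gcl[:, s_i] / n_tot if n_tot else np.full(n_perm, np.nan)
        # permutations preserve per-subtype totals, so comparing proportions
        # equals comparing integer GCL counts: exact, no float ties
        greater = int((null_gcl[:, s_i] > n_gcl).sum())
        if estimator == "plain":
            p = greater / n_perm
        else:
            p = (greater + 1) / (n_perm + 1)
        results.append(
            DisplacementResult(
                subtype=str(name),
                n_inl=n_tot - n_gcl,
                n_gcl=n_gcl,
                observed_prop=obs_prop,
                null_props=null_props,
                p_value=p,
                significant=bool(p < alpha and n_tot >= min_cells),
            )
        )
    return results


def assign_quadrants(
    cells: pd.DataFrame,
    orientation: str,
    rotation: float = 0.0,
    left_region: str | None = None,
) -> pd.Series:
    """Region label per cell: rotate the section upright, split at the x
    midpoint, and map the left/right halves to anatomical regions.

    ``left_region`` must be stated explicitly (one of the orientation's two
    regions); the left/right-to-anatomy mapping is unrecoverable from
    coordinates alone and is never guessed.  ``rotation`` is the angle (rad)
    that brings the section to its recorded upright pose (posterior at top).
    """
    pairs = {"dorsal-ventral": ("dorsal", "ventral"),
             "temporal-nasal": ("temporal", "nasal")}
    if orientation not in pairs:
        raise ValueError(f"orientation must be one of {sorted(pairs)}")
    if left_region is None:
        raise ValueError("left_region metadata is required and never guessed")
    a, b = pairs[orientation]
    if left_region not in (a, b):
        raise ValueError(f"left_region {left_region!r} not in {pairs[orientation]}")
    right_region = b if left_region == a else a
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    c, s = np.cos(-rotation), np.sin(-rotation)
    x_rot = xy[:, 0] * c - xy[:, 1] * s
    mid = 0.5 * (x_rot.min() + x_rot.max())
    labels = np.where(x_rot < mid, left_region, right_region)
    return pd.Series(labels, index=cells.index, name="region")


def compare_regional_composition(
    sections: list[pd.DataFrame],
    unit: str = "subtype",
    normalization: str = "all",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-region composition comparison across sections.

    Each section DataFrame needs ``region`` plus ``subtype``/``major_type``
    columns.  Per section and region the proportion of each unit is computed
    under the chosen normalization (``"all"``: of all cells;
    ``"within_major"``: within the unit's major type), then the two regions
    are compared per unit with a two-sided two-sample t-test across sections.
    Units absent from every section are reported untested.
    """
    if unit not in ("subtype", "major_type"):
        raise ValueError("unit must be 'subtype' or 'major_type'")
    if normalization not in ("all", "within_major"):
        raise ValueError("normalization must be 'all' or 'within_major'")
    if normalization == "within_major" and unit == "major_type":
        raise ValueError("within_major normalization applies to subtypes")
    regions = sorted({r for df in sections for r in df["region"].unique()})
    if len(regions) != 2:
        raise ValueError(f"expected exactly two regions, got {regions}")
    for reg in regions:
        n_secs = sum((df["region"] == reg).any() for df in sections)
        if n_secs < 2:
            raise ValueError(f"need at least 2 sections covering region {reg!r}")

    units = sorted({u for df in sections for u in df[unit].unique()})
    props: dict[str, dict[str, list[float]]] = {
        u: {r: [] for r in regions} for u in units
    }
    for df in sections:
        for reg in regions:
            sub = df[df["region"] == reg]
            if len(sub) == 0:
                continue
            for u in units:
                in_u = sub[unit] == u
                if normalization == "all":
                    denom = len(sub)
                else:
                    major = df.loc[df[unit] == u, "major_type"]
                    if len(major) == 0:
                        continue
                    denom = int((sub["major_type"] == major.iloc[0]).sum())
                if denom == 0:
                    continue
                props[u][reg].append(float(in_u.sum()) / denom)
    rows = []
    for u in units:
        va = np.array(props[u][regions[0]])
        vb = np.array(props[u][regions[1]])
        if len(va) < 2 or len(vb) < 2:
            rows.append({"unit": u, "region_a": regions[0], "region_b": regions[1],
                         "mean_a": np.nan, "mean_b": np.nan, "t_statistic": np.nan,
                         "p_value": np.nan, "significant": False, "tested": False})
            continue
        if np.concatenate([va, vb]).std() == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(va, vb)
        rows.append({"unit": u, "region_a": regions[0], "region_b": regions[1],
                     "mean_a": va.mean(), "mean_b": vb.mean(),
                     "t_statistic": float(t), "p_value": float(p),
                     "significant": bool(p < alpha), "tested": True})
    out = pd.DataFrame(rows)
    out.attrs["normalization"] = normalization
    return out
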