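# stratafish

Laminar geometry and integration statistics for imaging spatial
transcriptomics of layered neural tissue.

Imaging spatial transcriptomics (e.g. MERFISH) measures a targeted gene
panel per cell in intact tissue. In a layered tissue like the retina —
three soma layers (ONL, INL, GCL, apical to basal) separated by cell-free
plexiform layers — turning those measurements into biology requires a chain
of spatial computations that generic single-cell tools do not provide.
stratafish implements that chain as a tested, reusable pipeline for
computational biologists working with sectioned layered tissue:

- **Dual-segmentation fusion + QC** — keep all polygons from a primary
  segmenter, rescue polygons from a second segmenter only when their
  overlap with the primary set is strictly below 0.1% of their own area;
  assign transcript spots to cells (containment first, then certified
  nearest-boundary via a k-d tree); filter cells on five metrics (DAPI,
  minimum-enclosing-circle radius, area, perimeter, transcript total).
- **Alpha-shape layer boundaries** — a point is *alpha-extreme* if an open
  ball of radius α (default 100 µm) touches it without covering any other
  point; boundary edges join extreme pairs with an empty witness ball.
  Edges split into apical/basal chains by whether the witness ball lies
  radially outward or inward of a fitted tissue center; normalized laminar
  depth is d_apical / (d_apical + d_basal) ∈ [0, 1].
- **Displacement statistics** — per amacrine subtype, the fraction of
  cells in the GCL, tested against a within-section label-permutation null
  (1000 permutations, p = fraction of null draws strictly greater,
  significant at p < 0.05); plus per-subtype laminar position summaries
  with pairwise t-tests, and quadrant (dorsal/ventral, temporal/nasal)
  composition comparisons.
- **Reference integration** — transfer subtype labels from a dissociated
  reference through a shared latent space (linear SVM on reference latents,
  k = 3 neighbor-averaged query features) and impute full-transcriptome
  expression per cell as a convex combination of *same-type* reference
  cells (Gaussian-kernel weights, or simplex-constrained weights optimized
  for panel-gene Pearson correlation).
- **Synthetic tissue generator** — arc-shaped sections with known
  per-cell ground truth (layer, subtype, depth, region), marker-structured
  Poisson counts at ~80 transcripts/cell, paired reference data sharing
  per-subtype latents, and two-segmenter polygon fixtures with controlled
  overlaps; every downstream claim is validated against this truth.

See `docs/methods.md` for the models, defaults, and design decisions.

## Worked example

Run the full pipeline on one synthetic section (~17k cells, 400-gene
universe) and read off the displacement analysis:

```python
from stratafish import PipelineConfig, run_pipeline
import pandas as pd

cfg = PipelineConfig(seed=1, out_dir="run1")
manifest = run_pipeline(cfg)
disp = pd.read_csv("run1/displacement.csv")
print(disp[["subtype", "observed_prop", "p_value", "significant"]]
      .sort_values("observed_prop", ascending=False).head(4).to_string(index=False))
```

```
subtype  observed_prop  p_value  significant
    AC3       0.814159    0.000         True
    AC2       0.508929    0.000         True
    AC1       0.220339    0.044         True
    AC8       0.080808    0.997        False
```

The generator seeded AC1/AC2/AC3 with displacement ratios 0.2/0.5/0.8 over
a 0.05 background: the three seeded subtypes are recovered as significantly
displaced with estimated ratios near truth, and background subtypes are
not. `run1/` also contains the merged segmentation (GeoJSON), QC survivors,
boundary chains, per-cell depth records, transfer assignments, per-gene
imputation correlations (`S1.imputation_summary.json` reports a median
panel-gene Pearson correlation of 0.80 on this run), regional
compositions, and a `manifest.json` whose checksums are identical across
reruns with the same seed.

The same stages are available from the shell:

```sh
stratafish run --config config.yaml
stratafish segment-merge --primary A.geojson --rescue B.geojson \
    --spots spots.csv --overlap-threshold 0.001 --out merged/
stratafish displacement --cells ac_cells.csv --n-perm 1000 --seed 1 --out disp.csv
```

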