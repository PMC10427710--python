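# Methods

stratafish analyzes imaging spatial transcriptomics of layered neural
tissue — concretely, MERFISH cross-sections of the mouse retina, where cell
somata occupy three nuclear layers (outer nuclear layer ONL, inner nuclear
layer INL, ganglion cell layer GCL, apical to basal) separated by cell-free
plexiform layers.  This note describes each model and procedure, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was open.

## Segmentation fusion and QC

Two segmenters cover complementary regions: a primary one reliable in the
nuclear layers and a rescue one that recovers cells elsewhere but
over-splits.  A rescue polygon is kept iff its overlap with the union of
primary polygons is **strictly below 0.1%** (`overlap_threshold = 0.001`) of
its own area.  The normalizing denominator is a choice — the source method
states only "<0.1% area" — and we divide by the rescue polygon's area
because the rule decides that polygon's fate; `denominator="primary"` is
available.  Overlap areas are exact polygon clipping (GEOS via shapely).

Transcript spots are assigned to the containing polygon when one exists
(ties to the lexicographically smallest cell id), else to the polygon with
minimum boundary distance.  Candidates come from a k-d tree over polygon
centroids; the pool (default 10) doubles until the best candidate's boundary
distance is provably minimal: any excluded polygon's boundary distance is at
least its centroid distance minus the global maximum centroid-to-vertex
radius.  There is no distance cap by default; `max_distance` exists as a
flag.  Whether the original pipeline built its k-d tree over vertices or
centroids is unstated; the centroid-plus-certificate scheme is our choice,
and a brute-force scan over all polygons arbitrates correctness in tests.

Cell QC is the conjunction of five inclusive interval tests: mean DAPI
intensity ≥ 80, minimum-enclosing-circle radius in [10, 80], polygon area in
[500, 10 000], perimeter in [50, 400], total transcripts ≥ 10.  These
defaults are in the source units (pixel-scale imaging); all bounds are
configurable, and the synthetic pipeline overrides them to its µm scale
(radius [1, 20] µm, area [5, 2000] µm², perimeter [5, 200] µm) since its
polygons are soma-sized hexagons.  The minimum enclosing circle is exact
(`shapely.minimum_bounding_circle`); degenerate one- and two-point inputs
return radius 0 and half the separation.

## Alpha-shape boundary geometry

A point is *alpha-extreme* when an open ball of radius α exists with the
point on its boundary covering no other point.  The candidate ball centers
for point *p* form the circle of radius α around *p*; each neighbor *q* at
distance d < 2α excludes an open arc of half-width arccos(d/2α).  *p* is
extreme iff the union of excluded arcs (split at the 0/2π seam and merged)
leaves a gap.  This test is exact; a k-d tree merely restricts the arc set
to neighbors within 2α.  Edges join extreme pairs admitting an empty
*witness* ball of radius α through both endpoints; both candidate centers
are tested against the point set, and the largest connected component of the
edge graph that contains a cycle is retained as the closed tissue boundary.
Strict open-ball inequalities carry a 1e−9 relative slack so points exactly
on a witness boundary (co-circular constructions) never count as covered.

**α default: 100 µm**, the value that traces a tight boundary at the tissue
scale this package targets (sections with ~mm curvature radius and cell
spacing well under 100 µm).  α must exceed the typical cell spacing for a
closed chain to exist, and must stay below the *basal curvature radius*: an
empty ball of radius α cannot be tangent inside a concave hole of radius
r < α without swallowing the rim, so a basal boundary of curvature radius
below α is invisible at that α.  Fixtures in this package use annular bands
at 900–1100 µm radius for exactly this reason.

**Tissue center.** The apical/basal split needs a hypothetical center of
curvature.  A Kåsa algebraic circle fit seeds a geometric least-squares
refinement (Levenberg–Marquardt on radial residuals).  The algebraic fit
alone collapses the radius for short arcs of thick bands (errors up to
hundreds of µm at spans below ~1 rad), which flips the radial rule; the
geometric fit stays within a few percent of the band radius on the spans the
pipeline sees.  For full annuli both agree.  Collinear input falls back to
the centroid with a warning.  Note that for a thick band over a short arc
even the geometric optimum is biased by design (a repositioned circle can
reduce radial variance); the bias is small relative to the band radius and
sign-preserving for the classification rule.

**Classification.** An edge is apical when its empty witness center lies
radially farther from the tissue center than the edge midpoint, basal when
nearer — the witness ball sits on the empty side of the boundary.  Edges in
the extreme `lateral_fraction` (default 2.5%) angular tails at each end of
the section are labeled lateral (cut ends, where the radial rule is
meaningless).  A single majority-smoothing pass relabels isolated edges
disagreeing with both chain neighbors; this automates what was interactive
curation in the original workflow.  Arc geometry (witness centers) drives
classification; straight segments drive distances — matching the method's
own split.

**Depth.** A cell's distance to a chain is the exact minimum over segments
of point-to-segment distance.  Normalized laminar depth is
d_apical / (d_apical + d_basal), 0 at the apical boundary under the default
convention.  The verbal definition of the ratio's direction in the source is
ambiguous; apical-referenced is the default because the headline laminar
statements (e.g. rod bipolar somata in the top 20% of the INL) read
naturally in it, and `apical_reference=False` flips the convention.  Both
raw distances are always stored so either reading is recoverable.  Cells
with both distances zero get NaN and a flag.

**Two-pass INL boundary (pipeline).** The basal-most INL somata are
amacrine, yet amacrines are the very population whose layer membership the
displacement analysis must decide — anchoring the boundary on them naively
is circular.  Pass 1 anchors the alpha-shape on non-displaceable INL
residents (bipolar, horizontal, Müller cells); because these undersample the
basal fringe, the pass-1 basal chain sits a few µm apical of the band edge.
Pass 2 re-anchors after adding amacrines within `fringe_margin` (default
15 µm ≈ half the inner plexiform gap) below the provisional chain; truly
displaced amacrines lie a full plexiform gap lower and never enter the
anchor set.  Cells exactly on the final chain count as INL (the chain passes
through INL cell centroids).

## Displacement statistics

For each amacrine subtype the observed displacement ratio is the fraction of
its cells in the GCL.  The null hypothesis is exchangeability of subtype
labels given each section's layer composition: labels are shuffled within
each section independently, 1000 times, and
p = #{permutations with strictly greater GCL proportion} / n_perm.
A subtype is significantly displaced at p < 0.05 with at least `min_cells`
(default 10) cells; the guard exists because subtypes as rare as a few cells
cannot be tested stably.  A conservative `(k+1)/(n_perm+1)` estimator is
exposed because the plain one can return 0.  Implementation detail: a
uniform within-section shuffle makes the per-subtype GCL count vector
exactly multivariate hypergeometric (colors = subtype totals, draws = GCL
count), so the null is sampled directly from that law — identical in
distribution and far faster than materializing permutations; the
single-section case is cross-checked against the closed-form hypergeometric
tail in tests.  Because permutations preserve per-subtype totals, comparing
proportions is integer count comparison: exact, with no float ties.

Two properties of the strictly-greater formula matter for interpretation:
it is anti-conservative by the probability mass of ties
P(null = observed), and its p-values are discrete.  Both effects scale with
the count resolution; calibration checks therefore use fixtures with
~10³ cells per subtype so proportions are quasi-continuous, and a KS
uniformity check uses one p-value per replicate (p-values within a
replicate are dependent).  At those sizes the empirical type-I error at 0.05
sits near 0.05 and p-values are indistinguishable from uniform.

Laminar position summaries report median, quartiles, and 1.5×IQR whiskers
per subtype; pairwise position differences use two-sided t-tests on
per-section mean depths (the section is the independent unit),
Benjamini–Hochberg adjusted — the source is silent on multiplicity and BH
is our choice.

Quadrant analysis rotates each section to its recorded upright pose, splits
at the midpoint of the x-range, and maps left/right to anatomy
(dorsal/ventral or temporal/nasal) from **explicit metadata only** — the
mapping is unrecoverable from coordinates and is never guessed.  Regional
composition per unit is compared across sections by a two-sided two-sample
t-test on per-section proportions, normalized either by all cells or within
the unit's major type.

## Label transfer and imputation

The co-embedding that places spatial and reference cells in a shared
d = 15 latent space is an *input* (the synthetic generator supplies shared
latents); computing it is out of scope.  Major types of spatial cells are
scored per cell as the mean over a marker set of library-size-normalized,
per-gene z-scored expression, argmax over types, ties and empty cells
"unassigned".

Subtype labels transfer through a multi-class maximum-margin classifier
(linear-kernel SVM with pairwise-coupling probability calibration,
seed-fixed) trained on reference latents; the kernel and calibration scheme
are unstated in the source and are our choice, validated by synthetic
recovery only.  Each query cell's feature is the mean latent of its k = 3
nearest reference cells; assignment takes the maximum class probability.

Expression imputation is restricted to reference cells **of the same cell
type** — the restriction is absolute: weights never cross it, which is
audited on every run.  Per query cell the candidates are its k = 30 nearest
same-type reference cells (k is our default; the source states none).
`kernel` mode (default) weights candidates by a Gaussian kernel on latent
distance with bandwidth equal to that cell's median candidate distance,
normalized to sum 1.  `fit` mode replaces the original global
mapping-probability optimizer with a desk-scale scheme: weights are
parameterized on the simplex (softmax), initialized at the kernel solution,
and updated by projected gradient ascent (analytic gradient) on the mean
per-gene Pearson correlation between imputed and measured panel genes, with
an iteration cap (60) and relative tolerance (1e−6); the best iterate is
kept, so fit never scores below kernel.  Fidelity is the per-gene Pearson
correlation across cells on shared genes; zero-variance genes are reported
as undefined and excluded from summaries.

## Synthetic tissue generator

The generator is the package's ground-truth instrument, not a fixture: an
arc-shaped band (default center of curvature at the origin, GCL 790–840 µm,
INL 870–940 µm, ONL 945–1045 µm, span 1.8 rad around the vertical — the
gaps are the cell-free plexiform layers) with per-layer densities (GCL
0.012, INL 0.035, ONL 0.07 cells/µm², ~17k cells/section, cell spacing
~4–10 µm as for ~7 µm somata).  Within a layer, angle is uniform and radius
follows the subtype's Beta(a, b) law on normalized depth (0 = apical);
Beta is our stand-in family — bounded, two parameters reproduce apical and
basal skew — not an inference about real depth profiles.  Amacrine cells
move to the GCL band with their subtype's displacement probability; the
default roster has 12 amacrine subtypes, three displaced at 0.2 / 0.5 / 0.8
over a 0.05 background, mirroring the regime the displacement test must
resolve.  The rod-bipolar subtype carries a ventral abundance multiplier
(35% → 30% of bipolar cells) to seed the quadrant asymmetry.

Counts are Poisson around the subtype's profile scaled to 80 transcripts
per cell (the measured scale of the data this emulates); a 400-gene
universe contains a 200-gene imaging panel.  Profiles are marker-structured:
five disjoint marker genes per major type (strongly expressed in the own
type, silent elsewhere), and every other gene "on" (~marker-like, ×150
fold) in a small random subset of subtypes (3% each, at least one
somewhere).  This emulates a panel of cell-type-informative genes and gives
held-out genes enough between-subtype variance to make imputation recovery
measurable above Poisson noise at 80 counts/cell; flat housekeeping-like
genes are deliberately not represented, so recovery numbers speak to
informative genes only.  Latents for sections and reference are drawn from
the same per-subtype Gaussians (sd 1, means rejection-sampled to ≥ 6 sd
pairwise separation) — emulating a *successful* co-embedding; nothing here
validates co-embedding quality on real data.  The reference draws 1000
counts/cell over the full universe.

The segmentation fixture builds soma-sized hexagons (circumradius 3.2 µm)
over ONL+INL cells (primary) and GCL cells (rescue), scatters each cell's
transcripts uniformly inside its polygon (spot totals equal the count
matrix exactly), draws DAPI intensities (N(150, 25²) with a 3% dim
fraction so the QC filter bites), and can place extra rescue polygons at
requested overlap fractions, found by bisection against the primary union
along an outward radial from a rim polygon — the recorded fraction is the
realized clipping fraction.

What passing tests on this generator do **not** show: robustness to
segmentation errors beyond polygon overlap, to co-embedding failure, to
overdispersed counts (Poisson only by default), to 3D effects (z is
collapsed; the analysis is 2D), or to depth laws outside the Beta family.

## Problem sizes and determinism

Validation runs use: 200 random instances (n ≤ 60) for geometry-oracle
equivalence; a 2000-cell annulus (band 900–1100 µm, α 100 µm) for boundary
and depth recovery; 500 null replicates × 1000 permutations for
calibration; 12 pooled sections (~1900 cells per amacrine subtype) for
displacement recovery — the 0.2-over-pooled-null signal needs roughly 2000
cells per subtype for reliable detection, since the permutation null
centers on the *overall* GCL share (~0.16 with the seeded roster), not the
0.05 background; 5000 reference / 2000 query cells for transfer; one
full-scale section for the end-to-end run, with determinism verified by
re-running a reduced-density configuration and comparing manifest
checksums.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical outputs, and
the run manifest records a config hash and SHA-256 checksums per output.

## Known limitations

- The alpha-shape basal boundary requires α below the basal curvature
  radius; no diagnostic currently warns when α is too large for the
  tissue's curvature (the shape simply loses its inner chain and the run
  fails with a no-closed-component error or misclassified edges).
- The strictly-greater permutation p-value can return 0 and is mildly
  anti-conservative at small subtype counts; the conservative estimator is
  available but the count-discreteness itself is irreducible.
- The quadrant split at the empirical x-midpoint drifts by a few µm from
  the geometric midline with finite sampling; cells within ~10 µm of the
  midline are effectively unassignable.
- `fit`-mode imputation optimizes a non-convex objective; it is guaranteed
  not to fall below its kernel start but not to reach a global optimum.
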