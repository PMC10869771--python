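# Methods

This note documents the models and procedures implemented in `spatialniche`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter for
reproducibility.

## Data model and QC

The unit of input is segmenter output: a per-molecule table (x, y in μm,
gene, assigned `cell_id`, optional molecule-cluster label and confidence in
[0, 1]) and a per-cell statistics table (centroid, transcript count, area in
μm², elongation ≥ 1, mean segmentation confidence). `cell_id = 0` is the
reserved noise/unassigned id, following the common segmenter convention; all
operations ignore noise molecules except where "unassigned" is itself the
quantity of interest. Coordinates are continuous positions in μm — there is
no pixel grid and no 0/1-based ambiguity (only grid tiles and spot ids are
indexed, both from 1).

QC retains a cell iff its transcript count **strictly exceeds**
`min_transcripts` (default 5, configurable). The area, elongation and
confidence gates exist but are off by default: segmentation statistics vary
enough across segmenters and tissues that no universal numeric default is
defensible, so they are opt-in and recorded in the filter report when used.
The filter never alters retained cells' fields; the count matrix and
molecule table are subset consistently, and the report carries
`n_in = n_retained + n_removed` plus per-gate removal counts (a cell failing
several gates is counted once per gate it fails).

Cell typing takes the modal molecule-cluster label among a cell's assigned
molecules. Ties are broken by lexicographic order of the label strings:
deterministic, seed-free, and order-independent. Cells with zero labeled
molecules get the sentinel `"unlabeled"` rather than being dropped.

## Organ coordinates

The tissue boundary is estimated as an alpha shape: Delaunay triangles with
circumradius ≤ α are kept and the union's outer ring is the boundary. α is a
length scale; α = ∞ recovers the convex hull. The default α is 3× the median
nearest-neighbour spacing of the input points — scale-adaptive, and loose
enough that ≥ 99% of points fall inside on realistic densities. Holes and
multi-lobed tissues are out of scope: only the largest outer ring is kept.

The organ frame is the boundary plus a user-chosen origin strictly inside it
(for kidney sections: a centre point in the papilla). A helper suggests the
centroid of a named cell type, but nothing is picked silently. Each point p
is then assigned

- **depth** = |p − b| / |o − b| where b is the *first intersection of the
  origin→p ray* with the boundary — 0 at the capsule, 1 at the origin;
- **angle** = atan2 of p − o, in (−π, π].

The ray-intersection convention (rather than nearest-boundary-point
distance) makes the numerator and the normalising denominator refer to the
same boundary point, which guarantees depth ∈ [0, 1] and makes depth
invariant under rigid motions and strictly decreasing along any ray from the
origin. A nearest-point variant of the boundary distance would differ on
eccentric geometries; the ray convention is the one implemented and tested.
Conventions for degenerate inputs: p = origin → depth 1, angle 0; points
outside the boundary are clamped to depth 0, flagged in the output, and
counted in a warning.

Boundaries known analytically can be given as a `Circle`, in which case the
ray intersection is solved in closed form (one quadratic per point) and
depth is exact to machine precision; polygonal boundaries go through
ray-segment intersection and inherit the polygon's resolution. Depth
profiles bin depth into equal-width bins over [0, 1] (last bin closed);
within-bin category proportions sum to 1, and empty bins are reported as
zero counts with NaN proportions rather than propagating NaN.

## Proximity statistics

Nearest-distance distributions and density profiles are cell-centric: for
each reference-type cell, the distance to the nearest target-type cell (self
excluded when the types coincide), or the count / areal density (count/πr²)
/ composition fraction of target cells at increasing radii. A k-NN scale
mode reports the target-type fraction among the k nearest cells, for
readouts expressed in "numbers of cells" rather than μm. Neighbour queries
use a k-d tree but are contractually identical to brute force — the test
suite checks exact agreement with O(n²) oracles.

Pair enrichment at radius r (default 50 μm): observed probability of an
unordered type pair = (# unordered cell pairs of that type pair with
distance ≤ r) / (# all unordered cell pairs with distance ≤ r), self-pairs
excluded. The null permutes the observed labels over the fixed positions
(default 1000 permutations, explicit seed); enrichment = observed/null-mean,
z = (obs − null mean)/null sd, and p = (1 + #{null ≥ obs})/(1 + N) with
additive smoothing, so the smallest attainable p is 1/(N+1). No edge
correction is applied: the null shares the geometry, so boundary effects
cancel in the ratio. Same-type pairs for types with fewer than 2 cells are
flagged `insufficient_cells` instead of producing spurious statistics.

One behaviour worth knowing: because the null shuffles labels globally, any
*zonal* colocalization (two types sharing a compartment) also registers as
enrichment, on top of true cell-to-cell niches. That is a property of the
statistic, not a bug; fixtures that isolate niche effects (planted doublets
on a background) are provided for testing the niche signal alone.

The rank-sum (Mann–Whitney) test enumerates the exact null distribution of
U over all assignments of the pooled values when n₁ + n₂ ≤ 20, with ties
half-counted — identical samples therefore give a two-sided p of exactly 1.
Larger samples use the normal approximation with continuity and tie
correction (delegated to scipy, which the exact branch is also tested
against in the tie-free regime).

## Spot-grid integration

Registration is landmark-based least-squares similarity fitting
(rotation + translation + optional isotropic scale), solved by SVD of the
landmark cross-covariance (the Procrustes/Umeyama solution). Reflections are
rejected with an explicit error rather than silently accepted — mirrored
sections must be flipped deliberately. The RMS landmark residual is always
reported. Intensity- or feature-based registration and non-rigid warping are
out of scope.

Cells (or molecules) are binned to the *nearest spot centre*; by default
there is no distance cutoff, so every cell is assigned, matching the notion
that the closest spot is the spot a point "lies within". An optional
`max_distance` (a sensible choice is pitch/2) unassigns cells that fall
between spots, since a cell 200 μm from every centre does not physically sit
in any 55 μm spot. Distance ties go to the smallest spot id. Spot geometry
(square or hexagonally offset) is always taken from the positions table,
never assumed.

Measured composition is the per-spot count table of assigned cells by type,
with row-normalised proportions; empty spots are flagged and excluded from
the proportions table. Benchmarking of external deconvolution predictions
computes Pearson r in three named scopes — pooled over all (spot, type)
entries, per type across spots, per spot across types — because published
comparisons rarely state which is meant and the three can differ materially.
Type-label harmonization between modalities is an explicit two-column
mapping, never fuzzy matching; zero-variance vectors yield NaN with the
reason recorded rather than an exception.

## Synthetic tissue generator

The generator *is* the study condition for all tests. It draws cell
centroids as a homogeneous Poisson process within each type's zone — a depth
interval [d₀, d₁] mapped to the annulus of radii [R(1−d₁), R(1−d₀)] of a
circular organ of radius R — so zone membership, true depth and the organ
frame are known exactly by construction. Per-cell expression is Poisson with
type-specific per-gene means; molecule positions are uniform in a disk of
radius 6 μm around the centroid and carry the cell's type as their
molecule-cluster label; noise molecules (cell_id 0, no label) are uniform
over the organ disk at a configurable rate. Cell polygons are regular
12-gons — sufficient for format and geometry tests, not a morphology model.
Planted niches are A–B doublets at a fixed intra-pair distance, with anchors
laid out on a deterministic lattice far enough apart that the planted pair
is the only systematic proximity structure at test radii.

The demo configuration (13 cell types, 200 genes, cortex/medulla/papilla
zones at depths 0–0.35/0.35–0.7/0.7–1, a glomerular podocyte+gEC niche and
an immune C3⁺-monocyte+failed-repair-PT niche, ~1200 cells in a 1 mm-radius
disk) is qualitatively kidney-like and deliberately small; the two-zone
configuration used by the acceptance script (~1000 cells, two types with
known Poisson programs) is sized so the whole script runs in seconds. These
sizes are the package's own choice of desk-scale study conditions.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: gene–gene covariance and count overdispersion
beyond Poisson, segmentation errors (molecule misassignment between
neighbouring cells), irregular cell shapes and densities, anisotropic or
multi-lobed organs, and optical artefacts. Tests against the generator
validate the statistics' contracts and calibration, not biological effect
sizes.

All randomness flows through `numpy.random.default_rng` (PCG64) with
explicit seed plumbing and no global state; a fixed seed reproduces every
output file byte-for-byte, which is itself under test.

## Numerical conventions

- FOV grid tiles partition the bounding box half-open: a point on a shared
  edge belongs to the tile with the larger index; the outer maximum edges
  fold into the last tile. Explicit bounding-box selection is closed on all
  sides so the full-extent bbox is an identity subset.
- Count matrices are genes × cells sparse integer matrices with explicit
  gene/cell-id vectors; I/O via MatrixMarket + sidecar name files or dense
  CSV.
- Spot-assignment ties are resolved within 1e-9 μm; similarity fitting
  refuses configurations with coincident source landmarks.
- Permutation p-values are additively smoothed; enrichment of an
  empty-neighbourhood pair is 0 with p = 1, never a division error.

## Known limitations

- Depth against a polygonal boundary is limited by the polygon's vertex
  density (use `Circle` for analytic boundaries).
- The enrichment null conditions on the global label multiset only; a
  zone-stratified null would separate niche effects from compartment
  colocalization and is not implemented.
- The exact rank-sum branch enumerates C(n₁+n₂, n₁) assignments and is
  capped at combined n = 20 by default.
- Registration assumes a single similarity transform across the section;
  local distortions between adjacent sections are not modelled.
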