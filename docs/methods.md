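# Methods

## Lattice model and neighbor graph

Visium spots form a hexagonal packing: rows are spaced spacing·√3/2 apart,
spots within a row sit one spacing apart, and alternate rows are offset by
half a spacing, so each interior spot has six neighbors at exactly the
minimum center-to-center distance (100 μm on standard slides).
Spaceranger encodes this with offset array coordinates in which
`array_col` shares the parity of `array_row`; the neighbors of array
position (r, c) are the present spots at (r, c±2) and (r±1, c±1).

Two neighbor constructions are provided and are proven equivalent on
regular lattices by the test suite:

- **array** (default) — the offset-coordinate rule above. Exact on
  spaceranger exports and immune to pixel jitter in the image-registered
  coordinates.
- **euclidean** — link all center pairs within 1.05× the minimum pairwise
  distance. The tolerance absorbs floating-point and registration jitter
  while safely excluding the second hex shell at ≈1.73× the spacing. Use
  this for non-Visium or synthetic geometries without array coordinates.

Spots excluded by the histology mapping (below) are removed **before**
graph construction, so they never count among a spot's six neighbors.

## Invasion boundary

Each raw histology label must be mapped by the user to
`tumor` / `nontumor` / `exclude`; no mapping is guessed, because real
pathology annotations are multi-class (e.g. lymphoid aggregates, necrosis)
and only the analyst can binarize them. A spot is a boundary spot iff at
least 2 of its lattice neighbors are tumor **and** at least 2 are
nontumor. Only the neighbors vote: the spot's own label does not
participate. By default the rule is applied over however many neighbors a
spot actually has (an edge spot with 4 neighbors split 2/2 qualifies); an
`interior_only` switch restricts classification to spots with all six
neighbors, since the counts-over-six phrasing presupposes a full
neighborhood.

For a straight interface parallel to a lattice row axis the boundary set
is exactly the two spot rows abutting the interface: each spot in those
rows has two opposite-side neighbors (the pair in the adjacent row across
the interface), while spots one row further have none. The perpendicular
width of the zone — span of boundary centers plus one spacing, since each
spot's footprint extends half a spacing on either side — is then
√3/2·100 + 100 ≈ 186.6 μm, inside the 100–200 μm band that
histopathology conventions give for invasive fronts. This is the
calibration the acceptance script recomputes.

## Signed distance and layers

Every retained spot gets the minimum Euclidean distance from its center to
any boundary-spot center, divided by the global minimum inter-spot
distance d_min. Normalizing by d_min makes the field dimensionless and
cancels per-slide pixel scale factors, so slides can be pooled without
consulting `scalefactors_json.json`. Boundary spots are 0; tumor-side
distances are negated. Non-boundary spots necessarily satisfy
|d| ≥ 1. A slide with no boundary spot raises an explicit error rather
than emitting silent zeros.

Distances are binned into layers of width w (default 1.0 normalized unit
≈ 100 μm): layer 0 is exactly the boundary, positive d in ((k−1)w, kw]
maps to layer k, negative d in [−kw, −(k−1)w) to −k. Layer 0 of niche
profiles therefore contains the boundary spots themselves.

## Niche scores

All three scores count over the six neighbors of interior spots by
default (`interior_only=True`), because their 1–6 / 0–6 ranges presuppose
a complete neighborhood; edge spots can be included on request and are
then scored over their available neighbors.

- NS(s) = number of distinct niche labels among the neighbors of s;
  reported per niche as the mean over that niche's spots.
- AS(X) = mean over niche-X spots of their same-niche neighbor count.
- CS(A,B) = mean over niche-A spots of their niche-B neighbor count. The
  matrix is not symmetric (a rare niche embedded in a common one scores
  high toward it, not vice versa). Two exact identities follow from the
  definitions and are asserted in tests: CS(X,X) = AS(X), and for
  interior-only scoring Σ_B CS(A,B) = 6 for every A.

When profiling multiple slides, per-slide profiles are computed first and
then averaged with equal weight per slide — the slide, not the spot, is
the unit of replication; per-slide tables remain available.

## Ro/e enrichment

For a niche × region count table O, expected counts are
E[i,j] = (row_i total)(col_j total)/N — the χ² independence model, which
is all this statistic borrows from the χ² test — and Ro/e = O/E. Values
above 1 mark enrichment. All-zero rows/columns are dropped with a report;
O = 0 cells get Ro/e 0, a plain ratio. No p-values or continuity
corrections are attached, since the ratio itself is the readout.

## CNV score

Input is a genes × cells matrix of inferCNV-style residuals (the upstream
HMM/denoising is out of scope; any numeric matrix is accepted). Per cell,
values are min-max rescaled to [−1, 1] via y = 2(x−min)/(max−min) − 1 —
per-cell min/max, not global — and the score is the mean of y² over
genes, bounded in [0, 1]. The transform is invariant to positive affine
changes of a cell's values, so it is insensitive to per-cell scaling
conventions upstream. Cells with constant input carry no copy-number
signal; they score 0 and are flagged `degenerate_flag` rather than
erroring, so batches run through. An optional `standardize_first` switch
z-scores each cell across genes before rescaling, for upstream outputs
where "scaled" denotes standardization; it is off by default because the
min-max transform already absorbs per-cell affine differences and the
switch changes nothing for non-constant cells.

## Synthetic data

The generator emulates exactly the structure the metrics assume:

- **Lattice** — regular hex geometry as above; defaults 40×40 spots at
  100 μm spacing, the scale of a small Visium capture-area region.
- **Regions** — half-plane or disk predicates stand in for pathologist
  tumor/nontumor annotation. They produce clean, noise-free label
  geometry.
- **Niche fields** — i.i.d. uniform labels over k niches followed by s
  rounds of synchronous majority-of-neighbors relabeling (unique
  plurality winner adopted, ties keep the current label). Chosen over a
  Potts/MCMC sampler for determinism and speed; the one property needed —
  monotonically tunable self-clustering — holds empirically: mean AS is
  non-decreasing in s across seeds (asserted over 20 seeds).
- **Abundance columns** — amplitude·exp(−(layer−center)²/2σ²) plus
  Gaussian noise truncated at 0 (deconvolved abundances are
  non-negative). Defaults: center 0, σ = 1.5 layers, amplitude 1, noise
  sd 0.1 — a clear but noisy boundary peak of the kind immune populations
  show at invasive margins.
- **CNV matrices** — baseline cells N(1, sd) per gene; tumor cells shift
  non-overlapping segments by ±amplitude. Defaults: 200 genes, 100 cells,
  tumor fraction 0.5, amplitude 0.5 = 5× the noise sd of 0.1, segments
  covering a fifth of the genome each (one gain, one loss).

All generators are bitwise-reproducible given a seed (default 0; every
CLI command exposes `--seed`).

What the synthetic data does **not** emulate: expression counts and
library-size effects, segmentation noise in histology labels, irregular
tissue outlines, multiple disconnected interfaces, or spatial correlation
between niche labels and the boundary geometry. Passing tests therefore
demonstrate correctness of the lattice computations and score algebra on
idealized fields, not robustness to annotation error in real slides.

## Numerical choices and degenerate inputs

- Exact minimum pairwise distance via k-d tree nearest-neighbor query; no
  approximation.
- Nearest-boundary search likewise via k-d tree; ties in the nearest
  boundary spot need no tie-breaking (only the minimum matters).
- Duplicate spot centers raise a geometry error (euclidean method);
  duplicate barcodes or gene/cell ids are rejected at read time.
- Isolated spots (no neighbors): non-boundary with a warning, excluded
  from score tables with a warning.
- Empty layers are emitted as missing rows, never 0/0; zero denominator
  sums in per-niche ratios give missing values with a warning; negative
  abundances are a validation error.
- Missing values in annotation value columns: policy `drop` (default,
  rows recorded) or `zero`; labels on such rows are retained.

## Problem sizes

The test suite and acceptance script use lattices up to 40×40 spots
(1600), random sub-lattices of ≤300 spots against O(n²) brute-force
oracles, and CNV matrices up to 200×100; each suite runs in seconds.
These sizes were chosen as the smallest at which the asymptotic geometry
(interior fraction, straight-interface calibration) is clearly expressed.

## Known limitations

- One boundary set per slide: all boundary spots form a single set, and
  distances refer to the nearest of them; multiple distinct interfaces on
  one slide are not labeled separately.
- No smoothing or regularization of the boundary curve and no H&E image
  handling; the histology labels are taken as ground truth.
- Visium HD square-bin grids are out of scope (the 6-neighbor geometry is
  specific to hexagonal packing).
- CS significance is not assessed (no permutation null); scores are
  reported raw.
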