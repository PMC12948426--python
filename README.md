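# posst

**Position analysis of sequencing-based spatial transcriptomics** — a
library and CLI for quantifying tumor invasion boundaries and the spatial
organization of expression niches on 10x Visium slides, plus Ro/e
tissue-preference enrichment and per-cell CNV scoring.

## The problem

On a Visium slide, spots are packed hexagonally with 100 μm
center-to-center spacing, so every interior spot has six equidistant
neighbors. When pathologists annotate spots as tumor vs nontumor, the
histological *invasive margin* — where tumor tissue meets normal tissue —
can be located directly on this lattice, and the composition of the tissue
can be profiled as a function of distance from that margin. This is how
immune niches that concentrate at tumor boundaries (e.g. at a tumor–liver
interface) are detected and quantified.

## Core definitions

Let N(s) be the ≤6 hex neighbors of spot s.

- **Boundary (BD) spot** — s is on the invasion boundary iff N(s) contains
  ≥2 tumor spots **and** ≥2 nontumor spots. At 100 μm spacing this yields a
  boundary zone 100–200 μm wide, matching histopathological conventions for
  invasive fronts.
- **Signed distance** — d(s) = (min Euclidean distance from s to any
  boundary spot) / d_min, where d_min is the minimum inter-spot distance
  (so scale factors cancel). Negative on the tumor side, 0 on the boundary.
  Distances are binned into ~100 μm **layers** for profiling.
- **Neighborhood score** NS(s) = #distinct niche labels in N(s) ∈ {1..6}.
- **Aggregation score** AS(X) = mean over niche-X spots of the number of
  niche-X neighbors ∈ [0, 6] (self-clustering tendency).
- **Colocalization score** CS(A,B) = mean over niche-A spots of the number
  of niche-B neighbors ∈ [0, 6]; CS(X,X) = AS(X), and with interior-only
  scoring Σ_B CS(A,B) = 6.
- **Ro/e** = observed / expected spot counts of a niche per region, with
  expected counts from the χ² independence model; Ro/e > 1 = enriched.
- **CNV score** — per cell, inferCNV-style residuals are min-max rescaled
  to [−1, 1] (y = 2(x−min)/(max−min) − 1) and the score is the mean of y²
  ∈ [0, 1].

A seed-controlled synthetic module generates hex lattices, tumor/nontumor
geometries, clustered niche fields, boundary-peaked abundance columns and
segment-amplified CNV matrices, so everything is testable without patient
data.

## Worked example

```python
import numpy as np
from posst import (make_hex_lattice, label_regions, HalfPlane, build_neighbor_graph,
                   annotate_boundary, sample_niche_field, niche_score_table,
                   layer_profile, simulate_spot_values)

lattice = make_hex_lattice(30, 30, spacing_um=100.0)
sides = label_regions(lattice, HalfPlane(np.pi / 2, lattice.spots["y"].median()))
graph = build_neighbor_graph(lattice)
ann = annotate_boundary(lattice, graph, sides)
print(f"boundary spots: {int(ann.table['is_boundary'].sum())}")
print(f"boundary zone width: {ann.boundary_zone_width(lattice):.1f} um")
```

```
boundary spots: 58
boundary zone width: 186.6 um
```

A straight tumor/nontumor interface picks out exactly the two spot rows
abutting it (58 spots here, two 29-spot rows), and the zone width — the
span of boundary-spot centers plus one spacing — is 186.6 μm, inside the
100–200 μm histological calibration band.

```python
niches = sample_niche_field(graph, k=3, smoothing=3, seed=0)
print(niche_score_table(graph, niches).round(3))

abundance = simulate_spot_values(ann.table["layer"], seed=0)
prof = layer_profile(ann.table["layer"], values=abundance.to_frame("abundance"))
print(prof.loc[-2:2].round(3))
```

```
         mean_NS  mean_AS  n_spots
niche
niche_0    1.934    4.156      212
niche_1    1.971    4.130      208
niche_2    1.747    4.676      364

       n_spots  mean_abundance
layer
-2          31           0.392
-1          30           0.801
 0          58           1.009
 1          30           0.798
 2          31           0.422
```

After three rounds of majority smoothing the niches are blocky: each spot
sees about 2 distinct niches among its 6 neighbors (mean NS ≈ 1.9) and
over 4 same-niche neighbors (mean AS > 4). The simulated abundance column
peaks at layer 0 — the boundary — and decays symmetrically into the tumor
(negative layers) and nontumor (positive layers) sides, the center-peak
pattern characteristic of boundary-enriched immune populations.

The same analyses run from the shell:

```sh
posst simulate --rows 30 --cols 30 --out sim/
posst boundary --positions sim/tissue_positions.csv \
               --annotations sim/annotations.tsv \
               --mapping sim/mapping.yaml --out out/
posst scores --positions sim/tissue_positions.csv \
             --annotations sim/annotations.tsv --out out/
posst roe --annotations sim/annotations.tsv \
          --niche-column niche --region-column histology --out out/
posst cnvscore --matrix sim/cnv_matrix.tsv --out out/
```

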