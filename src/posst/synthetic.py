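"""Seed-controlled synthetic slides and CNV matrices.

Emulates the geometric and statistical structure the spatial metrics
assume, so every operation is exercisable without patient data:

* a regular hexagonal spot lattice with 100 μm center-to-center spacing
  (offset-row geometry matching the spaceranger parity convention);
* binary tumor/nontumor region geometries (half-plane or disk), standing
  in for pathologist histology annotation;
* multi-class niche label fields with tunable self-clustering, via
  synchronous majority-of-neighbors smoothing of an i.i.d. uniform start —
  deterministic given a seed, and monotone in aggregation;
* per-spot abundance columns with a Gaussian center-peak profile across
  the boundary (the pattern immune-cell abundances show at invasive
  margins), truncated at 0 since deconvolved abundances are non-negative;
* genes × cells CNV matrices where a tumor subset carries amplified or
  deleted segments over a noisy diploid baseline.

All generators are bitwise-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boundary import NONTUMOR, TUMOR
from .lattice import NeighborGraph, SpotLattice

__all__ = [
    "HalfPlane",
    "Disk",
    "CnvModel",
    "make_hex_lattice",
    "label_regions",
    "sample_niche_field",
    "simulate_spot_values",
    "simulate_cnv_matrix",
]

DEFAULT_SPACING_UM = 100.0


def make_hex_lattice(
    rows: int, cols: int, spacing_um: float = DEFAULT_SPACING_UM
) -> SpotLattice:
    """Regular hex lattice of ``rows`` × ``cols`` spots.

    Row pitch is spacing·√3/2, within-row pitch is the spacing, and
    alternate rows are offset by half a spacing, so the minimum
    center-to-center distance is exactly ``spacing_um`` and every interior
    spot has six equidistant neighbors.  Array coordinates follow the
    spaceranger convention: ``array_col`` shares the parity of
    ``array_row``.
    """
    if rows < 3 or cols < 3:
        raise ValueError("lattice must be at least 3x3")
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r = r.ravel()
    c = c.ravel()
    array_col = 2 * c + (r % 2)
    x = array_col * spacing_um / 2.0
    y = r * spacing_um * np.sqrt(3) / 2.0
    barcodes = [f"S{rr:03d}_{cc:03d}" for rr, cc in zip(r, array_col)]
    spots = pd.DataFrame(
        {"array_row": r, "array_col": array_col, "x": x, "y": y},
        index=pd.Index(barcodes, name="barcode"),
    )
    return SpotLattice(spots)


@dataclass
class HalfPlane:
    """Tumor side of a line: spots with x·cos(angle) + y·sin(angle) < offset.

    ``angle`` in radians; ``angle = π/2`` makes the interface parallel to a
    lattice row axis (tumor where y < offset).
    """

    angle: float
    offset: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return x * np.cos(self.angle) + y * np.sin(self.angle) < self.offset


@dataclass
class Disk:
    """Tumor region: spots within ``radius`` of ``center`` (x, y)."""

    center: tuple[float, float]
    radius: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2


def label_regions(lattice: SpotLattice, geometry) -> pd.Series:
    """Deterministic tumor/nontumor side labels from a geometric predicate."""
    inside = geometry.contains(
        lattice.spots["x"].to_numpy(dtype=float),
        lattice.spots["y"].to_numpy(dtype=float),
    )
    if inside.all() or not inside.any():
        import warnings

        warnings.warn(
            "geometry labels every spot on one side: no boundary will exist",
            stacklevel=2,
        )
    sides = np.where(inside, TUMOR, NONTUMOR)
    return pd.Series(sides, index=lattice.spots.index, name="side")


def sample_niche_field(
    graph: NeighborGraph, k: int, smoothing: int = 0, seed: int = 0
) -> pd.Series:
    """Random k-niche label field with tunable self-clustering.

    Starts from i.i.d. uniform labels over ``k`` niches and applies
    ``smoothing`` rounds of synchronous majority-of-neighbors relabeling
    (a spot keeps its label on ties).  More smoothing yields blockier
    fields and higher aggregation scores.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, k, size=graph.n_spots)
    for _ in range(smoothing):
        new = labels.copy()
        for i, nbrs in enumerate(graph.neighbors):
            if len(nbrs) == 0:
                continue
            counts = np.bincount(labels[nbrs], minlength=k)
            winners = np.flatnonzero(counts == counts.max())
            # unique plurality winner replaces the label; ties keep it
            if len(winners) == 1:
                new[i] = winners[0]
        labels = new
    names = np.array([f"niche_{j}" for j in range(k)])
    return pd.Series(
        names[labels], index=pd.Index(graph.barcodes, name="barcode"), name="niche"
    )


def simulate_spot_values(
    layers: pd.Series,
    center_layer: float = 0.0,
    sigma: float = 1.5,
    amplitude: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.Series:
    """Abundance column with a Gaussian center-peak across the boundary.

    value = amplitude · exp(−(layer − center)² / 2σ²) + N(0, noise_sd),
    truncated at 0.  With the defaults the peak sits at the boundary layer,
    mimicking immune-cell enrichment at the invasive margin.
    """
    rng = np.random.default_rng(seed)
    lay = layers.to_numpy(dtype=float)
    signal = amplitude * np.exp(-((lay - center_layer) ** 2) / (2.0 * sigma**2))
    noise = rng.normal(0.0, noise_sd, size=lay.shape) if noise_sd > 0 else 0.0
    vals = np.maximum(signal + noise, 0.0)
    return pd.Series(vals, index=layers.index, name="abundance")


@dataclass
class CnvModel:
    """Configuration for a synthetic inferCNV-style residual matrix.

    Baseline cells draw each gene from N(1, noise_sd); tumor cells
    additionally shift the genes inside each ``(start, stop, sign)``
    segment by ``sign × amplitude`` (half-open gene index ranges, must not
    overlap).  The default segments place one amplification and one
    deletion, each spanning a fifth of the genome.
    """

    n_genes: int = 200
    n_cells: int = 100
    tumor_fraction: float = 0.5
    segments: list[tuple[int, int, int]] | None = None
    amplitude: float = 0.5
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.segments is None:
            g = self.n_genes
            self.segments = [(g // 10, 3 * g // 10, +1), (6 * g // 10, 8 * g // 10, -1)]
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        spans = sorted((s, e) for s, e, _ in self.segments)
        for (s, e), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e:
                raise ValueError(f"overlapping CNV segments: ({s},{e}) and ({s2},{e2})")
        for s, e, _ in self.segments:
            if not (0 <= s < e <= self.n_genes):
                raise ValueError(f"segment ({s},{e}) outside gene range [0,{self.n_genes})")


def simulate_cnv_matrix(
    model: CnvModel, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes × cells matrix plus ground-truth cell classes.

    Returns the matrix and a per-cell Series with values ``"tumor"`` /
    ``"baseline"``.  The first ``round(tumor_fraction · n_cells)`` cells
    are tumor.
    """
    rng = np.random.default_rng(seed)
    n_tumor = int(round(model.tumor_fraction * model.n_cells))
    vals = rng.normal(1.0, model.noise_sd, size=(model.n_genes, model.n_cells))
    for start, stop, sign in model.segments:
        vals[start:stop, :n_tumor] += sign * model.amplitude
    genes = [f"gene_{g:04d}" for g in range(model.n_genes)]
    cells = [f"cell_{c:04d}" for c in range(model.n_cells)]
    matrix = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=cells)
    classes = pd.Series(
        ["tumor"] * n_tumor + ["baseline"] * (model.n_cells - n_tumor),
        index=pd.Index(cells, name="cell"),
        name="truth",
    )
    return matrix, classes
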