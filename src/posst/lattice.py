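"""Hexagonal Visium lattice model and 6-neighbor adjacency.

A Visium capture area packs spots hexagonally: each interior spot has six
equidistant neighbors at the minimum center-to-center spacing (100 μm on
standard slides).  All downstream metrics (boundary detection, neighborhood
diversity, aggregation and colocalization scores) are defined on this
6-neighbor graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SpotLattice",
    "NeighborGraph",
    "build_neighbor_graph",
    "min_center_distance",
    "GeometryError",
]

#: Euclidean neighbor search accepts centers up to this factor times the
#: minimum spacing; absorbs pixel jitter while excluding the second hex
#: shell at ~1.73x the spacing.
NEIGHBOR_TOLERANCE = 1.05


class GeometryError(ValueError):
    """Raised when spot geometry is degenerate (e.g. duplicate centers)."""


@dataclass
class SpotLattice:
    """Spots of one slide with array and physical coordinates.

    Parameters
    ----------
    spots
        One row per spot, indexed by barcode, with integer columns
        ``array_row``/``array_col`` (0-based hex-offset coordinates as
        emitted by spaceranger) and float columns ``x``/``y`` (physical
        centers in fullres pixels or μm).  Additional columns hold
        categorical labels (histology, niche) and numeric values
        (deconvolved abundances, pathway scores).
    label_columns, value_columns
        Names of the categorical and numeric annotation columns.
    """

    spots: pd.DataFrame
    label_columns: list[str] = field(default_factory=list)
    value_columns: list[str] = field(default_factory=list)

    REQUIRED = ("array_row", "array_col", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.spots.columns]
        if missing:
            raise ValueError(f"SpotLattice missing required columns: {missing}")
        if self.spots.index.has_duplicates:
            dups = self.spots.index[self.spots.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate barcodes: {dups}")
        coords = self.spots[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite spot coordinates")
        # Regular Visium exports have array_row and array_col of equal
        # parity; real exports occasionally violate this, so warn only.
        parity_ok = (
            self.spots["array_row"].to_numpy() % 2
            == self.spots["array_col"].to_numpy() % 2
        )
        self._parity_violations = int((~parity_ok).sum())

    @property
    def barcodes(self) -> np.ndarray:
        return self.spots.index.to_numpy()

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def coords(self) -> np.ndarray:
        """Physical spot centers as an (n, 2) float array of (x, y)."""
        return self.spots[["x", "y"]].to_numpy(dtype=float)

    def label(self, name: str) -> pd.Series:
        if name not in self.label_columns:
            raise KeyError(f"unknown label column {name!r}; have {self.label_columns}")
        return self.spots[name]

    def value(self, name: str) -> pd.Series:
        if name not in self.value_columns:
            raise KeyError(f"unknown value column {name!r}; have {self.value_columns}")
        return self.spots[name]

    def subset(self, barcodes) -> "SpotLattice":
        """Restrict to the given barcodes, preserving annotation columns."""
        return SpotLattice(
            self.spots.loc[barcodes].copy(),
            label_columns=list(self.label_columns),
            value_columns=list(self.value_columns),
        )

    def with_columns(
        self,
        table: pd.DataFrame,
        label_columns: list[str] | None = None,
        value_columns: list[str] | None = None,
    ) -> "SpotLattice":
        """Attach annotation columns (aligned on barcode) to a copy."""
        label_columns = list(label_columns or [])
        value_columns = list(value_columns or [])
        spots = self.spots.copy()
        for col in label_columns + value_columns:
            spots[col] = table[col].reindex(spots.index)
        return SpotLattice(
            spots,
            label_columns=self.label_columns + label_columns,
            value_columns=self.value_columns + value_columns,
        )


@dataclass
class NeighborGraph:
    """Symmetric ≤6-neighbor adjacency over the spots of one lattice.

    ``neighbors[i]`` holds the integer positions (into ``barcodes``) of the
    spots adjacent to spot ``i``.  Interior spots are those with exactly six
    neighbors.
    """

    barcodes: np.ndarray
    neighbors: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.barcodes) != len(self.neighbors):
            raise ValueError("barcodes and neighbor lists differ in length")
        self.neighbors = [np.asarray(n, dtype=np.intp) for n in self.neighbors]
        for i, nbrs in enumerate(self.neighbors):
            if len(nbrs) > 6:
                raise ValueError(f"spot {self.barcodes[i]} has {len(nbrs)} > 6 neighbors")
            if i in nbrs:
                raise ValueError(f"self-loop at {self.barcodes[i]}")
            for j in nbrs:
                if i not in self.neighbors[j]:
                    raise ValueError(
                        f"asymmetric edge {self.barcodes[i]} -> {self.barcodes[j]}"
                    )

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def degree(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbors], dtype=int)

    @property
    def interior(self) -> np.ndarray:
        """True where a spot has the full complement of 6 neighbors."""
        return self.degree == 6

    def adjacency_dict(self) -> dict[str, list[str]]:
        return {
            str(self.barcodes[i]): [str(self.barcodes[j]) for j in nbrs]
            for i, nbrs in enumerate(self.neighbors)
        }

    def to_edge_table(self) -> pd.DataFrame:
        """Undirected edge list (each edge once) as a two-column table."""
        rows = [
            (str(self.barcodes[i]), str(self.barcodes[j]))
            for i, nbrs in enumerate(self.neighbors)
            for j in nbrs
            if i < j
        ]
        return pd.DataFrame(rows, columns=["barcode_a", "barcode_b"])


def min_center_distance(lattice: SpotLattice) -> float:
    """Exact minimum pairwise center-to-center distance between spots.

    This is the normalization constant of the method: signed distances to
    the boundary are expressed in multiples of it so that pixel-scale
    factors cancel out.
    """
    if lattice.n_spots < 2:
        raise ValueError("min_center_distance requires at least 2 spots")
    coords = lattice.coords
    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=2)
    d_min = float(dists[:, 1].min())
    if d_min <= 0:
        raise GeometryError("duplicate spot centers: minimum spacing is 0")
    return d_min


def _array_neighbor_graph(lattice: SpotLattice) -> NeighborGraph:
    rows = lattice.spots["array_row"].to_numpy(dtype=int)
    cols = lattice.spots["array_col"].to_numpy(dtype=int)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(zip(rows, cols))}
    if len(index) != lattice.n_spots:
        raise GeometryError("duplicate array coordinates in lattice")
    # Hex-offset adjacency: two same-row neighbors and two in each
    # adjacent row.
    offsets = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))
    neighbors = []
    for r, c in zip(rows, cols):
        nbrs = [
            index[(r + dr, c + dc)]
            for dr, dc in offsets
            if (r + dr, c + dc) in index
        ]
        neighbors.append(np.array(sorted(nbrs), dtype=np.intp))
    return NeighborGraph(lattice.barcodes, neighbors)


def _euclidean_neighbor_graph(lattice: SpotLattice) -> NeighborGraph:
    d_min = min_center_distance(lattice)
    coords = lattice.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=NEIGHBOR_TOLERANCE * d_min, output_type="ndarray")
    adj: list[list[int]] = [[] for _ in range(lattice.n_spots)]
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    neighbors = [np.array(sorted(n), dtype=np.intp) for n in adj]
    return NeighborGraph(lattice.barcodes, neighbors)


def build_neighbor_graph(lattice: SpotLattice, method: str = "array") -> NeighborGraph:
    """Construct the hex 6-neighbor graph.

    Parameters
    ----------
    lattice
        Spot lattice with at least two spots.
    method
        ``"array"`` uses the hex-offset array coordinates: the neighbors of
        ``(r, c)`` are the present spots at ``(r, c±2)`` and ``(r±1, c±1)``.
        Exact on spaceranger exports and immune to pixel jitter.
        ``"euclidean"`` links every pair of centers within 1.05x the minimum
        spacing; use for non-Visium or jittered geometries.  Both yield
        exactly six neighbors at interior spots of a regular lattice.
    """
    if lattice.n_spots < 2:
        raise ValueError("neighbor graph requires at least 2 spots")
    if method == "array":
        return _array_neighbor_graph(lattice)
    if method == "euclidean":
        return _euclidean_neighbor_graph(lattice)
    raise ValueError(f"unknown neighbor method {method!r}")
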