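"""Spatial niche scores and distance-layer profiles.

Three per-niche statistics on the hex 6-neighbor graph:

* **Neighborhood score (NS)** — neighborhood diversity: the number of
  distinct niche categories among a spot's 6 neighbors, from 1
  (homogeneous surroundings) to 6 (every neighbor a different niche);
  averaged over the spots of each niche.
* **Aggregation score (AS)** — self-clustering: how many of a niche-X
  spot's 6 neighbors are also niche X, from 0 (isolated) to 6 (center of a
  perfect cluster); averaged over niche-X spots.
* **Colocalization score (CS)** — interniche relationships: CS(A, B) is
  the mean number of niche-B neighbors over all niche-A spots, from 0 (no
  spatial association) to 6 (perfect surrounding).  Not symmetric in
  general; CS(X, X) equals AS(X), and with interior-only scoring each row
  sums to exactly 6.

Layer profiles tabulate niche composition or mean numeric values per
signed-distance layer across the invasion boundary.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .lattice import NeighborGraph

__all__ = [
    "per_spot_neighborhood_scores",
    "per_spot_aggregation_counts",
    "neighborhood_scores",
    "aggregation_scores",
    "niche_score_table",
    "colocalization_matrix",
    "layer_profile",
    "per_niche_value_ratio",
]


def _aligned_labels(graph: NeighborGraph, niches: pd.Series) -> np.ndarray:
    niches = niches.reindex(pd.Index(graph.barcodes))
    if niches.isna().any():
        missing = niches.index[niches.isna()].tolist()
        raise ValueError(f"spots without a niche label: {missing[:5]}")
    return niches.to_numpy()


def _scored_mask(graph: NeighborGraph, interior_only: bool) -> np.ndarray:
    if interior_only:
        return graph.interior
    deg = graph.degree
    if (deg == 0).any():
        warnings.warn(
            f"{int((deg == 0).sum())} spots with no neighbors excluded from scoring",
            stacklevel=3,
        )
    return deg > 0


def per_spot_neighborhood_scores(
    graph: NeighborGraph, niches: pd.Series, interior_only: bool = True
) -> pd.Series:
    """NS per spot: distinct niche categories among its neighbors."""
    labels = _aligned_labels(graph, niches)
    mask = _scored_mask(graph, interior_only)
    out = {}
    for i in np.flatnonzero(mask):
        out[graph.barcodes[i]] = len(set(labels[graph.neighbors[i]]))
    return pd.Series(out, name="NS", dtype=int).rename_axis("barcode")


def per_spot_aggregation_counts(
    graph: NeighborGraph, niches: pd.Series, interior_only: bool = True
) -> pd.Series:
    """Per spot: how many neighbors share the spot's own niche."""
    labels = _aligned_labels(graph, niches)
    mask = _scored_mask(graph, interior_only)
    out = {}
    for i in np.flatnonzero(mask):
        out[graph.barcodes[i]] = int((labels[graph.neighbors[i]] == labels[i]).sum())
    return pd.Series(out, name="AS", dtype=int).rename_axis("barcode")


def _per_niche_mean(scores: pd.Series, niches: pd.Series, name: str) -> pd.Series:
    grouped = scores.groupby(niches.reindex(scores.index)).mean()
    grouped.name = name
    grouped.index.name = "niche"
    return grouped


def neighborhood_scores(
    graph: NeighborGraph, niches: pd.Series, interior_only: bool = True
) -> pd.Series:
    """Mean NS per niche (how diverse that niche's typical surroundings are)."""
    per_spot = per_spot_neighborhood_scores(graph, niches, interior_only)
    return _per_niche_mean(per_spot, niches, "mean_NS")


def aggregation_scores(
    graph: NeighborGraph, niches: pd.Series, interior_only: bool = True
) -> pd.Series:
    """Mean same-niche neighbor count per niche (self-clustering tendency)."""
    per_spot = per_spot_aggregation_counts(graph, niches, interior_only)
    return _per_niche_mean(per_spot, niches, "mean_AS")


def niche_score_table(
    graph: NeighborGraph, niches: pd.Series, interior_only: bool = True
) -> pd.DataFrame:
    """Combined per-niche table: mean_NS, mean_AS and scored-spot counts."""
    ns = neighborhood_scores(graph, niches, interior_only)
    per_spot_as = per_spot_aggregation_counts(graph, niches, interior_only)
    as_ = _per_niche_mean(per_spot_as, niches, "mean_AS")
    counts = per_spot_as.groupby(niches.reindex(per_spot_as.index)).size()
    table = pd.DataFrame({"mean_NS": ns, "mean_AS": as_, "n_spots": counts})
    table.index.name = "niche"
    return table


def colocalization_matrix(
    graph: NeighborGraph, niches: pd.Series, interior_only: bool = True
) -> pd.DataFrame:
    """CS(A, B) for every ordered niche pair (rows = source niche A).

    For each niche-A spot, count neighbors belonging to niche B; average
    those counts over all scored A spots.
    """
    labels = _aligned_labels(graph, niches)
    mask = _scored_mask(graph, interior_only)
    cats = sorted(pd.unique(labels))
    cat_index = {c: k for k, c in enumerate(cats)}
    sums = np.zeros((len(cats), len(cats)))
    n_spots = np.zeros(len(cats))
    for i in np.flatnonzero(mask):
        a = cat_index[labels[i]]
        n_spots[a] += 1
        for j in graph.neighbors[i]:
            sums[a, cat_index[labels[j]]] += 1
    empty = n_spots == 0
    if empty.any():
        warnings.warn(
            f"niches with no scored spots omitted: {[cats[k] for k in np.flatnonzero(empty)]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        cs = sums / n_spots[:, None]
    out = pd.DataFrame(cs, index=pd.Index(cats, name="niche"), columns=cats)
    return out.loc[~empty]


def layer_profile(
    layers: pd.Series,
    niches: pd.Series | None = None,
    values: pd.DataFrame | None = None,
    slides: pd.Series | None = None,
) -> pd.DataFrame:
    """Profile niche composition and/or mean values across distance layers.

    Parameters
    ----------
    layers
        Signed layer index per barcode (layer 0 = boundary spots).
    niches
        Optional niche labels; emits one ``frac_<niche>`` column per niche,
        with fractions summing to 1 per layer over retained spots.
    values
        Optional numeric columns; emits ``mean_<col>`` layer means.
    slides
        Optional slide id per barcode.  Profiles are then computed per
        slide and averaged across slides with equal weight (the unit of
        aggregation is the slide); per-slide tables are recoverable by
        calling this function on each slide's spots.

    Layers with no spots in a slide contribute missing values, never 0/0.
    """
    if niches is None and values is None:
        raise ValueError("provide niche labels and/or value columns to profile")

    if slides is not None:
        slides = slides.reindex(layers.index)
        parts = []
        for _, idx in layers.groupby(slides).groups.items():
            parts.append(
                layer_profile(
                    layers.loc[idx],
                    None if niches is None else niches.loc[idx],
                    None if values is None else values.loc[idx],
                )
            )
        stacked = pd.concat(parts)
        prof = stacked.groupby(level=0).mean()
        prof["n_spots"] = stacked["n_spots"].groupby(level=0).sum()
        return prof

    out = pd.DataFrame(index=pd.Index(np.sort(layers.unique()), name="layer"))
    out["n_spots"] = layers.value_counts().reindex(out.index).astype(int)
    if niches is not None:
        niches = niches.reindex(layers.index)
        counts = pd.crosstab(layers, niches)
        fracs = counts.div(counts.sum(axis=1), axis=0)
        for niche in fracs.columns:
            out[f"frac_{niche}"] = fracs[niche].reindex(out.index)
    if values is not None:
        values = values.reindex(layers.index)
        means = values.groupby(layers).mean()
        for col in values.columns:
            out[f"mean_{col}"] = means[col].reindex(out.index)
    return out


def per_niche_value_ratio(
    niches: pd.Series,
    numerator: pd.Series,
    denominator: pd.Series,
) -> pd.Series:
    """Ratio of summed abundances A/B within each niche.

    Both columns must be non-negative (deconvolved abundances).  Niches
    whose denominator sums to 0 get a missing ratio with a warning.
    """
    numerator = numerator.reindex(niches.index)
    denominator = denominator.reindex(niches.index)
    for name, col in (("numerator", numerator), ("denominator", denominator)):
        vals = col.dropna()
        if (vals < 0).any():
            raise ValueError(f"negative abundances in {name} column")
    num = numerator.groupby(niches).sum()
    den = denominator.groupby(niches).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    zero_den = den == 0
    if zero_den.any():
        warnings.warn(
            f"zero denominator sum in niches {den.index[zero_den].tolist()}; "
            "ratio reported as missing",
            stacklevel=2,
        )
        ratio[zero_den] = np.nan
    ratio.name = "ratio"
    ratio.index.name = "niche"
    return ratio
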