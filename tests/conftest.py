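import numpy as np
import pandas as pd
import pytest

from posst import build_neighbor_graph, make_hex_lattice


@pytest.fixture(scope="session")
def lattice_10():
    return make_hex_lattice(10, 10, spacing_um=100.0)


@pytest.fixture(scope="session")
def graph_10(lattice_10):
    return build_neighbor_graph(lattice_10)


@pytest.fixture(scope="session")
def hex_patch():
    """3x3 hex patch: the central spot has exactly 6 neighbors."""
    lattice = make_hex_lattice(3, 3, spacing_um=100.0)
    graph = build_neighbor_graph(lattice)
    center = lattice.barcodes[int(np.flatnonzero(graph.interior)[0])]
    return lattice, graph, center


def random_sublattice(rows, cols, n_keep, seed):
    """Random subset of a regular lattice (keeps annotation-free spots)."""
    lattice = make_hex_lattice(rows, cols, spacing_um=100.0)
    rng = np.random.default_rng(seed)
    keep = rng.choice(lattice.barcodes, size=n_keep, replace=False)
    return lattice.subset(sorted(keep))


def random_niches(graph, k, seed):
    rng = np.random.default_rng(seed)
    labels = [f"n{j}" for j in rng.integers(0, k, size=graph.n_spots)]
    return pd.Series(labels, index=pd.Index(graph.barcodes, name="barcode"))
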