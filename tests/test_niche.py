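import numpy as np
import pandas as pd
import pytest

from posst import (
    aggregation_scores,
    build_neighbor_graph,
    colocalization_matrix,
    layer_profile,
    make_hex_lattice,
    neighborhood_scores,
    niche_score_table,
    per_niche_value_ratio,
    per_spot_aggregation_counts,
    per_spot_neighborhood_scores,
)

from conftest import random_niches, random_sublattice


def patch_labels(graph, center, center_niche, neighbor_niches, fill="bg"):
    """Label a hex patch: the center, its 6 neighbors, background elsewhere."""
    idx = {b: i for i, b in enumerate(graph.barcodes)}
    labels = {b: fill for b in graph.barcodes}
    labels[center] = center_niche
    for b, niche in zip(
        (graph.barcodes[j] for j in graph.neighbors[idx[center]]), neighbor_niches
    ):
        labels[b] = niche
    return pd.Series(labels, index=pd.Index(graph.barcodes, name="barcode"))


def brute_force_scores(graph, niches):
    """Direct per-spot oracle for NS (distinct neighbor niches) and AS
    (same-niche neighbor count), interior spots only."""
    labels = niches.reindex(pd.Index(graph.barcodes)).to_numpy()
    ns, as_ = {}, {}
    for i, nbrs in enumerate(graph.neighbors):
        if len(nbrs) != 6:
            continue
        b = graph.barcodes[i]
        neigh = [labels[j] for j in nbrs]
        ns[b] = len(set(neigh))
        as_[b] = sum(1 for lab in neigh if lab == labels[i])
    return ns, as_


class TestScoreExtremes:
    def test_ns_is_one_on_homogeneous_surroundings(self, hex_patch):
        _, graph, center = hex_patch
        niches = patch_labels(graph, center, "q", ["q"] * 6)
        assert per_spot_neighborhood_scores(graph, niches)[center] == 1

    def test_ns_is_six_on_maximal_diversity(self, hex_patch):
        _, graph, center = hex_patch
        niches = patch_labels(graph, center, "q", [f"n{i}" for i in range(6)])
        assert per_spot_neighborhood_scores(graph, niches)[center] == 6

    def test_as_zero_for_isolated_spot(self, hex_patch):
        _, graph, center = hex_patch
        niches = patch_labels(graph, center, "X", ["other"] * 6)
        assert per_spot_aggregation_counts(graph, niches)[center] == 0

    def test_as_six_at_perfect_cluster_center(self, hex_patch):
        _, graph, center = hex_patch
        niches = patch_labels(graph, center, "X", ["X"] * 6, fill="X")
        assert per_spot_aggregation_counts(graph, niches)[center] == 6

    def test_cs_six_under_perfect_surrounding(self, hex_patch):
        _, graph, center = hex_patch
        niches = patch_labels(graph, center, "A", ["B"] * 6, fill="B")
        cs = colocalization_matrix(graph, niches)
        assert cs.loc["A", "B"] == 6.0

    def test_cs_zero_without_contact(self):
        lattice = make_hex_lattice(6, 6)
        graph = build_neighbor_graph(lattice)
        # split by row bands with a buffer band between A and B
        rows = lattice.spots["array_row"].to_numpy()
        labels = np.where(rows <= 1, "A", np.where(rows >= 4, "B", "buffer"))
        niches = pd.Series(labels, index=pd.Index(graph.barcodes, name="barcode"))
        cs = colocalization_matrix(graph, niches)
        assert cs.loc["A", "B"] == 0.0
        assert cs.loc["B", "A"] == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_per_spot_scores_match_brute_force(self, seed):
        lattice = random_sublattice(15, 15, n_keep=150, seed=seed)
        graph = build_neighbor_graph(lattice)
        niches = random_niches(graph, k=10, seed=seed)
        ns_oracle, as_oracle = brute_force_scores(graph, niches)
        ns = per_spot_neighborhood_scores(graph, niches)
        as_ = per_spot_aggregation_counts(graph, niches)
        assert dict(ns) == ns_oracle
        assert dict(as_) == as_oracle

    @pytest.mark.parametrize("seed", range(10))
    def test_cs_matrix_matches_counting_oracle(self, seed):
        lattice = random_sublattice(12, 12, n_keep=100, seed=seed + 50)
        graph = build_neighbor_graph(lattice)
        niches = random_niches(graph, k=4, seed=seed)
        labels = niches.reindex(pd.Index(graph.barcodes)).to_numpy()
        cs = colocalization_matrix(graph, niches)
        for a in cs.index:
            spots = [
                i
                for i in np.flatnonzero(graph.interior)
                if labels[i] == a
            ]
            for b in cs.columns:
                counts = [
                    sum(1 for j in graph.neighbors[i] if labels[j] == b)
                    for i in spots
                ]
                assert cs.loc[a, b] == pytest.approx(np.mean(counts))


class TestIdentities:
    @pytest.mark.parametrize("seed", range(5))
    def test_as_equals_cs_diagonal_and_rows_sum_to_six(self, seed):
        lattice = make_hex_lattice(12, 12)
        graph = build_neighbor_graph(lattice)
        niches = random_niches(graph, k=5, seed=seed)
        as_ = aggregation_scores(graph, niches, interior_only=True)
        cs = colocalization_matrix(graph, niches, interior_only=True)
        for x in cs.index:
            assert cs.loc[x, x] == pytest.approx(as_[x])
        np.testing.assert_allclose(cs.sum(axis=1).to_numpy(), 6.0)

    def test_bounds(self, graph_10):
        niches = random_niches(graph_10, k=7, seed=3)
        table = niche_score_table(graph_10, niches)
        assert table["mean_NS"].between(1, 6).all()
        assert table["mean_AS"].between(0, 6).all()
        assert table["n_spots"].sum() == int(graph_10.interior.sum())

    def test_relabeling_permutes_rows_and_columns(self, graph_10):
        niches = random_niches(graph_10, k=4, seed=9)
        perm = {"n0": "zeta", "n1": "alpha", "n2": "mid", "n3": "beta"}
        renamed = niches.map(perm)
        cs = colocalization_matrix(graph_10, niches)
        cs2 = colocalization_matrix(graph_10, renamed)
        relabeled = cs.rename(index=perm, columns=perm).sort_index(axis=0).sort_index(axis=1)
        pd.testing.assert_frame_equal(relabeled, cs2.sort_index(axis=0).sort_index(axis=1))


class TestLayerProfile:
    def test_single_niche_fraction_is_one(self):
        layers = pd.Series([0, 1, 1, -1], index=list("abcd"))
        niches = pd.Series(["q"] * 4, index=list("abcd"))
        prof = layer_profile(layers, niches=niches)
        assert (prof["frac_q"] == 1.0).all()

    def test_hand_counted_three_layer_example(self):
        layers = pd.Series([-1, -1, -1, 0, 0, 1, 1, 1], index=list("abcdefgh"))
        niches = pd.Series(
            ["q", "q", "r", "q", "r", "r", "r", "r"], index=list("abcdefgh")
        )
        prof = layer_profile(layers, niches=niches)
        assert prof.loc[-1, "frac_q"] == pytest.approx(2 / 3)
        assert prof.loc[-1, "frac_r"] == pytest.approx(1 / 3)
        assert prof.loc[0, "frac_q"] == pytest.approx(1 / 2)
        assert prof.loc[0, "frac_r"] == pytest.approx(1 / 2)
        assert prof.loc[1, "frac_q"] == 0.0
        assert prof.loc[1, "frac_r"] == 1.0
        assert prof["n_spots"].tolist() == [3, 2, 3]

    def test_fractions_sum_to_one_per_layer(self, lattice_10, graph_10):
        rng = np.random.default_rng(0)
        layers = pd.Series(
            rng.integers(-3, 4, size=graph_10.n_spots), index=lattice_10.spots.index
        )
        niches = random_niches(graph_10, k=4, seed=1)
        prof = layer_profile(layers, niches=niches)
        frac_cols = [c for c in prof.columns if c.startswith("frac_")]
        np.testing.assert_allclose(prof[frac_cols].sum(axis=1).to_numpy(), 1.0)

    def test_value_means_and_empty_layer_missing(self):
        layers = pd.Series([0, 0, 2], index=list("abc"))
        values = pd.DataFrame({"v": [1.0, 3.0, 5.0]}, index=list("abc"))
        prof = layer_profile(layers, values=values)
        assert prof.loc[0, "mean_v"] == 2.0
        assert prof.loc[2, "mean_v"] == 5.0
        assert 1 not in prof.index  # empty layers are absent, never 0/0

    def test_multi_slide_unweighted_mean(self):
        layers = pd.Series([0, 0, 0, 0], index=list("abcd"))
        values = pd.DataFrame({"v": [1.0, 1.0, 4.0, 8.0]}, index=list("abcd"))
        slides = pd.Series(["s1", "s1", "s1", "s2"], index=list("abcd"))
        prof = layer_profile(layers, values=values, slides=slides)
        # s1 mean 2.0, s2 mean 8.0 -> unweighted cross-slide mean 5.0
        assert prof.loc[0, "mean_v"] == pytest.approx(5.0)
        assert prof.loc[0, "n_spots"] == 4


class TestValueRatio:
    def test_simple_ratio(self):
        niches = pd.Series(["cc", "cc", "ct"], index=list("abc"))
        a = pd.Series([4.0, 2.0, 1.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        ratio = per_niche_value_ratio(niches, a, b)
        assert ratio["cc"] == pytest.approx(2.0)
        assert ratio["ct"] == pytest.approx(0.25)

    def test_zero_denominator_is_missing_with_warning(self):
        niches = pd.Series(["cc", "ct"], index=list("ab"))
        a = pd.Series([1.0, 1.0], index=list("ab"))
        b = pd.Series([2.0, 0.0], index=list("ab"))
        with pytest.warns(UserWarning, match="zero denominator"):
            ratio = per_niche_value_ratio(niches, a, b)
        assert np.isnan(ratio["ct"])

    def test_negative_abundance_rejected(self):
        niches = pd.Series(["cc"], index=["a"])
        with pytest.raises(ValueError, match="negative"):
            per_niche_value_ratio(
                niches, pd.Series([-1.0], index=["a"]), pd.Series([1.0], index=["a"])
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_grouped_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        idx = [f"s{i}" for i in range(n)]
        niches = pd.Series(rng.choice(["u", "v", "w"], size=n), index=idx)
        a = pd.Series(rng.uniform(0, 5, size=n), index=idx)
        b = pd.Series(rng.uniform(0.1, 5, size=n), index=idx)
        ratio = per_niche_value_ratio(niches, a, b)
        for niche in ("u", "v", "w"):
            mask = niches == niche
            assert ratio[niche] == pytest.approx(a[mask].sum() / b[mask].sum())
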