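"""Potts modularity, Leiden clustering, resolution tuning, valid bins."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import (
    all_set_partitions,
    brute_force_potts_modularity,
    random_weighted_map,
)
from hicmag.binning import (
    Partition,
    extract_valid_bins,
    leiden_cluster,
    potts_modularity,
    tune_resolution,
)
from hicmag.contact_map import ContactMap, ContigCatalog
from hicmag.evaluation import pair_metrics


class TestPottsModularity:
    def test_single_community_is_zero_at_gamma_one(self):
        rng = np.random.default_rng(0)
        a = np.triu(rng.random((5, 5)), k=1)
        a += a.T
        cmap = ContactMap([f"n{i}" for i in range(5)], a)
        assert potts_modularity(cmap, np.zeros(5, dtype=int), gamma=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_singletons(self):
        a = np.ones((3, 3)) - np.eye(3)
        cmap = ContactMap(["a", "b", "c"], a)
        q = potts_modularity(cmap, [0, 1, 2], gamma=1.0)
        assert q == pytest.approx(-2.0)  # -3 * 2^2 / 6

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        cmap = random_weighted_map(rng)
        n = cmap.n_contigs
        memb = rng.integers(0, n, size=n)
        gamma = float(rng.uniform(0.2, 5.0))
        expected = brute_force_potts_modularity(cmap.matrix.toarray(), memb, gamma)
        assert potts_modularity(cmap, memb, gamma) == pytest.approx(expected, abs=1e-10)

    def test_empty_graph_errors(self):
        cmap = ContactMap([], np.zeros((0, 0)))
        with pytest.raises(ValueError):
            potts_modularity(cmap, [], 1.0)


class TestLeidenCluster:
    def test_two_cliques_recovered_and_globally_optimal(self, two_clique_map):
        part = leiden_cluster(two_clique_map, gamma=1.0, seed=0)
        groups = part.communities()
        assert sorted(sorted(g) for g in groups.values()) == [
            [f"c{i}" for i in range(4)],
            [f"c{i}" for i in range(4, 8)],
        ]
        # exhaustive optimality over all 4140 partitions of the 8 nodes
        best_q = max(
            potts_modularity(
                two_clique_map,
                _membership_from_blocks(two_clique_map.contig_ids, blocks),
                1.0,
            )
            for blocks in all_set_partitions(list(two_clique_map.contig_ids))
        )
        q = potts_modularity(two_clique_map, part, 1.0)
        assert q == pytest.approx(best_q, abs=1e-10)

    def test_beats_trivial_partitions(self, two_clique_map):
        part = leiden_cluster(two_clique_map, gamma=1.0, seed=0)
        q = potts_modularity(two_clique_map, part, 1.0)
        n = two_clique_map.n_contigs
        assert q >= potts_modularity(two_clique_map, np.arange(n), 1.0)
        assert q >= potts_modularity(two_clique_map, np.zeros(n, dtype=int), 1.0)

    def test_edgeless_graph_all_singletons(self):
        cmap = ContactMap(["a", "b", "c"], np.zeros((3, 3)))
        part = leiden_cluster(cmap, gamma=1.0, seed=0)
        assert part.n_communities == 3

    def test_deterministic_given_seed(self, default_community):
        cmap = default_community.cmap
        p1 = leiden_cluster(cmap, gamma=1.0, seed=42)
        p2 = leiden_cluster(cmap, gamma=1.0, seed=42)
        assert (p1.membership == p2.membership).all()

    def test_communities_are_connected(self, small_community):
        import igraph  # noqa: F401 -- traversal check below is igraph-free

        cmap = small_community.cmap
        part = leiden_cluster(cmap, gamma=1.0, seed=0)
        adj = cmap.matrix
        for members in part.communities().values():
            idx = [cmap.index[c] for c in members]
            sub = adj[np.ix_(idx, idx)]
            # BFS traversal from node 0 must reach all members
            seen = {0}
            frontier = [0]
            while frontier:
                node = frontier.pop()
                for nbr in sub[node].nonzero()[1]:
                    if nbr not in seen:
                        seen.add(nbr)
                        frontier.append(nbr)
            assert len(seen) == len(idx)

    def test_species_recovery_on_synthetic_community(self, small_community):
        sim = small_community
        part = leiden_cluster(sim.cmap, gamma=1.0, seed=0)
        _, ari = pair_metrics(sim.truth, part.as_series())
        assert ari >= 0.95

    def test_community_count_nondecreasing_in_gamma(self, small_community):
        counts = [
            leiden_cluster(small_community.cmap, gamma=g, seed=0).n_communities
            for g in (1, 5, 10, 20, 30)
        ]
        assert counts == sorted(counts)


def _membership_from_blocks(ids, blocks):
    memb = {}
    for k, block in enumerate(blocks):
        for c in block:
            memb[c] = k
    return [memb[c] for c in ids]


class TestTuneResolution:
    def test_returns_argmax_of_mean_score(self, small_community):
        sim = small_community
        gamma, scores = tune_resolution(sim.cmap, sim.labels, candidates=(1, 5, 10), seed=0)
        best = scores.loc[scores["score"].idxmax(), "gamma"]
        assert gamma == best
        assert (scores["score"] == (scores["ari"] + scores["nmi"]) / 2).all()

    def test_tie_breaks_to_smallest_gamma(self, small_community):
        # a perfectly separable community scores 1.0 at several resolutions
        sim = small_community
        gamma, scores = tune_resolution(sim.cmap, sim.labels, candidates=(1, 5), seed=0)
        if scores["score"].nunique() == 1:
            assert gamma == 1.0
        else:
            assert gamma == scores.loc[scores["score"].idxmax(), "gamma"]

    def test_nested_structure_selects_higher_gamma(self):
        """Two blocks of tightly linked sub-blocks: labels follow the fine
        sub-blocks, which only a higher resolution separates."""
        n_sub, size = 8, 10
        n = n_sub * size
        a = np.zeros((n, n))
        for s in range(n_sub):
            sl = slice(s * size, (s + 1) * size)
            a[sl, sl] = 3.0
        # moderate coupling between consecutive sub-block pairs: at gamma=1
        # each coupled pair merges, at gamma=5 the fine sub-blocks survive
        for s in range(0, n_sub, 2):
            a[s * size : (s + 1) * size, (s + 1) * size : (s + 2) * size] = 0.5
        a = np.triu(a, 1)
        a += a.T
        ids = [f"c{i}" for i in range(n)]
        cmap = ContactMap(ids, a)
        labels = pd.Series([f"s{i // size}" for i in range(n)], index=ids)
        gamma, scores = tune_resolution(cmap, labels, candidates=(1, 5), seed=0)
        # direct scoring confirms gamma=5 separates the sub-blocks
        assert scores.set_index("gamma").loc[5.0, "score"] > scores.set_index("gamma").loc[1.0, "score"]
        assert gamma == 5.0

    def test_no_labeled_nodes_errors(self, small_community):
        with pytest.raises(ValueError):
            tune_resolution(small_community.cmap, pd.Series(dtype=object), seed=0)


class TestExtractValidBins:
    def _catalog(self, lengths):
        return ContigCatalog(
            pd.DataFrame(
                {"length": pd.Series(lengths), "coverage": 1.0, "sites": 1, "signal": 1}
            )
        )

    def test_size_cutoff_boundaries(self):
        lengths = {"a": 149_999, "b": 150_001, "c": 150_000}
        part = Partition(["a", "b", "c"], np.array([0, 1, 2]))
        bins = extract_valid_bins(part, self._catalog(lengths))
        kept = {c for members in bins.bins.values() for c in members}
        assert kept == {"b"}  # strictly above 150 kbp only
        assert set(bins.unbinned) == {"a", "c"}

    def test_empty_partition(self):
        bins = extract_valid_bins(Partition([], np.array([])), self._catalog({}))
        assert bins.n_bins == 0

    def test_contig_conservation(self, small_community):
        sim = small_community
        part = leiden_cluster(sim.cmap, gamma=1.0, seed=0)
        bins = extract_valid_bins(part, sim.catalog)
        binned = {c for members in bins.bins.values() for c in members}
        assert binned | set(bins.unbinned) == set(part.contig_ids)
        assert not binned & set(bins.unbinned)

    def test_summary_totals(self):
        lengths = {"a": 100_000, "b": 60_000, "c": 200_000}
        part = Partition(["a", "b", "c"], np.array([0, 0, 1]))
        bins = extract_valid_bins(part, self._catalog(lengths))
        assert bins.n_bins == 2
        assert sorted(bins.summary["total_bp"]) == [160_000, 200_000]
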