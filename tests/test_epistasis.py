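"""Gene network construction, link communities, centrality, small-world stats."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metasoil import epistasis
from metasoil.epistasis import GeneNetwork, partition_density
from metasoil.types import InteractionMatrix


def lc_oracle_best_density(graph: nx.Graph) -> float:
    """Independent link-community oracle on a small graph.

    Single-linkage clustering at threshold t is exactly the connected
    components of the edge-similarity graph restricted to pairs with
    distance <= t, so enumerating all observed similarity levels visits
    every dendrogram partition. Similarities are re-derived from the
    definition (Jaccard of inclusive neighbourhoods of non-shared ends).
    """
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    m = len(edges)
    inc = {v: set(graph.neighbors(v)) | {v} for v in graph.nodes}
    sims = {}
    for ea, eb in itertools.combinations(edges, 2):
        shared = set(ea) & set(eb)
        if not shared:
            continue
        best = 0.0
        for k in shared:
            i = ea[0] if ea[1] == k else ea[1]
            j = eb[0] if eb[1] == k else eb[1]
            best = max(best, len(inc[i] & inc[j]) / len(inc[i] | inc[j]))
        sims[(ea, eb)] = best
    levels = sorted({0.0} | set(sims.values()))
    best_d = 0.0  # the all-singletons partition has density 0
    for s in levels:
        if s <= 0:
            continue
        eg = nx.Graph()
        eg.add_nodes_from(edges)
        eg.add_edges_from(pair for pair, v in sims.items() if v >= s)
        comms = [set(c) for c in nx.connected_components(eg)]
        best_d = max(best_d, partition_density(comms, m))
    return best_d


class TestMapSnpsToGenes:
    ann = pd.DataFrame(
        {
            "gene": ["A", "B", "C"],
            "chrom": [1, 1, 1],
            "start": [1_000_000, 5_000_000, 9_000_000],
            "end": [1_100_000, 5_100_000, 9_100_000],
        }
    )

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (1_050_000, "A"),  # inside the body, distance 0
            (4_000_001, "B"),  # 999,999 bp upstream of B, > 1 Mb from others
            (1_150_000, "A"),  # 50 kb past A's end, nearest gene wins
        ],
    )
    def test_assignment(self, pos, expected):
        snps = pd.DataFrame({"snp": ["s"], "chrom": [1], "pos": [pos]})
        mapping, _ = epistasis.map_snps_to_genes(snps, self.ann)
        assert mapping.get("s") == expected

    def test_exact_tie_goes_to_smaller_gene_id(self):
        snps = pd.DataFrame({"snp": ["s"], "chrom": [1], "pos": [3_050_000]})
        # 3,050,000 is 1,950,000 past A's end and 1,950,000 before B's start
        ann = self.ann.copy()
        ann.loc[0, "end"] = 2_550_000
        ann.loc[1, "start"] = 3_550_000  # both 500 kb away
        mapping, _ = epistasis.map_snps_to_genes(snps, ann)
        assert mapping["s"] == "A"

    def test_unassigned_reported(self):
        snps = pd.DataFrame({"snp": ["far"], "chrom": [2], "pos": [100]})
        mapping, unassigned = epistasis.map_snps_to_genes(snps, self.ann)
        assert unassigned == ["far"] and not mapping


class TestBuildGeneNetwork:
    def make_im(self, q_pairs):
        n = 4
        G = np.zeros((n, n))
        q = np.ones((n, n))
        for (i, j), (qv, s) in q_pairs.items():
            q[i, j] = q[j, i] = qv
            G[i, j] = G[j, i] = s
        return InteractionMatrix([f"rs{i}" for i in range(n)], G, np.ones((n, n)), q)

    def test_max_weight_and_self_loop_rules(self):
        im = self.make_im({(0, 1): (0.001, 2.1), (2, 3): (0.001, 3.4), (0, 2): (0.5, 9.0)})
        snp2gene = {"rs0": "gA", "rs1": "gB", "rs2": "gA", "rs3": "gB"}
        net = epistasis.build_gene_network(im, snp2gene)
        # both significant pairs map to (gA, gB): one edge, max weight
        assert net.edges == [("gA", "gB")]
        assert net.graph["gA"]["gB"]["weight"] == 3.4

    def test_intra_gene_pair_discarded_and_empty_ok(self):
        im = self.make_im({(0, 1): (0.001, 2.0)})
        net = epistasis.build_gene_network(im, {"rs0": "gA", "rs1": "gA"})
        assert net.graph.number_of_edges() == 0
        net2 = epistasis.build_gene_network(self.make_im({}), {"rs0": "gA"})
        assert net2.graph.number_of_edges() == 0

    def test_invariant_to_snp_ordering(self):
        im = self.make_im({(0, 1): (0.001, 2.1), (1, 2): (0.002, 1.5)})
        perm = [2, 0, 3, 1]
        im2 = InteractionMatrix(
            [im.snp_ids[i] for i in perm],
            im.G[np.ix_(perm, perm)],
            im.p[np.ix_(perm, perm)],
            im.q[np.ix_(perm, perm)],
        )
        s2g = {"rs0": "gA", "rs1": "gB", "rs2": "gC", "rs3": "gD"}
        e1 = set(epistasis.build_gene_network(im, s2g).edges)
        e2 = set(epistasis.build_gene_network(im2, s2g).edges)
        assert e1 == e2


class TestLinkCommunities:
    def test_two_triangles_sharing_a_node(self):
        """Shared node bridges exactly two link communities."""
        g = nx.Graph(
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e"), ("c", "e")]
        )
        net = epistasis.link_communities(GeneNetwork(graph=g))
        assert len(set(net.link_communities.values())) == 2
        assert net.centrality["c"] == 2
        assert all(net.centrality[v] == 1 for v in "abde")
        d = partition_density(
            [
                {e for e, c in net.link_communities.items() if c == k}
                for k in set(net.link_communities.values())
            ],
            6,
        )
        assert d == pytest.approx(lc_oracle_best_density(g))

    def test_single_clique_is_one_community(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        net = epistasis.link_communities(GeneNetwork(graph=g))
        assert len(set(net.link_communities.values())) == 1
        assert set(net.centrality.values()) == {1}

    def test_isolated_edge(self):
        net = epistasis.link_communities(GeneNetwork(graph=nx.Graph([("x", "y")])))
        assert net.link_communities == {("x", "y"): 1}
        assert net.centrality == {"x": 1, "y": 1}

    @pytest.mark.parametrize("seed", range(12))
    def test_cut_maximises_partition_density(self, seed):
        """Returned cut attains the oracle's best density (graphs <= 12 edges)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        g = nx.gnm_random_graph(n, min(12, int(rng.integers(3, 13))), seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        g = nx.relabel_nodes(g, str)
        if g.number_of_edges() == 0:
            pytest.skip("degenerate draw")
        net = epistasis.link_communities(GeneNetwork(graph=g))
        comms: dict[int, set] = {}
        for e, c in net.link_communities.items():
            comms.setdefault(c, set()).add(e)
        achieved = partition_density(list(comms.values()), g.number_of_edges())
        assert achieved == pytest.approx(lc_oracle_best_density(g), abs=1e-12)

    def test_centrality_bounded_by_degree(self):
        g = nx.relabel_nodes(nx.barbell_graph(4, 1), str)
        net = epistasis.link_communities(GeneNetwork(graph=g))
        for v in g.nodes:
            assert 1 <= net.centrality[v] <= g.degree(v)


class TestNetworkStats:
    def test_complete_graph_clustering(self):
        g = nx.relabel_nodes(nx.complete_graph(5), str)
        out = epistasis.network_stats(GeneNetwork(graph=g), rewires=3, seed=0)
        assert out["clustering"] == 1.0

    def test_path_graph_closed_form(self):
        g = nx.relabel_nodes(nx.path_graph(3), str)
        out = epistasis.network_stats(GeneNetwork(graph=g), rewires=3, seed=0)
        assert out["clustering"] == 0.0
        assert out["mean_shortest_path"] == pytest.approx(4 / 3)

    def test_small_world_graph_has_sigma_above_one(self):
        hits = 0
        for seed in range(10):
            g = nx.connected_watts_strogatz_graph(120, 6, 0.1, seed=seed)
            g = nx.relabel_nodes(g, str)
            out = epistasis.network_stats(GeneNetwork(graph=g), rewires=8, seed=seed)
            hits += out["sigma"] > 1
        assert hits >= 9


class TestTopCentralGenes:
    def net_with_centrality(self, cent, degrees=None):
        g = nx.Graph()
        for v in cent:
            g.add_node(v)
        net = GeneNetwork(graph=g)
        net.centrality = dict(cent)
        return net

    def test_fraction_one_returns_all(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        net = epistasis.link_communities(GeneNetwork(graph=g))
        assert set(epistasis.top_central_genes(net, 1.0)) == set(g.nodes)

    def test_top_decile_and_tie_rule(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")])
        net = epistasis.link_communities(GeneNetwork(graph=g))
        top = epistasis.top_central_genes(net, 0.10)
        assert len(top) == 1
        # deterministic across repeated calls
        assert top == epistasis.top_central_genes(net, 0.10)
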