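"""Metastasis disease-module assembly and topology scoring.

Seed genes from three expression screens (differential expression,
stemness correlation, metastasis expression index) are merged and expanded
over the regulatory network with the DIAMOnD algorithm, which at each step
adds the node whose connectivity to the current module is most
hypergeometrically surprising. The resulting subnetwork is characterised
by modularity communities with gene-set over-representation, and by the
bow-tie score b(v) = S_v * T_v / (S * T) — the fraction of source-TF /
target reach combinations routed through v — whose positive-score genes
form the network core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm
from statsmodels.stats.multitest import multipletests

from .types import RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass
class SeedSet:
    de_genes: set[str]
    stemness_genes: set[str]
    index_genes: set[str]
    union: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.union = self.de_genes | self.stemness_genes | self.index_genes

    def sizes(self) -> dict[str, int]:
        return {
            "de": len(self.de_genes),
            "stemness": len(self.stemness_genes),
            "index": len(self.index_genes),
            "union": len(self.union),
        }


def merge_seeds(
    de: set[str] | list[str],
    stemness: set[str] | list[str],
    index_screen: set[str] | list[str],
) -> SeedSet:
    """Union of the three metastasis seed sources (per-source kept)."""
    seeds = SeedSet(set(de), set(stemness), set(index_screen))
    if not seeds.union:
        raise ValueError("seed union is empty")
    return seeds


def diamond_expand(
    graph: nx.Graph | RegulatoryNetwork,
    seeds: set[str] | list[str],
    n_iter: int = 200,
) -> pd.DataFrame:
    """DIAMOnD module expansion.

    ``graph`` may be an undirected graph or a regulatory network (directed
    edges treated as undirected for connectivity). At each step, every
    candidate node with ``k_s`` links into the module out of degree ``k``
    is scored with the hypergeometric tail P(X >= k_s) (population = all
    nodes, successes = current module size); the minimum-p node is added
    (ties: higher k_s, then smaller id). Stops early when nothing connects.

    Returns the added genes in order with columns ``gene, step, p``.
    """
    if isinstance(graph, RegulatoryNetwork):
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_edges_from(zip(graph.edges["tf"], graph.edges["target"]))
        graph = g
    module = set(seeds) & set(graph.nodes)
    if not module:
        raise ValueError("no seed gene is present in the network")
    n_total = graph.number_of_nodes()
    added = []
    for step in range(1, n_iter + 1):
        best = None
        s = len(module)
        for node in graph.nodes:
            if node in module:
                continue
            k = graph.degree(node)
            k_s = sum(1 for nb in graph.neighbors(node) if nb in module)
            if k_s == 0:
                continue
            p = float(hypergeom.sf(k_s - 1, n_total, s, k))
            key = (p, -k_s, node)
            if best is None or key < best[0]:
                best = (key, node, p)
        if best is None:
            logger.info("diamond_expand: no connected candidate at step %d", step)
            break
        module.add(best[1])
        added.append((best[1], step, best[2]))
    return pd.DataFrame(added, columns=["gene", "step", "p"])


def bowtie(net: RegulatoryNetwork) -> pd.DataFrame:
    """Bow-tie scores on the directed TF->target network.

    S_v counts the source TFs that can reach v (excluding v itself), T_v
    the targets v can reach (excluding itself); S and T are the total
    source-TF and target counts. b(v) = S_v*T_v/(S*T); the core is the set
    of genes with b > 0. Returns per-gene columns ``S_v, T_v, b, core``.
    """
    g = nx.DiGraph()
    g.add_edges_from(zip(net.edges["tf"], net.edges["target"]))
    nodes = sorted(g.nodes)
    # fan-in component: the declared TFs; fan-out component: sink genes
    # (in a strictly bipartite TF->target map the sinks are exactly the
    # non-TF genes; intermediates that both receive and emit edges form
    # the candidate core)
    sources = {v for v in nodes if v in net.tfs}
    targets = {v for v in nodes if g.out_degree(v) == 0}
    S, T = len(sources), len(targets)
    rows = []
    if S == 0 or T == 0:
        logger.warning("bowtie: no sources or no targets; all scores zero")
    for v in nodes:
        anc = nx.ancestors(g, v)
        dec = nx.descendants(g, v)
        s_v = len(anc & sources)
        t_v = len(dec & targets)
        b = (s_v * t_v) / (S * T) if S > 0 and T > 0 else 0.0
        rows.append((v, s_v, t_v, b, b > 0))
    return pd.DataFrame(rows, columns=["gene", "S_v", "T_v", "b", "core"]).set_index(
        "gene"
    )


def read_gmt(path: str) -> dict[str, set[str]]:
    """Parse a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def communities_and_enrichment(
    net: RegulatoryNetwork,
    gene_sets: dict[str, set[str]],
    q_max: float = 0.001,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Modularity communities plus per-community gene-set enrichment.

    Communities come from greedy modularity optimisation on the undirected
    projection (deterministic). For every (community, gene set) pair a
    hypergeometric over-representation p is computed with universe = the
    network's nodes, then BH-adjusted across all pairs; rows with
    q < q_max are flagged ``enriched``.
    """
    if not gene_sets:
        raise ValueError("gene_sets must be non-empty")
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(zip(net.edges["tf"], net.edges["target"]))
    comms = list(nx.algorithms.community.greedy_modularity_communities(g))
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    labels = {v: i + 1 for i, comm in enumerate(comms) for v in comm}
    universe = set(g.nodes)
    n_u = len(universe)
    rows = []
    for i, comm in enumerate(comms):
        comm_set = set(comm)
        for name, genes in sorted(gene_sets.items()):
            in_universe = genes & universe
            k = len(comm_set & in_universe)
            p = float(hypergeom.sf(k - 1, n_u, len(in_universe), len(comm_set)))
            rows.append((i + 1, name, k, len(comm_set), len(in_universe), p))
    table = pd.DataFrame(
        rows, columns=["community", "gene_set", "overlap", "community_size", "set_size", "p"]
    )
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["enriched"] = table["q"] < q_max
    return labels, table


def proportion_ztest(hits: int, n: int, p0: float) -> tuple[float, float]:
    """One-proportion z-test, upper tail (overrepresentation direction)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    if n * p0 < 5:
        logger.warning(
            "proportion_ztest: n*p0=%.2f < 5, normal approximation questionable",
            n * p0,
        )
    z = (hits / n - p0) / np.sqrt(p0 * (1 - p0) / n)
    return float(z), float(norm.sf(z))


def map_to_grn(
    central_genes: list[str] | set[str], net: RegulatoryNetwork
) -> dict[str, set[str]]:
    """Intersect a gene list with the regulatory network.

    Returns the mapped genes, the TF subset among them, and the targets
    those TFs regulate within the network.
    """
    central = set(central_genes)
    nodes = net.nodes
    mapped = central & nodes
    if not mapped:
        logger.warning("map_to_grn: no central gene maps to the regulatory network")
    tf_subset = mapped & net.tfs
    regs = net.regulons
    targets_of_tfs: set[str] = set()
    for tf in tf_subset:
        targets_of_tfs |= regs.get(tf, set())
    return {"mapped": mapped, "tfs": tf_subset, "targets_of_tfs": targets_of_tfs}
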