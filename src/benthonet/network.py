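"""Graph assembly, module detection, topology, and group comparison.

Builds an undirected co-occurrence graph from the filtered edge table
(nodes are OTUs with at least one retained edge), detects modules by
Louvain modularity maximization on the unweighted, sign-ignored graph, and
summarizes topology with the standard indices used to compare microbial
networks: average degree, average local clustering coefficient, modularity
Q, average shortest path on the largest connected component, and a
descriptive log-log degree-distribution regression as a scale-free
diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AbundanceTable, PipelineConfig
from . import association
from .contamination import compare_groups_ranksum

logger = logging.getLogger("benthonet")


@dataclass
class CooccurrenceNetwork:
    """Undirected OTU co-occurrence graph with taxonomy/module attributes."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def domain_fractions(self) -> dict:
        if self.n_nodes == 0:
            return {}
        domains = [d.get("domain", "Unclassified") for _, d in self.graph.nodes(data=True)]
        vals, counts = np.unique(domains, return_counts=True)
        return {v: c / self.n_nodes for v, c in zip(vals, counts)}


def build(edges: pd.DataFrame, taxonomy: pd.DataFrame | None = None) -> CooccurrenceNetwork:
    """Assemble the graph from an edge table (otu_a, otu_b, rho, p, sign).

    Isolated OTUs never appear (the graph only has edge endpoints).
    Duplicate pairs are collapsed with a warning.  Node attributes carry
    the domain and class-level taxonomy ("Unclassified" when unknown) and
    the degree.
    """
    g = nx.Graph()
    if len(edges) == 0:
        warnings.warn("empty edge list: building an empty network", stacklevel=2)
        return CooccurrenceNetwork(graph=g)
    seen = set()
    for row in edges.itertuples(index=False):
        key = tuple(sorted((row.otu_a, row.otu_b)))
        if key[0] == key[1]:
            warnings.warn(f"self-edge on {key[0]!r} skipped", stacklevel=2)
            continue
        if key in seen:
            warnings.warn(f"duplicate edge {key} collapsed", stacklevel=2)
            continue
        seen.add(key)
        g.add_edge(row.otu_a, row.otu_b, rho=float(row.rho), p=float(row.p),
                   sign=str(row.sign))
    for node in g.nodes:
        if taxonomy is not None and node in taxonomy.index:
            g.nodes[node]["domain"] = str(taxonomy.loc[node].get("domain", "Unclassified"))
            g.nodes[node]["class"] = str(taxonomy.loc[node].get("class", "Unclassified"))
        else:
            g.nodes[node]["domain"] = "Unclassified"
            g.nodes[node]["class"] = "Unclassified"
        g.nodes[node]["degree"] = g.degree(node)
    net = CooccurrenceNetwork(graph=g)
    logger.info("build: network with %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def detect_modules(net: CooccurrenceNetwork, resolution: float = 1.0,
                   seed: int = 0) -> dict:
    """Louvain modules on the unweighted graph, numbered by decreasing size.

    Returns {otu_id: module_number} with modules numbered from 1.  Edge
    signs and weights are ignored (plain topological modularity).  Module
    numbers are also written onto the graph nodes as the "module"
    attribute.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        return {}
    communities = nx.community.louvain_communities(
        g, weight=None, resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    assignment = {}
    for num, members in enumerate(communities, start=1):
        for node in members:
            assignment[node] = num
            g.nodes[node]["module"] = num
    return assignment


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    modularity: float
    average_shortest_path: float
    powerlaw_slope: float
    powerlaw_r2: float

    def to_dict(self) -> dict:
        return asdict(self)


def modularity_q(graph: nx.Graph, assignment: dict) -> float:
    """Newman modularity of a node partition of an unweighted graph."""
    communities: dict = {}
    for node, mod in assignment.items():
        communities.setdefault(mod, set()).add(node)
    return float(nx.community.modularity(graph, communities.values(), weight=None))


def topology(net: CooccurrenceNetwork, modules: dict | None = None,
             seed: int = 0) -> TopologySummary:
    """Topological summary of the network.

    Average local clustering counts degree-<2 nodes as 0; average shortest
    path is over the largest connected component; modularity Q is that of
    the supplied (or freshly detected) module partition; the scale-free
    diagnostic is the slope and R^2 of a log-log regression of the degree
    histogram.
    """
    g = net.graph
    if g.number_of_nodes() < 2 or g.number_of_edges() == 0:
        nan = float("nan")
        return TopologySummary(g.number_of_nodes(), g.number_of_edges(),
                               nan, nan, nan, nan, nan, nan)
    if modules is None:
        modules = detect_modules(net, seed=seed)
    degrees = np.array([d for _, d in g.degree()])
    avg_deg = float(2 * g.number_of_edges() / g.number_of_nodes())
    avg_clust = float(nx.average_clustering(g, count_zeros=True))
    q = modularity_q(g, modules)
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    avg_path = float(nx.average_shortest_path_length(giant)) if giant.number_of_nodes() > 1 else float("nan")
    slope, r2 = _powerlaw_diagnostic(degrees)
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        average_degree=avg_deg,
        average_clustering=avg_clust,
        modularity=q,
        average_shortest_path=avg_path,
        powerlaw_slope=slope,
        powerlaw_r2=r2,
    )


def _powerlaw_diagnostic(degrees: np.ndarray) -> tuple[float, float]:
    vals, counts = np.unique(degrees[degrees > 0], return_counts=True)
    if len(vals) < 3:
        return float("nan"), float("nan")
    x = np.log(vals)
    y = np.log(counts / counts.sum())
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def split_and_compare(
    table: AbundanceTable,
    core_otus: list[str],
    labels: pd.Series,
    config: PipelineConfig | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> dict:
    """Rebuild edge tables and networks for contaminated vs pristine
    sample groups and compare their topology.

    The core OTU set is fixed; the sample set is split by ``labels``
    (values "contaminated"/"pristine"), correlations are recomputed within
    each group, and per-node degree and clustering distributions are
    compared by two-sided rank-sum tests.  Returns a dict with per-group
    TopologySummary objects, the comparison p-values, and the networks.
    A group whose network is empty yields NaN comparisons.
    """
    config = config or PipelineConfig()
    out: dict = {"groups": {}, "comparison": {}}
    nets = {}
    for label in ("pristine", "contaminated"):
        samples = [s for s in table.sample_ids if labels.get(s) == label]
        if len(samples) < 4:
            raise ValueError(f"group {label!r} has {len(samples)} samples; need >= 4")
        sub = table.subset_samples(samples).subset_otus(core_otus)
        edges = association.edge_table(sub, config)
        net = build(edges, taxonomy)
        modules = detect_modules(net, seed=config.random_seed)
        nets[label] = net
        out["groups"][label] = {
            "n_samples": len(samples),
            "topology": topology(net, modules),
            "network": net,
        }
    for metric, getter in (
        ("degree", lambda g: [d for _, d in g.degree()]),
        ("clustering", lambda g: list(nx.clustering(g).values())),
    ):
        vals = {lab: getter(nets[lab].graph) for lab in nets}
        if any(len(v) < 2 for v in vals.values()):
            out["comparison"][metric] = {"p": float("nan"), "significant": None}
            continue
        _, p = compare_groups_ranksum(vals["pristine"], vals["contaminated"])
        out["comparison"][metric] = {"p": p, "significant": bool(p < 0.05)}
    return out
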