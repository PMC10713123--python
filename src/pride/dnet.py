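"""Turn posterior summaries into a differential network.

An edge (gene j, gene k) is included when its posterior inclusion
probability reaches the chosen threshold (0.5 by default); its intensity is
the posterior mean of the interaction coefficient beta_jk. Higher thresholds
carve out nested subnets, and node degrees highlight hubs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import pandas as pd

from .screening import n_pairs
from .ssl_posterior import PosteriorSummary

__all__ = [
    "DNetEdge",
    "DifferentialNetwork",
    "build_dnet",
    "subnet",
    "rank_edges",
    "hub_degrees",
    "sparsity",
    "write_edge_list",
    "to_graphml",
]


@dataclass(frozen=True)
class DNetEdge:
    gene_j: str
    gene_k: str
    probability: float
    intensity: float


@dataclass(frozen=True)
class DifferentialNetwork:
    """Thresholded edge list over the full node set."""

    edges: tuple
    threshold: float
    node_set: tuple

    def __post_init__(self):
        seen = set()
        for e in self.edges:
            if not (0.0 <= e.probability <= 1.0):
                raise ValueError("edge probability outside [0, 1]")
            if e.probability < self.threshold:
                raise ValueError("edge below the network threshold")
            key = frozenset((e.gene_j, e.gene_k))
            if key in seen:
                raise ValueError(f"duplicate edge {e.gene_j}-{e.gene_k}")
            seen.add(key)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _edge_sort_key(e: DNetEdge):
    # probability desc, then |intensity| desc, then lexicographic pair
    return (-e.probability, -abs(e.intensity), e.gene_j, e.gene_k)


def _summary_edges(summary: PosteriorSummary) -> list:
    names = summary.gene_names
    edges = []
    for idx, (j, k) in enumerate(summary.pair_index):
        gj = names[j] if names else str(j)
        gk = names[k] if names else str(k)
        if gk < gj:
            gj, gk = gk, gj
        edges.append(
            DNetEdge(
                gene_j=gj,
                gene_k=gk,
                probability=float(summary.inclusion_prob[idx]),
                intensity=float(summary.beta_mean[idx]),
            )
        )
    return edges


def build_dnet(summary: PosteriorSummary, threshold: float = 0.5) -> DifferentialNetwork:
    """Edges with inclusion probability >= threshold, sorted by probability."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    edges = [e for e in _summary_edges(summary) if e.probability >= threshold]
    edges.sort(key=_edge_sort_key)
    nodes = tuple(summary.gene_names) if summary.gene_names else tuple(
        sorted({str(i) for pair in summary.pair_index for i in pair})
    )
    return DifferentialNetwork(edges=tuple(edges), threshold=threshold, node_set=nodes)


def subnet(
    network: DifferentialNetwork,
    higher_threshold: float,
    restrict_nodes: bool = False,
) -> DifferentialNetwork:
    """Sub-network at a more stringent probability cutoff."""
    if higher_threshold < network.threshold:
        raise ValueError(
            f"subnet threshold {higher_threshold} is below the parent's {network.threshold}"
        )
    edges = tuple(e for e in network.edges if e.probability >= higher_threshold)
    nodes = network.node_set
    if restrict_nodes:
        nodes = tuple(sorted({g for e in edges for g in (e.gene_j, e.gene_k)}))
    return DifferentialNetwork(edges=edges, threshold=higher_threshold, node_set=nodes)


def rank_edges(summary: PosteriorSummary) -> list:
    """All candidate edges ordered by probability (ties: |intensity|, then name)."""
    return sorted(_summary_edges(summary), key=_edge_sort_key)


def hub_degrees(network: DifferentialNetwork) -> dict:
    """Node -> number of incident retained edges; isolated nodes get 0."""
    deg = {node: 0 for node in network.node_set}
    for e in network.edges:
        deg[e.gene_j] = deg.get(e.gene_j, 0) + 1
        deg[e.gene_k] = deg.get(e.gene_k, 0) + 1
    return deg


def sparsity(num_edges: int, P: int) -> float:
    """Percentage of realized pairs, 100 * E / (P(P-1)/2), to one decimal.

    Rounded half-up (so 3.45 -> 3.5), matching how network sparsities are
    conventionally tabulated.
    """
    phi = n_pairs(P)
    if num_edges < 0:
        raise ValueError("edge count cannot be negative")
    if num_edges > phi:
        raise ValueError(f"{num_edges} edges exceed the {phi} possible pairs")
    pct = Decimal(100 * num_edges) / Decimal(phi)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def to_networkx(network: DifferentialNetwork) -> nx.Graph:
    """Undirected graph with probability/intensity edge attributes and degree."""
    g = nx.Graph()
    g.add_nodes_from(network.node_set)
    for e in network.edges:
        g.add_edge(e.gene_j, e.gene_k, probability=e.probability, intensity=e.intensity)
    degrees = hub_degrees(network)
    nx.set_node_attributes(g, degrees, "degree")
    return g


def to_graphml(network: DifferentialNetwork, path) -> None:
    nx.write_graphml(to_networkx(network), path)


def write_edge_list(network: DifferentialNetwork, path) -> None:
    """TSV with columns gene_j, gene_k, probability, intensity."""
    pd.DataFrame(
        [(e.gene_j, e.gene_k, e.probability, e.intensity) for e in network.edges],
        columns=["gene_j", "gene_k", "probability", "intensity"],
    ).to_csv(path, sep="\t", index=False)
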