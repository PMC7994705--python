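"""Per-node graph measures: degree, betweenness, clustering, hub calls.

Degree is the binary connection count.  Betweenness centrality counts
shortest paths through a node (fractional credit for ties, endpoints
excluded) with edge length 1/weight by default, so strong correlations are
short.  Clustering is Onnela's weighted coefficient,
C_i = 2/(k_i (k_i-1)) * sum_{j<h} (w'_ij w'_ih w'_jh)^(1/3) with w' = w/max w.
Normalized betweenness divides by the network mean, b_i = B_i / <B>, and a
node is a hub when b_i exceeds the conventional 1.7 cutoff (strictly).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import BrainGraph

HUB_CUTOFF = 1.7


def degree(g: BrainGraph) -> np.ndarray:
    """Number of nonzero incident edges per node."""
    return (g.weights > 0).sum(axis=1).astype(int)


def betweenness(g: BrainGraph, length_transform: str = "inv") -> np.ndarray:
    """Exact weighted betweenness centrality, unnormalized.

    Shortest paths are computed on edge lengths ``1/w`` (``inv``, default) or
    ``1 - w`` (``sub``); ties share credit fractionally; pairs in different
    components contribute nothing.
    """
    gx = g.to_networkx(length_transform=length_transform)
    bc = nx.betweenness_centrality(gx, normalized=False, weight="length")
    return np.array([bc[i] for i in range(g.n_nodes)])


def clustering(g: BrainGraph) -> np.ndarray:
    """Onnela weighted clustering coefficient per node (0 when k_i < 2)."""
    gx = g.to_networkx()
    cc = nx.clustering(gx, weight="weight")
    return np.array([cc[i] for i in range(g.n_nodes)])


def normalized_betweenness(b: np.ndarray) -> np.ndarray:
    """b_i = B_i / <B>; the mean of the result is exactly 1."""
    b = np.asarray(b, dtype=float)
    mean = b.mean()
    if mean <= 0:
        raise ValueError(
            "mean betweenness is zero (e.g. a complete graph); normalized "
            "betweenness and hubs are undefined"
        )
    return b / mean


def identify_hubs(
    b_norm: np.ndarray,
    node_names: tuple[str, ...] | None = None,
    cutoff: float = HUB_CUTOFF,
) -> list[tuple[str, float]]:
    """Nodes with b_i strictly above the cutoff, strongest first."""
    b_norm = np.asarray(b_norm, dtype=float)
    names = node_names or tuple(f"ROI_{i+1}" for i in range(len(b_norm)))
    idx = np.flatnonzero(b_norm > cutoff)
    order = idx[np.argsort(-b_norm[idx])]
    return [(names[i], float(b_norm[i])) for i in order]


@dataclass(frozen=True)
class NodeMetricTable:
    """Per-node measures for one graph, with provenance of the graph config."""

    table: pd.DataFrame
    graph_kind: str
    sparsity: float | None
    length_transform: str

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(self.table["roi_name"])


def node_metric_table(
    g: BrainGraph,
    length_transform: str = "inv",
    hub_cutoff: float = HUB_CUTOFF,
) -> NodeMetricTable:
    """Degree, betweenness, clustering, normalized betweenness and hub flag.

    On graphs where every betweenness is zero (e.g. the full graph, where all
    shortest paths are direct edges) normalized betweenness is undefined and
    reported as NaN with no hubs.
    """
    k = degree(g)
    b = betweenness(g, length_transform)
    c = clustering(g)
    if b.mean() > 0:
        bn = normalized_betweenness(b)
        hubs = bn > hub_cutoff
    else:
        bn = np.full(g.n_nodes, np.nan)
        hubs = np.zeros(g.n_nodes, dtype=bool)
    df = pd.DataFrame(
        {
            "roi_name": list(g.node_names),
            "degree": k,
            "betweenness": b,
            "clustering": c,
            "normalized_betweenness": bn,
            "is_hub": hubs,
        }
    )
    return NodeMetricTable(df, g.kind, g.sparsity, length_transform)
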