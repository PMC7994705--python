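"""Weighted brain-network construction: full graph, spanning tree, sparsity.

The full network correlates every pair of regional representative signals
(negatives zeroed, as for voxel pairs) and uses the correlation as edge
weight.  Two simplifications remove redundant edges while keeping the core
structure:

* the maximum-total-correlation spanning tree (Kruskal on descending weight;
  equivalently the minimum spanning tree on distance 1 - r), always n - 1
  edges over n nodes;
* sparsity thresholding, which keeps the round(S * n(n-1)/2) strongest edges
  for a sparsity fraction S — the standard sweep is S = 6%..36% in 6% steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .voxel_nodes import RoiSignalMatrix

logger = logging.getLogger(__name__)

DEFAULT_SPARSITIES = (0.06, 0.12, 0.18, 0.24, 0.30, 0.36)


@dataclass(frozen=True)
class BrainGraph:
    """Weighted undirected graph over parcellation regions.

    ``weights`` is symmetric with zero diagonal, entries in [0, 1].  ``kind``
    is one of ``full``, ``mst`` or ``sparsity`` (the latter carrying the
    requested sparsity fraction).
    """

    weights: np.ndarray = field(repr=False)
    kind: str = "full"
    sparsity: float | None = None
    node_names: tuple[str, ...] = ()
    achieved_sparsity: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < 0 or w.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        if not self.node_names:
            object.__setattr__(
                self, "node_names", tuple(f"ROI_{i+1}" for i in range(w.shape[0]))
            )
        if len(self.node_names) != w.shape[0]:
            raise ValueError("one name per node required")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int((self.weights > 0).sum() // 2)

    def edge_list(self) -> list[tuple[int, int, float]]:
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return [(int(a), int(b), float(self.weights[a, b])) for a, b in zip(i, j)]

    def to_networkx(self, length_transform: str | None = None) -> nx.Graph:
        """Graph with ``weight`` (and optionally ``length``) edge attributes."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for a, b, w in self.edge_list():
            attrs = {"weight": w}
            if length_transform == "inv":
                attrs["length"] = 1.0 / w
            elif length_transform == "sub":
                attrs["length"] = 1.0 - w
            elif length_transform is not None:
                raise ValueError(f"unknown length transform {length_transform!r}")
            g.add_edge(a, b, **attrs)
        return g


def full_network(signals: RoiSignalMatrix) -> BrainGraph:
    """Correlate all regional signals into the full weighted network.

    Applies the same zeroing rule as the voxel stage: negative correlations
    become 0 and the diagonal (self-correlation) is 0.
    """
    mat = np.asarray(signals.signals, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 regions")
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        bad = [int(signals.roi_labels[i]) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant representative series for region(s) {bad}")
    w = np.corrcoef(mat)
    np.fill_diagonal(w, 0.0)
    w = np.clip(w, 0.0, 1.0)
    w = (w + w.T) / 2.0
    names = tuple(signals.roi_names) or tuple(
        f"ROI_{int(l)}" for l in signals.roi_labels
    )
    return BrainGraph(w, kind="full", node_names=names)


def maximum_spanning_tree(g: BrainGraph) -> BrainGraph:
    """Kruskal spanning tree maximising total correlation.

    Edges are visited in descending weight and added whenever their endpoints
    lie in different trees; the result spans all n nodes with exactly n - 1
    edges.  Raises if the positive-weight subgraph is disconnected.
    """
    gx = g.to_networkx()
    n_comp = nx.number_connected_components(gx)
    if n_comp > 1:
        raise ValueError(
            f"positive-weight graph has {n_comp} components; spanning tree "
            "requires a connected graph"
        )
    tree = nx.maximum_spanning_tree(gx, weight="weight", algorithm="kruskal")
    w = np.zeros_like(g.weights)
    for a, b in tree.edges:
        w[a, b] = w[b, a] = g.weights[a, b]
    return BrainGraph(w, kind="mst", node_names=g.node_names)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def n_edges_at_sparsity(n_nodes: int, s: float) -> int:
    """Edge budget round(S * n(n-1)/2), rounding half away from zero."""
    return _round_half_away(s * n_nodes * (n_nodes - 1) / 2.0)


def threshold_by_sparsity(
    g: BrainGraph, s: float, ensure_connected: bool = False
) -> BrainGraph:
    """Keep the E(S) strongest edges of the full graph.

    Ties at the cut are broken deterministically by ascending (i, j) index.
    If fewer positive edges exist than the budget, all positive edges are kept
    with a warning and the achieved sparsity is recorded.  With
    ``ensure_connected`` the spanning-tree edges are unioned in so the result
    is connected (the achieved sparsity then reflects the union).
    """
    if not 0 < s <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    n = g.n_nodes
    budget = n_edges_at_sparsity(n, s)
    if budget == 0:
        raise ValueError(f"sparsity {s} keeps zero edges on {n} nodes")
    edges = g.edge_list()
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    if budget > len(edges):
        warnings.warn(
            f"sparsity {s} asks for {budget} edges but only {len(edges)} "
            "positive edges exist; keeping all of them",
            stacklevel=2,
        )
        kept = edges
    else:
        kept = edges[:budget]
    w = np.zeros_like(g.weights)
    for a, b, wt in kept:
        w[a, b] = w[b, a] = wt
    if ensure_connected:
        tree = maximum_spanning_tree(g)
        w = np.maximum(w, tree.weights)
    achieved = (w > 0).sum() / 2.0 / (n * (n - 1) / 2.0)
    return BrainGraph(
        w,
        kind="sparsity",
        sparsity=s,
        node_names=g.node_names,
        achieved_sparsity=float(achieved),
    )


def sparsity_sweep(
    g: BrainGraph,
    s_values: tuple[float, ...] = DEFAULT_SPARSITIES,
    ensure_connected: bool = False,
) -> list[BrainGraph]:
    """One thresholded graph per sparsity value; edge sets are nested."""
    return [threshold_by_sparsity(g, s, ensure_connected) for s in s_values]
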