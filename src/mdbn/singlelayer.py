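"""Seven weighted-graph metrics on single-layer (per-window) networks.

Connection weights are PLI values, so a stronger edge means a shorter
functional distance: shortest-path metrics (path length, local efficiency,
betweenness) map weight to length by the reciprocal, ``d_ij = 1 / w_ij``.

Metrics: node strength (NS), characteristic path length per node (PL),
local efficiency (E-loc), betweenness centrality (BC), eigenvector
centrality (EC), clustering coefficient (CC, Onnela weighted form, per node
plus global mean), and strength assortativity (Ass, global).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "LayerGraph",
    "node_strength",
    "path_length",
    "local_efficiency",
    "betweenness",
    "eigenvector_centrality",
    "clustering_coefficient",
    "assortativity",
    "metric_sweep",
    "LOCAL_METRICS",
    "GLOBAL_METRICS",
]

LOCAL_METRICS = ("NS", "PL", "E-loc", "BC", "EC")
GLOBAL_METRICS = ("CC", "Ass")


@dataclass
class LayerGraph:
    """Symmetric non-negative weight matrix with optional channel names."""

    weights: np.ndarray
    channel_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if self.weights.min() < 0:
            raise ValueError("weights must be non-negative")
        if self.channel_names is None:
            self.channel_names = [f"CH{i}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(ii, jj):
            w = self.weights[i, j]
            g.add_edge(int(i), int(j), weight=w, length=1.0 / w)
        return g


def _as_graph(g) -> LayerGraph:
    return g if isinstance(g, LayerGraph) else LayerGraph(np.asarray(g))


def node_strength(g) -> np.ndarray:
    """NS_i = sum of weights of edges incident to node i."""
    return _as_graph(g).weights.sum(axis=1)


def path_length(g) -> np.ndarray:
    """Mean shortest-path distance from each node to every other node.

    Distances use reciprocal-weight edge lengths.  Unreachable pairs are
    excluded from the mean; a fully isolated node is flagged NaN.
    """
    lg = _as_graph(g)
    G = lg.to_networkx()
    out = np.full(lg.n_nodes, np.nan)
    for i in range(lg.n_nodes):
        dist = nx.single_source_dijkstra_path_length(G, i, weight="length")
        finite = [d for j, d in dist.items() if j != i]
        if finite:
            out[i] = float(np.mean(finite))
    return out


def _efficiency(weights: np.ndarray) -> float:
    """Global efficiency of a weight matrix: mean of 1/d over node pairs."""
    n = weights.shape[0]
    if n < 2:
        return 0.0
    G = LayerGraph(weights).to_networkx()
    inv_sum = 0.0
    for i in range(n):
        dist = nx.single_source_dijkstra_path_length(G, i, weight="length")
        for j, d in dist.items():
            if j != i and d > 0:
                inv_sum += 1.0 / d
    return inv_sum / (n * (n - 1))


def local_efficiency(g) -> np.ndarray:
    """Efficiency of each node's neighborhood subgraph.

    E-loc_i is the global efficiency of the subgraph induced by i's
    neighbors (harmonic mean of inter-neighbor distances); nodes with fewer
    than two neighbors score 0.
    """
    lg = _as_graph(g)
    out = np.zeros(lg.n_nodes)
    for i in range(lg.n_nodes):
        nbrs = np.flatnonzero(lg.weights[i] > 0)
        if len(nbrs) < 2:
            continue
        out[i] = _efficiency(lg.weights[np.ix_(nbrs, nbrs)])
    return out


def betweenness(g) -> np.ndarray:
    """Normalized weighted betweenness centrality (reciprocal-weight lengths)."""
    lg = _as_graph(g)
    bc = nx.betweenness_centrality(lg.to_networkx(), weight="length", normalized=True)
    return np.array([bc[i] for i in range(lg.n_nodes)])


def eigenvector_centrality(g) -> np.ndarray:
    """Principal eigenvector of the weight matrix, unit max-norm.

    On a disconnected graph the centrality is computed on the largest
    connected component (by node count); other nodes get 0.
    """
    lg = _as_graph(g)
    W = lg.weights
    if not W.any():
        raise ValueError("eigenvector centrality undefined on an empty graph")
    G = lg.to_networkx()
    comp = max(nx.connected_components(G), key=len)
    idx = np.array(sorted(comp))
    sub = W[np.ix_(idx, idx)]
    vals, vecs = np.linalg.eigh(sub)
    v = vecs[:, -1]
    v = np.abs(v)  # Perron vector is sign-free; take the non-negative rep
    out = np.zeros(lg.n_nodes)
    out[idx] = v / v.max()
    return out


def clustering_coefficient(g) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node, plus the global (mean) value.

    Triangle intensity is the geometric mean of the three edge weights,
    normalized by the maximum weight in the graph, so uniform rescaling of
    all weights leaves CC unchanged.
    """
    lg = _as_graph(g)
    cc = nx.clustering(lg.to_networkx(), weight="weight")
    per_node = np.array([cc[i] for i in range(lg.n_nodes)])
    return per_node, float(per_node.mean())


def assortativity(g) -> float:
    """Pearson correlation of endpoint strengths over all edges.

    Each undirected edge contributes both orientations.  Returns NaN when
    there are fewer than two edges or the endpoint strengths have zero
    variance (e.g. a regular graph).
    """
    lg = _as_graph(g)
    ns = node_strength(lg)
    ii, jj = np.nonzero(np.triu(lg.weights, k=1))
    if len(ii) < 2:
        return float("nan")
    x = np.concatenate([ns[ii], ns[jj]])
    y = np.concatenate([ns[jj], ns[ii]])
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Sweep over (condition, band, window, trial) blocks
# ---------------------------------------------------------------------------

def metric_sweep(blocks: Iterable[tuple]) -> pd.DataFrame:
    """Compute all seven metrics for every labelled layer graph.

    ``blocks`` yields ``(condition, band, window, trial, graph)`` tuples,
    where ``graph`` is a :class:`LayerGraph` or a weight matrix.  Returns a
    long-form table with one row per (block, channel, metric): the five
    local metrics per channel, plus global CC and Ass rows with channel
    ``"GLOBAL"``.
    """
    rows = []
    for condition, band, window, trial, graph in blocks:
        lg = _as_graph(graph)
        names = lg.channel_names
        local = {
            "NS": node_strength(lg),
            "PL": path_length(lg),
            "E-loc": local_efficiency(lg),
            "BC": betweenness(lg),
            "EC": (
                eigenvector_centrality(lg)
                if lg.weights.any()
                else np.full(lg.n_nodes, np.nan)
            ),
        }
        cc_nodes, cc_global = clustering_coefficient(lg)
        base = {"condition": condition, "band": band, "window": window, "trial": trial}
        for metric, vals in local.items():
            for ch, v in zip(names, vals):
                rows.append({**base, "channel": ch, "metric": metric, "value": v})
        rows.append({**base, "channel": "GLOBAL", "metric": "CC", "value": cc_global})
        rows.append({**base, "channel": "GLOBAL", "metric": "Ass", "value": assortativity(lg)})
    return pd.DataFrame(rows)
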