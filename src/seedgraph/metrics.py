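"""Node- and network-level graph measures and hub classification.

All measures are computed on the binarized supra-threshold graph (the
modularity objective is the only consumer of the retained weights).
Definitions: unit edge lengths; characteristic path length averages over
connected ordered pairs and reports the unreachable count; efficiency
uses 1/inf = 0 for disconnected pairs; betweenness is normalized by
(n-1)(n-2)/2; local efficiency of a node is the global efficiency of its
neighbour subgraph.  Hubs are nodes whose degree AND betweenness lie at
least one sample standard deviation above the network mean; a connector
hub is a hub with the highest participation coefficient of its module.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import SignedAdjacency, ThresholdedGraph, threshold_graph

__all__ = [
    "degree",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "node_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "betweenness",
    "classify_hubs",
    "connector_hubs",
    "node_metrics_table",
    "summarize_over_thresholds",
]


def _graph(g: ThresholdedGraph | nx.Graph) -> nx.Graph:
    return g.graph if isinstance(g, ThresholdedGraph) else g


def degree(g: ThresholdedGraph | nx.Graph) -> np.ndarray:
    """Binary degree per node (node order = sorted node keys)."""
    graph = _graph(g)
    return np.array([graph.degree(u) for u in sorted(graph.nodes())], float)


def shortest_paths(g: ThresholdedGraph | nx.Graph) -> np.ndarray:
    """All-pairs shortest path lengths (unit edges), inf where unreachable."""
    graph = _graph(g)
    nodes = sorted(graph.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for u, lengths in nx.all_pairs_shortest_path_length(graph):
        for v, d in lengths.items():
            D[index[u], index[v]] = d
    return D


def characteristic_path_length(
    g: ThresholdedGraph | nx.Graph,
) -> tuple[float, int]:
    """Mean distance over connected ordered pairs, plus unreachable count."""
    D = shortest_paths(g)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_unreachable = int(off.sum() - finite.sum())
    if finite.sum() == 0:
        return float("nan"), n_unreachable
    return float(D[finite].mean()), n_unreachable


def global_efficiency(g: ThresholdedGraph | nx.Graph) -> float:
    """Mean inverse distance over ordered pairs (1/inf = 0)."""
    return float(nx.global_efficiency(_graph(g)))


def node_efficiency(g: ThresholdedGraph | nx.Graph) -> np.ndarray:
    """Per-node mean inverse distance to all other nodes."""
    D = shortest_paths(g)
    n = D.shape[0]
    if n < 2:
        return np.zeros(n)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(g: ThresholdedGraph | nx.Graph) -> np.ndarray:
    """Global efficiency of each node's neighbour subgraph (0 if < 2)."""
    graph = _graph(g)
    out = []
    for u in sorted(graph.nodes()):
        nbrs = list(graph.neighbors(u))
        if len(nbrs) < 2:
            out.append(0.0)
        else:
            out.append(nx.global_efficiency(graph.subgraph(nbrs)))
    return np.array(out, float)


def clustering_coefficient(g: ThresholdedGraph | nx.Graph) -> np.ndarray:
    """Binary local clustering coefficient per node."""
    graph = _graph(g)
    cc = nx.clustering(graph)
    return np.array([cc[u] for u in sorted(graph.nodes())], float)


def betweenness(g: ThresholdedGraph | nx.Graph) -> np.ndarray:
    """Betweenness centrality normalized by (n-1)(n-2)/2."""
    graph = _graph(g)
    bc = nx.betweenness_centrality(graph, normalized=True)
    return np.array([bc[u] for u in sorted(graph.nodes())], float)


def classify_hubs(
    degrees: np.ndarray, betweennesses: np.ndarray
) -> np.ndarray:
    """Hub = degree and betweenness both >= mean + 1 sample sd."""
    degrees = np.asarray(degrees, float)
    betweennesses = np.asarray(betweennesses, float)
    n = degrees.size
    if n < 3:
        raise ValueError("hub classification needs at least 3 nodes")
    k_cut = degrees.mean() + degrees.std(ddof=1)
    b_cut = betweennesses.mean() + betweennesses.std(ddof=1)
    # strict ">" against the mean keeps zero-variance (regular) metrics
    # from flagging every node when the sd collapses to 0
    return ((degrees >= k_cut) & (degrees > degrees.mean())
            & (betweennesses >= b_cut)
            & (betweennesses > betweennesses.mean()))


def connector_hubs(
    hub_flags: np.ndarray,
    participation: np.ndarray,
    labels: Sequence[int],
) -> np.ndarray:
    """Connector hub = hub with the maximal participation of its module.

    Ties at the module maximum flag all tied hubs.
    """
    hub_flags = np.asarray(hub_flags, bool)
    participation = np.asarray(participation, float)
    labels = np.asarray(labels)
    if not (hub_flags.size == participation.size == labels.size):
        raise ValueError("inputs must share length")
    out = np.zeros_like(hub_flags)
    for m in np.unique(labels):
        members = labels == m
        pmax = participation[members].max()
        out[members] = hub_flags[members] & np.isclose(
            participation[members], pmax
        )
    return out


def node_metrics_table(
    adj: SignedAdjacency, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Long-format per-node metrics at each threshold.

    Columns: node, threshold, degree, betweenness, node_efficiency,
    path_length (mean distance to reachable nodes), clustering, hub.
    """
    rows = []
    for tau in thresholds:
        g = threshold_graph(adj, tau)
        k = degree(g)
        b = betweenness(g)
        eff = node_efficiency(g)
        cc = clustering_coefficient(g)
        D = shortest_paths(g)
        hubs = classify_hubs(k, b)
        for i, node in enumerate(adj.node_ids):
            d_row = D[i][np.isfinite(D[i]) & (np.arange(len(adj.node_ids)) != i)]
            rows.append({
                "node": node,
                "threshold": tau,
                "degree": k[i],
                "betweenness": b[i],
                "node_efficiency": eff[i],
                "path_length": float(d_row.mean()) if d_row.size else np.nan,
                "clustering": cc[i],
                "hub": bool(hubs[i]),
            })
    return pd.DataFrame(rows)


def summarize_over_thresholds(table: pd.DataFrame) -> pd.DataFrame:
    """Threshold-averaged per-node summary with hub tiers.

    For every metric the per-node mean over thresholds is reported along
    with two flags per metric: ``*_above_mean`` (value above the network
    mean, the "yellow" tier) and ``*_top_tier`` (at least one sample sd
    above it, the "red" tier).  The overall ``hub`` flag applies the
    degree-and-betweenness hub rule to the threshold-averaged metrics.
    """
    metrics = ["degree", "betweenness", "node_efficiency", "path_length",
               "clustering"]
    wide = table.groupby("node", sort=False)[metrics].mean()
    for m in metrics:
        v = wide[m].to_numpy()
        mu, sd = np.nanmean(v), np.nanstd(v, ddof=1)
        wide[f"{m}_above_mean"] = v > mu
        wide[f"{m}_top_tier"] = v >= mu + sd
    wide["hub"] = classify_hubs(
        wide["degree"].to_numpy(), wide["betweenness"].to_numpy()
    )
    return wide.reset_index()
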