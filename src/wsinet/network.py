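"""Fold-change-weighted PPI networks and the weighted system impact score.

Each binary interaction is weighted with the inverse of the median of its
two endpoints' fold-change magnitudes (for two values the median is their
mean), so strongly regulated pairs sit *close* under shortest-path
distance.  On the main connected component, weighted closeness and
weighted betweenness are computed per protein and their sum is the
weighted system impact (wSI), a "dominance" score for a protein over the
network.

Sign handling: a downregulated pair would yield a negative distance, which
breaks shortest-path semantics, so edge weights use |FC| with a strictly
positive epsilon floor; the signed FC is kept as node metadata for
reporting.  Closeness is the standard (n-1)/sum-of-distances form and
betweenness uses the 2/((n-1)(n-2)) pair normalization so the two summands
share the same scale (a ``normalized=False`` escape hatch exists for the
raw quantities).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import FoldChangeTable, InteractionSet

logger = logging.getLogger("wsinet")


def build_network(
    fc: FoldChangeTable, interactions: InteractionSet, epsilon: float = 1e-6
) -> nx.Graph:
    """Weighted graph over the interactions whose endpoints both carry an FC.

    Edge weight w(u, v) = 1 / max(mean(|fc_u|, |fc_v|), epsilon); node
    attribute ``fc`` keeps the signed value.  Edges with an endpoint absent
    from the FC table are dropped (count logged).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    g = nx.Graph()
    dropped = 0
    for u, v in sorted(interactions.edges):
        if u not in fc or v not in fc:
            dropped += 1
            continue
        med = (abs(fc.entries[u]) + abs(fc.entries[v])) / 2.0  # median of 2 values
        w = 1.0 / max(med, epsilon)
        g.add_edge(u, v, weight=w)
    if dropped:
        logger.info("build_network: dropped %d edges lacking FC endpoints", dropped)
    if g.number_of_edges() == 0:
        raise ValueError("no interactions remain after restricting to the FC table")
    nx.set_node_attributes(g, {n: fc.entries[n] for n in g.nodes}, "fc")
    return g


def main_component(network: nx.Graph) -> nx.Graph:
    """The connected component with the most nodes (isolated sets deleted);
    size ties broken by the lexicographically smallest member id."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(network))
    max_size = max(len(c) for c in comps)
    candidates = [c for c in comps if len(c) == max_size]
    best = min(candidates, key=min)
    return network.subgraph(best).copy()


def weighted_centralities(network: nx.Graph, normalized: bool = True) -> pd.DataFrame:
    """Weighted closeness, weighted betweenness, and their sum (wSI).

    Distances are the edge weights; closeness(v) = (n-1)/sum_u d(v, u) and
    betweenness uses Brandes pair-dependency accumulation with the
    2/((n-1)(n-2)) normalization.  Requires a connected network (run
    :func:`main_component` first).  Returns a DataFrame sorted by node id
    with columns node, fc, closeness, betweenness, wsi.
    """
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    if not nx.is_connected(network):
        raise ValueError("network is disconnected; extract main_component first")
    if n < 3 and normalized:
        raise ValueError("betweenness normalization needs >= 3 nodes")
    closeness = nx.closeness_centrality(network, distance="weight")
    if not normalized:
        # raw form: inverse of the total distance to all other vertices
        closeness = {v: c / (n - 1) if n > 1 else 0.0 for v, c in closeness.items()}
    betweenness = nx.betweenness_centrality(
        network, weight="weight", normalized=normalized
    )
    nodes = sorted(network.nodes)
    fc = [network.nodes[v].get("fc", np.nan) for v in nodes]
    clo = [closeness[v] for v in nodes]
    btw = [betweenness[v] for v in nodes]
    return pd.DataFrame(
        {
            "node": nodes,
            "fc": fc,
            "closeness": clo,
            "betweenness": btw,
            "wsi": np.asarray(clo) + np.asarray(btw),
        }
    )


def wsi_rank(table: pd.DataFrame, k: int) -> list[str]:
    """Top-k nodes by wSI, descending, ties broken by node id (stable)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        logger.warning("wsi_rank: k=%d exceeds node count %d; returning all", k, len(table))
        k = len(table)
    ordered = table.sort_values(["wsi", "node"], ascending=[False, True], kind="stable")
    return list(ordered["node"].head(k))


def wsi_pipeline(
    fc: FoldChangeTable,
    interactions: InteractionSet,
    epsilon: float = 1e-6,
    normalized: bool = True,
) -> pd.DataFrame:
    """Build, restrict to the main component, and score in one call."""
    g = main_component(build_network(fc, interactions, epsilon=epsilon))
    return weighted_centralities(g, normalized=normalized)
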