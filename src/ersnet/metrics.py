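"""Node centralities and global network properties.

Strength is the sum of absolute edge weights at a node; bridge strength is
the part of that sum going to nodes outside the node's own group (emotion
regulation, depression, anxiety).  Global properties combine weighted-matrix
counts (edges, negative edges, density) with binarized-graph topology
(average path length, transitivity, mean local clustering): an edge is
present iff its weight is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import WeightedNetwork


def node_strength(net: WeightedNetwork) -> pd.Series:
    """strength_i = sum_j |w_ij|."""
    s = np.abs(net.weights).sum(axis=1)
    return pd.Series(s, index=net.node_ids, name="strength")


def bridge_strength(net: WeightedNetwork, groups: dict[str, str] | None = None) -> pd.Series:
    """Sum of |w_ij| over neighbours j in a different group than i."""
    groups = groups if groups is not None else net.groups
    if groups is None:
        raise ValueError("no group assignment available")
    missing = [n for n in net.node_ids if n not in groups]
    if missing:
        raise ValueError(f"nodes missing a group assignment: {missing}")
    labels = np.array([groups[n] for n in net.node_ids])
    cross = labels[:, None] != labels[None, :]
    s = (np.abs(net.weights) * cross).sum(axis=1)
    return pd.Series(s, index=net.node_ids, name="bridge_strength")


def centrality_table(net: WeightedNetwork, groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Strength and bridge strength per node, with z-scored columns for plots."""
    table = pd.DataFrame({"strength": node_strength(net)})
    if groups is not None or net.groups is not None:
        table["bridge_strength"] = bridge_strength(net, groups)
    for col in list(table.columns):
        sd = table[col].std(ddof=0)
        table[f"{col}_z"] = 0.0 if sd == 0 else (table[col] - table[col].mean()) / sd
    return table


@dataclass
class GlobalProperties:
    density: float
    n_edges: int
    n_negative_edges: int
    average_path_length: float
    transitivity: float
    clustering_coefficient: float
    connected: bool

    def to_dict(self) -> dict:
        return {
            "density": self.density,
            "n_edges": self.n_edges,
            "n_negative_edges": self.n_negative_edges,
            "average_path_length": self.average_path_length,
            "transitivity": self.transitivity,
            "clustering_coefficient": self.clustering_coefficient,
            "connected": self.connected,
        }


def global_properties(net: WeightedNetwork) -> GlobalProperties:
    """Edge counts on the signed matrix; topology on the binarized graph.

    For a disconnected graph the average path length is taken over the
    reachable ordered pairs only and ``connected`` is False.
    """
    p = net.p
    iu = np.triu_indices(p, k=1)
    upper = net.weights[iu]
    n_edges = int(np.count_nonzero(upper))
    n_negative = int(np.count_nonzero(upper < 0))
    n_pairs = p * (p - 1) // 2
    density = n_edges / n_pairs if n_pairs else 0.0

    g = nx.from_numpy_array((net.weights != 0).astype(int))
    connected = p > 0 and nx.is_connected(g)
    lengths = [
        d
        for _, dists in nx.all_pairs_shortest_path_length(g)
        for target, d in dists.items()
        if d > 0
    ]
    apl = float(np.mean(lengths)) if lengths else float("nan")

    return GlobalProperties(
        density=density,
        n_edges=n_edges,
        n_negative_edges=n_negative,
        average_path_length=apl,
        transitivity=float(nx.transitivity(g)),
        clustering_coefficient=float(nx.average_clustering(g)),
        connected=connected,
    )
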