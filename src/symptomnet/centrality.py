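"""Node centrality for weighted symptom networks.

Distances for shortest-path indices use the standard inverse-weight
convention: an edge of absolute weight w has length 1/w, so strong edges
are short.  Three indices:

* strength    — sum of absolute incident edge weights;
* closeness   — inverse of the summed shortest-path distance to all other
                nodes (0 if any node is unreachable);
* betweenness — number of shortest paths between other pairs passing
                through the node, with equal fractional credit when several
                paths tie.

z-scored columns (mean 0, SD 1 across nodes, n−1 denominator) are provided
alongside the raw values, which is how centrality profiles are usually
plotted for symptom networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .glasso import WeightedNetwork, ZERO_TOL

METRICS = ("betweenness", "closeness", "strength")


def zscore(values: np.ndarray | pd.Series) -> np.ndarray:
    """(x - mean) / SD across nodes, SD with n-1 denominator."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 nodes")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; z-scores undefined")
    return (x - np.mean(x)) / sd


@dataclass
class CentralityTable:
    """Raw and z-scored betweenness/closeness/strength per node."""

    table: pd.DataFrame = field(repr=False)
    disconnected: bool = False

    def __getitem__(self, metric: str) -> pd.Series:
        return self.table[metric]

    def z(self, metric: str) -> pd.Series:
        return self.table[f"z_{metric}"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _graph(net: WeightedNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(net.labels)
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = abs(net.weights[i, j])
            if w > ZERO_TOL:
                G.add_edge(net.labels[i], net.labels[j], weight=w, length=1.0 / w)
    return G


def node_centrality(net: WeightedNetwork) -> CentralityTable:
    """Compute all three centrality indices plus their z-scores.

    On a disconnected network unreachable pairs contribute infinite
    distance: the affected nodes get closeness 0 and the table carries a
    ``disconnected`` warning flag.
    """
    if net.p < 2:
        raise ValueError("need at least 2 nodes")
    G = _graph(net)
    labels = net.labels
    strength = np.abs(net.weights).sum(axis=1)
    betw = nx.betweenness_centrality(G, normalized=False, weight="length")
    closeness = np.zeros(net.p)
    disconnected = False
    dist = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
    for i, lab in enumerate(labels):
        d = dist.get(lab, {})
        if len(d) < net.p:  # some node unreachable
            disconnected = True
            closeness[i] = 0.0
        else:
            total = sum(v for k, v in d.items() if k != lab)
            closeness[i] = 1.0 / total if total > 0 else 0.0
    if disconnected:
        warnings.warn("network is disconnected; closeness set to 0 for affected nodes")
    table = pd.DataFrame(
        {
            "betweenness": [betw[lab] for lab in labels],
            "closeness": closeness,
            "strength": strength,
        },
        index=pd.Index(labels, name="symptom"),
    )
    for m in METRICS:
        col = table[m].to_numpy()
        table[f"z_{m}"] = zscore(col) if np.std(col, ddof=1) > 0 else np.nan
    return CentralityTable(table, disconnected=disconnected)
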