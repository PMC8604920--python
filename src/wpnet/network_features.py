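"""Five per-node network features for the baseline classifiers.

Degree centrality, eigenvector centrality (edge-weighted), closeness
centrality, betweenness centrality (edge-weighted) and the weighted
clustering coefficient, computed on the weighted patient network.

Conventions (the tie-strength/distance duality is a genuine modelling
choice, so it is pinned down here):

* Edge weights are tie *strengths* (shared-diagnosis counts).  Shortest-path
  measures (closeness, betweenness) therefore use distance = 1/weight, so
  strongly tied patients are "close".  Closeness accepts an unweighted
  toggle because the strength/distance convention for it is ambiguous in
  parts of the literature.
* Eigenvector centrality uses power iteration on the weighted adjacency
  (tolerance 1e-8, at most 1000 iterations) with Euclidean normalisation.
* The weighted clustering coefficient is the Onnela geometric-mean form,
  bounded in [0, 1]; weights are scaled by the network maximum.
* On a unit-weight network every weighted variant reduces exactly to its
  unweighted counterpart.

Disconnected networks are accepted: closeness follows the
Wasserman–Faust convention (computed over each node's reachable set and
scaled by its relative size).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .errors import DataError
from .graph_builder import node_order

__all__ = ["compute_features", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = [
    "degree_centrality",
    "eigenvector_centrality_w",
    "closeness_centrality",
    "betweenness_centrality_w",
    "clustering_coefficient_w",
]


def compute_features(net: nx.Graph, weighted_closeness: bool = True) -> pd.DataFrame:
    """Compute the five features for every node, in canonical node order.

    Returns a DataFrame indexed by patient ID with columns
    :data:`FEATURE_COLUMNS`.  Raises :class:`DataError` if eigenvector
    power iteration fails to converge.
    """
    if net.number_of_nodes() == 0:
        raise DataError("cannot compute features on an empty network")
    g = net.copy()
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1)
        if w <= 0:
            raise DataError(f"non-positive edge weight on ({u}, {v})")
        d["distance"] = 1.0 / w

    degree = nx.degree_centrality(g)
    try:
        eig = nx.eigenvector_centrality(g, max_iter=1000, tol=1e-8, weight="weight")
    except nx.PowerIterationFailedConvergence as exc:
        raise DataError(
            "eigenvector centrality power iteration failed to converge "
            "within 1000 iterations"
        ) from exc
    closeness = nx.closeness_centrality(
        g, distance="distance" if weighted_closeness else None
    )
    betweenness = nx.betweenness_centrality(g, weight="distance", normalized=True)
    clustering = nx.clustering(g, weight="weight")

    order = node_order(g)
    return pd.DataFrame(
        {
            "degree_centrality": [degree[n] for n in order],
            "eigenvector_centrality_w": [eig[n] for n in order],
            "closeness_centrality": [closeness[n] for n in order],
            "betweenness_centrality_w": [betweenness[n] for n in order],
            "clustering_coefficient_w": [clustering[n] for n in order],
        },
        index=pd.Index(order, name="patient_id"),
    )
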