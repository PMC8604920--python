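"""Patient–disease bipartite graph and its weighted one-mode projection.

Patients and grouped diagnoses form a bipartite graph; projecting onto the
patient side yields the *weighted patient network* (WPN), in which two
patients are tied iff they share at least one grouped diagnosis and the tie
weight is the number of diagnoses they share (common neighbours in the
bipartite graph).  Patients who share no diagnosis with anyone are isolated
after projection and are dropped, so the WPN node count can be slightly
below the cohort size.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import bipartite as nx_bipartite

from .cohort_builder import PatientProfile
from .errors import DataError

__all__ = [
    "build_bipartite",
    "project_weighted",
    "summarize",
    "node_order",
    "NetworkSummary",
]

PATIENT_SIDE = 0
DISEASE_SIDE = 1


def build_bipartite(profiles: list[PatientProfile]) -> nx.Graph:
    """Bipartite graph with one (patient, group) edge per grouped diagnosis.

    Patient nodes carry the profile's feature attributes; a patient with an
    empty diagnosis set is present with degree 0.
    """
    if not profiles:
        raise DataError("build_bipartite requires at least one profile")
    g = nx.Graph()
    for p in profiles:
        g.add_node(
            p.patient_id,
            bipartite=PATIENT_SIDE,
            age_norm=p.age_norm,
            gender=p.gender,
            smoking=p.smoking,
            label=p.label,
        )
        for disease in p.grouped_diagnoses:
            g.add_node(disease, bipartite=DISEASE_SIDE)
            g.add_edge(p.patient_id, disease)
    return g


def project_weighted(g: nx.Graph) -> nx.Graph:
    """Project the bipartite graph onto the patient side.

    Edge weight between two patients is the exact count of shared disease
    neighbours; patients isolated in the projection are removed.  Node
    attributes are carried over from the bipartite graph.
    """
    patients = [n for n, d in g.nodes(data=True) if d.get("bipartite") == PATIENT_SIDE]
    # ratio=False keeps raw common-neighbour counts as weights.
    wpn = nx_bipartite.weighted_projected_graph(g, patients, ratio=False)
    wpn.remove_nodes_from([n for n in list(wpn) if wpn.degree(n) == 0])
    return wpn


def node_order(net: nx.Graph) -> list:
    """Canonical node order for every exported matrix: sorted patient ID."""
    return sorted(net.nodes)


@dataclass
class NetworkSummary:
    """Node/edge counts, average degree (2E/N) and the edge-weight histogram."""

    n_nodes: int
    n_edges: int
    average_degree: float
    weight_histogram: dict[int, int]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_degree": self.average_degree,
            "weight_histogram": {str(k): v for k, v in sorted(self.weight_histogram.items())},
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def summarize(net: nx.Graph) -> NetworkSummary:
    """Exact network summary; raises on an empty network."""
    n = net.number_of_nodes()
    if n == 0:
        raise DataError("cannot summarise an empty network")
    e = net.number_of_edges()
    hist = Counter(int(w) for _, _, w in net.edges(data="weight", default=1))
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        weight_histogram=dict(hist),
    )


def adjacency_matrix(net: nx.Graph, weighted: bool = True) -> np.ndarray:
    """Dense adjacency in canonical node order (weights or 0/1)."""
    order = node_order(net)
    a = nx.to_numpy_array(net, nodelist=order, weight="weight" if weighted else None)
    return a


def node_feature_matrix(net: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    """Patient feature matrix X (age_norm, gender, smoking) and label vector.

    Rows follow the canonical node order; raises if any node lacks the
    profile attributes attached at bipartite construction time.
    """
    order = node_order(net)
    try:
        x = np.array(
            [
                [net.nodes[n]["age_norm"], net.nodes[n]["gender"], net.nodes[n]["smoking"]]
                for n in order
            ],
            dtype=float,
        )
        y = np.array([net.nodes[n]["label"] for n in order], dtype=int)
    except KeyError as exc:
        raise DataError(f"node is missing profile attribute {exc}") from exc
    return x, y


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Weighted edge list as 3-column CSV (source,target,weight)."""
    rows = [
        {"source": u, "target": v, "weight": int(w)}
        for u, v, w in sorted(net.edges(data="weight", default=1))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path)
    g = nx.Graph()
    for source, target, weight in df.itertuples(index=False):
        g.add_edge(source, target, weight=int(weight))
    return g


def write_node_attributes(net: nx.Graph, path: str | Path) -> None:
    rows = []
    for n in node_order(net):
        d = net.nodes[n]
        rows.append(
            {
                "patient_id": n,
                "age_norm": d.get("age_norm"),
                "gender": d.get("gender"),
                "smoking": d.get("smoking"),
                "label": d.get("label"),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_weight_histogram(summary: NetworkSummary, path: str | Path) -> None:
    """Edge-weight distribution as CSV (weight,count) for plotting."""
    rows = [
        {"weight": w, "count": c} for w, c in sorted(summary.weight_histogram.items())
    ]
    pd.DataFrame(rows, columns=["weight", "count"]).to_csv(path, index=False)
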