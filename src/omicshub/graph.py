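"""Signed correlation graphs: construction, centralities, and the hub test.

A correlation network is an undirected simple graph whose edges carry the
signed Spearman rho, an absolute-value weight in (0, 1], and a sign label.
Hub status of a focal node is assessed by comparing its centrality value
against the distribution over all other nodes with a one-sample Wilcoxon
signed-rank test, alongside the Hodges-Lehmann pseudo-median of the network.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .corrnet import CorrelationEdge
from .stats import hodges_lehmann, signed_rank_test

__all__ = [
    "NodeMetricsRecord",
    "HubTestResult",
    "build_graph",
    "largest_component",
    "node_metrics",
    "hub_test",
    "ego_subnetwork",
    "summarize_neighbors",
    "write_graphml",
    "read_graphml",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("degree", "closeness", "betweenness")
DISTANCE_MODES = ("inverse_weight", "raw_weight")


@dataclass(frozen=True)
class NodeMetricsRecord:
    feature_id: str
    degree: int
    closeness: float
    betweenness: float


@dataclass(frozen=True)
class HubTestResult:
    """Focal-node centrality versus the rest of the network.

    ``direction`` reports where the focal value sits relative to the
    network pseudo-median ("above", "below" or "none"); ``p`` is the
    two-sided signed-rank p-value of the non-focal values against the focal
    value as location.
    """

    focal_id: str
    metric: str
    focal_value: float
    network_pseudomedian: float
    W: float
    p: float
    direction: str
    n_nonfocal: int
    method: str

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2)


def build_graph(edges: Iterable[CorrelationEdge], threshold: float = 0.95,
                layers: dict | None = None) -> nx.Graph:
    """Build the signed |rho|-thresholded graph from an edge stream.

    Vertices are exactly the features incident to at least one surviving
    edge. Edge attributes: ``rho`` (signed), ``weight`` = |rho|, ``sign``
    ("+" or "-"). Conflicting duplicate pairs (same pair, different rho)
    raise; exact duplicates are tolerated. ``layers`` optionally maps feature
    ids to omics layers, stored as a node attribute.
    """
    graph = nx.Graph(threshold=float(threshold))
    for edge in edges:
        if abs(edge.rho) < threshold:
            continue
        a, b = edge.feature_a, edge.feature_b
        if a == b:
            raise ValueError(f"self-correlation edge for {a!r}")
        if graph.has_edge(a, b):
            if graph.edges[a, b]["rho"] != edge.rho:
                raise ValueError(
                    f"conflicting duplicate edge {a}--{b}: "
                    f"{graph.edges[a, b]['rho']} vs {edge.rho}")
            continue
        graph.add_edge(a, b, rho=float(edge.rho), weight=abs(float(edge.rho)),
                       sign="+" if edge.rho > 0 else "-")
    if layers:
        for node in graph.nodes:
            if node in layers:
                graph.nodes[node]["layer"] = layers[node]
    return graph


def largest_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties break deterministically toward the component containing the
    lexicographically smallest member id. An empty graph is returned as is.
    """
    if graph.number_of_nodes() == 0:
        return graph.copy()
    components = sorted(nx.connected_components(graph),
                        key=lambda comp: (-len(comp), min(comp)))
    return graph.subgraph(components[0]).copy()


def node_metrics(graph: nx.Graph,
                 distance_mode: str = "inverse_weight") -> list[NodeMetricsRecord]:
    """Degree, closeness and betweenness for every vertex.

    Degree is the unweighted incident-edge count. Shortest-path metrics use
    edge distances d = 1/weight (``inverse_weight``: stronger correlation is
    closer, the default) or d = weight (``raw_weight``). Closeness(v) is the
    number of other vertices reachable from v divided by the summed shortest
    distances to them, 0 for isolated vertices. Betweenness counts, per
    unordered pair s != t, the fraction of shortest s-t paths through v.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if distance_mode not in DISTANCE_MODES:
        raise ValueError(f"distance_mode must be one of {DISTANCE_MODES}")
    work = graph.copy()
    for a, b, data in work.edges(data=True):
        weight = data["weight"]
        if weight <= 0:
            raise ValueError(f"nonpositive edge weight on {a}--{b}")
        data["_dist"] = 1.0 / weight if distance_mode == "inverse_weight" else weight

    closeness = nx.closeness_centrality(work, distance="_dist", wf_improved=False)
    betweenness = nx.betweenness_centrality(work, weight="_dist", normalized=False)
    return [
        NodeMetricsRecord(feature_id=node, degree=work.degree(node),
                          closeness=float(closeness[node]),
                          betweenness=float(betweenness[node]))
        for node in sorted(work.nodes)
    ]


def metrics_frame(records: list[NodeMetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def hub_test(metrics: list[NodeMetricsRecord], focal_id: str,
             metric: str = "degree") -> HubTestResult:
    """One-sample Wilcoxon signed-rank test of a focal node's centrality.

    All non-focal nodes' values of ``metric`` are tested against the focal
    value as the null location (two-sided); the network location is
    summarized by the Hodges-Lehmann pseudo-median of the non-focal values.
    The focal node itself is excluded from the comparison distribution.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"metric must be one of {METRIC_NAMES}")
    by_id = {r.feature_id: r for r in metrics}
    if focal_id not in by_id:
        raise KeyError(f"focal feature {focal_id!r} not in metrics")
    focal_value = float(getattr(by_id[focal_id], metric))
    others = np.array([getattr(r, metric) for r in metrics
                       if r.feature_id != focal_id], dtype=float)
    if others.size < 10:
        raise ValueError("need at least 10 non-focal nodes for the hub test")
    result = signed_rank_test(others, location=focal_value)
    pseudomedian = hodges_lehmann(others)
    if focal_value > pseudomedian:
        direction = "above"
    elif focal_value < pseudomedian:
        direction = "below"
    else:
        direction = "none"
    return HubTestResult(
        focal_id=focal_id, metric=metric, focal_value=focal_value,
        network_pseudomedian=float(pseudomedian), W=result.W, p=result.p,
        direction=direction, n_nonfocal=int(others.size), method=result.method)


def ego_subnetwork(graph: nx.Graph, focal_id: str) -> nx.Graph:
    """Induced subgraph on the focal node and its direct neighbors.

    Neighbor-neighbor edges are retained (this is the induced subgraph, not a
    star). An isolated focal node yields a single-vertex graph.
    """
    if focal_id not in graph:
        raise KeyError(f"focal feature {focal_id!r} not in graph")
    nodes = {focal_id} | set(graph.neighbors(focal_id))
    return graph.subgraph(nodes).copy()


def summarize_neighbors(graph: nx.Graph, focal_id: str) -> pd.DataFrame:
    """Table of the focal node's direct neighbors with signed rho.

    Rows are sorted ascending by rho (strongest negative first, strongest
    positive last), ties broken by neighbor id for determinism.
    """
    if focal_id not in graph:
        raise KeyError(f"focal feature {focal_id!r} not in graph")
    rows = [
        {"neighbor_id": nbr, "rho": graph.edges[focal_id, nbr]["rho"]}
        for nbr in graph.neighbors(focal_id)
    ]
    table = pd.DataFrame(rows, columns=["neighbor_id", "rho"])
    return table.sort_values(["rho", "neighbor_id"], kind="stable",
                             ignore_index=True)


def write_graphml(graph: nx.Graph, path) -> None:
    out = graph.copy()
    for _, _, data in out.edges(data=True):
        data.pop("_dist", None)
    nx.write_graphml(out, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
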