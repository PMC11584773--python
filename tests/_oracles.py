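"""Independent brute-force oracles used across the test suite.

These deliberately avoid the implementation paths they validate: manual rank
averaging + Pearson for Spearman, exhaustive simple-path enumeration for
shortest-path centralities, and full 2^n sign-pattern enumeration for the
one-sample signed-rank null.
"""

import itertools

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from omicshub.graph import NodeMetricsRecord


def manual_spearman(x, y):
    """Pearson correlation on manually averaged ranks."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(len(v))
        for i, value in enumerate(v):
            smaller = np.sum(v < value)
            equal = np.sum(v == value)
            ranks[i] = smaller + (equal + 1) / 2.0
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def exhaustive_metrics(graph, distance_mode):
    """Path-enumeration closeness/betweenness oracle for tiny graphs."""
    nodes = sorted(graph.nodes)
    dist, paths = {}, {}
    for s, t in itertools.combinations(nodes, 2):
        best, best_paths = None, []
        for path in nx.all_simple_paths(graph, s, t):
            w = sum(1.0 / graph.edges[u, v]["weight"]
                    if distance_mode == "inverse_weight"
                    else graph.edges[u, v]["weight"]
                    for u, v in zip(path, path[1:]))
            if best is None or w < best - 1e-12:
                best, best_paths = w, [path]
            elif abs(w - best) <= 1e-12:
                best_paths.append(path)
        if best is not None:
            dist[(s, t)] = best
            paths[(s, t)] = best_paths
    records = []
    for v in nodes:
        reach = [pair for pair in dist if v in pair]
        total = sum(dist[pair] for pair in reach)
        closeness = len(reach) / total if total > 0 else 0.0
        betweenness = sum(
            sum(1 for p in best_paths if v in p[1:-1]) / len(best_paths)
            for (s, t), best_paths in paths.items() if v not in (s, t))
        records.append(NodeMetricsRecord(v, graph.degree(v), closeness,
                                         betweenness))
    return records


def brute_force_signed_rank_p(d):
    """Two-sided one-sample signed-rank p by enumerating all sign patterns."""
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    stats = np.array([ranks[np.array(signs) > 0].sum()
                      for signs in itertools.product([1, -1], repeat=len(d))])
    return min(1.0, 2 * min((stats <= w + 1e-9).mean(),
                            (stats >= w - 1e-9).mean()))
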