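"""Model/Results interface for the correlation-network hub analysis.

:class:`HubNetworkModel` is built from an :class:`~omicshub.matrix.OmicsFeatureMatrix`
and a focal feature; ``fit()`` runs imputation, optional wild-type
normalization, blocked all-pairs Spearman correlation, graph construction and
centrality computation, and the signed-rank hub tests, returning a
:class:`HubNetworkResults` that carries the estimates and a ``summary()``
table.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .corrnet import all_pairs_correlations
from .graph import (METRIC_NAMES, HubTestResult, build_graph, ego_subnetwork,
                    hub_test, largest_component, node_metrics, metrics_frame,
                    summarize_neighbors, write_graphml)
from .matrix import OmicsFeatureMatrix, read_matrix_tsv, read_sample_table
from .preprocess import half_min_impute, normalize_to_reference

__all__ = ["HubNetworkModel", "HubNetworkResults"]

logger = logging.getLogger(__name__)


class HubNetworkModel:
    """Multi-omics correlation-network hub model for one focal feature.

    Parameters
    ----------
    matrix : OmicsFeatureMatrix
        Layered abundance matrix (may contain missing values; imputation is
        part of the fit).
    focal_id : str
        Feature whose hub status is tested.
    config : PipelineConfig, optional
        Thresholds and conventions; defaults to the study constants.
    """

    def __init__(self, matrix: OmicsFeatureMatrix, focal_id: str,
                 config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        if focal_id not in matrix.feature_ids:
            raise KeyError(f"focal feature {focal_id!r} not in matrix")
        self.matrix = matrix
        self.focal_id = focal_id

    @classmethod
    def from_tsv(cls, matrix_path, samples_path, focal_id: str,
                 config: PipelineConfig | None = None) -> "HubNetworkModel":
        config = config or PipelineConfig()
        samples = read_sample_table(samples_path)
        matrix = read_matrix_tsv(matrix_path, samples=samples,
                                 zeros_as_missing=config.zeros_as_missing)
        return cls(matrix, focal_id, config)

    def _preprocess(self) -> OmicsFeatureMatrix:
        matrix = self.matrix
        if self.config.impute_layers:
            matrix = half_min_impute(matrix, layers=self.config.impute_layers)
        # layers never selected for imputation must already be complete
        if matrix.values.isna().any().any():
            bad = matrix.layers[matrix.values.isna().any(axis=1)].unique().tolist()
            raise ValueError(
                f"missing values remain in layers {bad}; include them in impute_layers")
        if self.config.reference_genotype is not None:
            samples = matrix.samples
            mask = samples["genotype"] == self.config.reference_genotype
            if self.config.reference_tissue is not None:
                mask &= samples["tissue"] == self.config.reference_tissue
            reference_ids = samples.loc[mask, "sample_id"].tolist()
            matrix = normalize_to_reference(matrix, reference_ids)
        return matrix

    def fit(self) -> "HubNetworkResults":
        cfg = self.config
        matrix = self._preprocess()
        if self.focal_id not in matrix.feature_ids:
            raise ValueError(
                f"focal feature {self.focal_id!r} was dropped during preprocessing")
        edges = list(all_pairs_correlations(matrix, prefilter=cfg.prefilter_threshold,
                                            block_size=cfg.block_size))
        layers = matrix.layers.to_dict()
        graph = build_graph(edges, threshold=cfg.network_threshold, layers=layers)
        if self.focal_id not in graph:
            raise ValueError(
                f"focal feature {self.focal_id!r} has no edge at "
                f"|rho| >= {cfg.network_threshold}")
        component = largest_component(graph)
        metrics = node_metrics(graph, distance_mode=cfg.distance_mode)
        tests = {name: hub_test(metrics, self.focal_id, metric=name)
                 for name in METRIC_NAMES}
        ego = ego_subnetwork(graph, self.focal_id)
        neighbors = summarize_neighbors(graph, self.focal_id)
        return HubNetworkResults(model=self, preprocessed=matrix, edges=edges,
                                 graph=graph, component=component,
                                 metrics=metrics, hub_tests=tests, ego=ego,
                                 neighbors=neighbors)


class HubNetworkResults:
    """Fitted correlation-network hub analysis.

    Attributes
    ----------
    edges_ : pandas.DataFrame
        Prefiltered correlation edges (feature_a, feature_b, rho).
    graph_, largest_component_, ego_ : networkx.Graph
        Thresholded network, its largest connected component, and the focal
        ego subnetwork.
    metrics_ : pandas.DataFrame
        Per-node degree, closeness, betweenness.
    hub_tests_ : dict[str, HubTestResult]
        Signed-rank hub test per centrality metric.
    neighbors_ : pandas.DataFrame
        Focal neighbors with signed rho, ascending.
    """

    def __init__(self, model, preprocessed, edges, graph, component, metrics,
                 hub_tests, ego, neighbors):
        self.model = model
        self.config = model.config
        self.focal_id = model.focal_id
        self.preprocessed_ = preprocessed
        self.edges_ = pd.DataFrame(edges, columns=["feature_a", "feature_b", "rho"])
        self.graph_ = graph
        self.largest_component_ = component
        self.metric_records_ = metrics
        self.metrics_ = metrics_frame(metrics)
        self.hub_tests_ = hub_tests
        self.ego_ = ego
        self.neighbors_ = neighbors

    @property
    def focal_degree(self) -> int:
        return int(self.graph_.degree(self.focal_id))

    def network_median(self, metric: str = "degree") -> float:
        return float(self.metrics_[metric].median())

    def summary(self) -> str:
        """Human-readable summary table of the fitted network and hub tests."""
        cfg = self.config
        lines = []
        lines.append("Correlation-network hub analysis")
        lines.append("=" * 64)
        lines.append(f"Focal feature:        {self.focal_id}")
        lines.append(f"Samples:              {self.model.matrix.n_samples}")
        lines.append(f"Features (input):     {self.model.matrix.n_features}")
        lines.append(f"Prefilter |rho| >=    {cfg.prefilter_threshold}")
        lines.append(f"Network  |rho| >=     {cfg.network_threshold}")
        lines.append(f"Edges kept:           {len(self.edges_)}")
        lines.append(f"Network:              {self.graph_.number_of_nodes()} vertices, "
                     f"{self.graph_.number_of_edges()} edges")
        lines.append(f"Largest component:    {self.largest_component_.number_of_nodes()} "
                     f"vertices, {self.largest_component_.number_of_edges()} edges")
        neg = int((self.neighbors_["rho"] < 0).sum())
        lines.append(f"Focal neighbors:      {len(self.neighbors_)} "
                     f"({len(self.neighbors_) - neg} positive, {neg} negative)")
        lines.append("-" * 64)
        lines.append(f"{'metric':<12}{'focal':>12}{'pseudomedian':>14}{'W':>10}"
                     f"{'p':>12}  dir")
        for name, test in self.hub_tests_.items():
            lines.append(f"{name:<12}{test.focal_value:>12.4f}"
                         f"{test.network_pseudomedian:>14.4f}{test.W:>10.1f}"
                         f"{test.p:>12.3e}  {test.direction}")
        lines.append("-" * 64)
        lines.append(f"distance mode: {cfg.distance_mode}; hub test: two-sided "
                     "one-sample Wilcoxon signed-rank, focal excluded")
        return "\n".join(lines)

    # -- artifact output ---------------------------------------------------
    def save(self, outdir) -> dict:
        """Write edge TSV, GraphML, metrics TSV, hub-test JSON and neighbor
        table under ``outdir``; returns {name: path}."""
        import json
        from pathlib import Path
        from .corrnet import write_edges_tsv, CorrelationEdge

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "edges": outdir / "edges.tsv",
            "graphml": outdir / "network.graphml",
            "metrics": outdir / "node_metrics.tsv",
            "hub_tests": outdir / "hub_tests.json",
            "neighbors": outdir / "neighbors.tsv",
        }
        write_edges_tsv(
            (CorrelationEdge(*row) for row in self.edges_.itertuples(index=False)),
            paths["edges"])
        write_graphml(self.graph_, paths["graphml"])
        self.metrics_.to_csv(paths["metrics"], sep="\t", index=False,
                             float_format="%.9f")
        with open(paths["hub_tests"], "w") as handle:
            json.dump({name: asdict(test) for name, test in self.hub_tests_.items()},
                      handle, indent=2)
        out = self.neighbors_.copy()
        out["rho"] = out["rho"].map(lambda v: f"{v:.9f}")
        out.to_csv(paths["neighbors"], sep="\t", index=False)
        return {name: str(path) for name, path in paths.items()}
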