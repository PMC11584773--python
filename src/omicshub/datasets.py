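"""Packaged reference datasets.

Currently one dataset: the published direct-neighbor table of the SCO2
transcript (Solyc01g108200) in the 15-sample tomato multi-omics correlation
network at the |rho| >= 0.95 threshold - 29 neighbors with signed Spearman
values, mostly transcripts plus three proteins. It serves as a ground-truth
ego network for reconstruction tests without any download.
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from .corrnet import CorrelationEdge
from .graph import build_graph
from .matrix import normalize_minus

__all__ = ["SCO2_FOCAL_ID", "load_sco2_neighbor_table", "sco2_ego_graph"]

SCO2_FOCAL_ID = "Solyc01g108200"


def load_sco2_neighbor_table() -> pd.DataFrame:
    """The packaged SCO2 neighbor table: neighbor_id, layer, annotation, rho.

    The source table prints negatives with the typographic minus (U+2212);
    it is normalized to ASCII on parse. Rows are in ascending rho order.
    """
    text = (resources.files("omicshub") / "fixtures" / "sco2_ego_neighbors.tsv").read_text(
        encoding="utf-8")
    table = pd.read_csv(io.StringIO(text), sep="\t", keep_default_na=False)
    table["rho"] = table["rho"].map(lambda s: float(normalize_minus(str(s))))
    return table


def sco2_ego_graph(threshold: float = 0.95):
    """Signed graph of the SCO2 transcript and its published direct neighbors.

    Only focal-neighbor edges are known from the published table, so the
    graph is a star around the focal node; layers are attached as node
    attributes (the focal gene is a transcript).
    """
    table = load_sco2_neighbor_table()
    edges = []
    for row in table.itertuples(index=False):
        a, b = sorted([SCO2_FOCAL_ID, row.neighbor_id])
        edges.append(CorrelationEdge(a, b, row.rho))
    layers = {row.neighbor_id: row.layer for row in table.itertuples(index=False)}
    layers[SCO2_FOCAL_ID] = "transcript"
    return build_graph(edges, threshold=threshold, layers=layers)
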