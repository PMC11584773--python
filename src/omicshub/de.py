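"""Differential-feature thresholding and enrichment-direction z-scores.

A feature counts as differential when its FDR-adjusted p-value is at most
``alpha`` (default 0.1) and its absolute log2 fold-change is at least
``lfc_min`` (default 1). For an annotation term with ``count`` member
features of which ``up`` are up- and ``down`` are downregulated, the
direction score

    z = (up - down) / sqrt(count)

summarizes whether the term's differential members lean up (z > 0) or down
(z < 0); |z| is bounded by sqrt(count).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["bh_adjust", "filter_differential", "term_zscore", "read_de_table",
           "write_de_table"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (m p_(j) / j), clipped at 1, with a stable sort so
    tied raw p-values receive identical adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def filter_differential(table: pd.DataFrame, lfc_min: float = 1.0,
                        alpha: float = 0.1) -> pd.DataFrame:
    """Keep rows with |log2fc| >= lfc_min and p_adj <= alpha (both inclusive).

    Returns the retained rows with a ``direction`` column: ``up`` for
    log2fc > 0, ``down`` for log2fc < 0.
    """
    if lfc_min < 0:
        raise ValueError("lfc_min must be nonnegative")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    required = {"feature_id", "log2fc", "p_adj"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    if table["p_adj"].isna().any():
        raise ValueError("p_adj must be set for all rows; run bh_adjust first")
    keep = (table["log2fc"].abs() >= lfc_min) & (table["p_adj"] <= alpha)
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def term_zscore(up: int, down: int, count: int) -> float:
    """Direction z-score (up - down) / sqrt(count) for one annotation term."""
    if count <= 0:
        raise ValueError("count must be positive")
    if up < 0 or down < 0:
        raise ValueError("up and down must be nonnegative")
    if up + down > count:
        raise ValueError("up + down cannot exceed count")
    return (up - down) / math.sqrt(count)


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_de_table(path) -> pd.DataFrame:
    from .matrix import _open_text, normalize_minus
    import io as _io
    with _open_text(path, "rt") as handle:
        text = normalize_minus(handle.read())
    table = pd.read_csv(_io.StringIO(text), sep="\t")
    if "feature_id" not in table.columns:
        raise ValueError("DE table must have a feature_id column")
    if table["feature_id"].duplicated().any():
        raise ValueError("duplicate feature_id in DE table")
    return table
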