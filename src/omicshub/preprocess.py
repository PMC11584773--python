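"""Matrix preprocessing: half-minimum imputation and wild-type normalization.

Both operations work row-wise on an :class:`~omicshub.matrix.OmicsFeatureMatrix`
and drop (with a structured log record) features that become undefined:
all-missing rows under imputation, zero/missing reference means under
normalization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import LAYERS, OmicsFeatureMatrix

__all__ = ["half_min_impute", "normalize_to_reference"]

logger = logging.getLogger(__name__)


def half_min_impute(matrix: OmicsFeatureMatrix, layers=("protein",)) -> OmicsFeatureMatrix:
    """Replace missing values with half the per-feature observed minimum.

    A left-censoring heuristic for intensity data: a value missing because it
    fell below detection is plausibly below the smallest observed one.
    Features in ``layers`` with no observed value at all cannot be imputed and
    are dropped (counted in the log). Other layers pass through untouched.
    """
    layers = set(layers)
    if not layers:
        raise ValueError("select at least one layer to impute")
    unknown = layers - set(LAYERS)
    if unknown:
        raise ValueError(f"unknown layers: {sorted(unknown)}")

    vals = matrix.values.to_numpy(copy=True)
    rows = np.flatnonzero(matrix.layer_mask(layers))
    sub = vals[rows]
    observed = ~np.isnan(sub)
    n_obs = observed.sum(axis=1)
    row_min = np.where(n_obs > 0, np.nanmin(np.where(observed, sub, np.inf), axis=1), np.nan)
    fill = np.where(observed, sub, (row_min / 2.0)[:, None])
    vals[rows] = fill

    values = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    dropped = matrix.values.index[rows[n_obs == 0]].tolist()
    if dropped:
        logger.info("half_min_impute: dropped %d all-missing feature(s)",
                    len(dropped), extra={"stage": "impute", "dropped": dropped})
        values = values.drop(index=dropped)
    keep = values.index
    return OmicsFeatureMatrix(values, matrix.layers.loc[keep], matrix.samples)


def normalize_to_reference(matrix: OmicsFeatureMatrix,
                           reference_sample_ids) -> OmicsFeatureMatrix:
    """Divide every feature by the mean of its reference-sample values.

    ``reference_sample_ids`` usually names the wild-type samples, expressing
    each abundance relative to the wild-type level (raw-scale ratio).
    Features whose reference mean is zero or undefined (all reference values
    missing) are dropped and logged.
    """
    reference_sample_ids = list(reference_sample_ids)
    if not reference_sample_ids:
        raise ValueError("reference sample set is empty")
    missing = set(reference_sample_ids) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"reference samples not in matrix: {sorted(missing)}")

    values = matrix.values
    ref_mean = values[reference_sample_ids].mean(axis=1, skipna=True)
    bad = ref_mean.isna() | (ref_mean == 0.0)
    dropped = values.index[bad].tolist()
    if dropped:
        logger.info("normalize_to_reference: dropped %d feature(s) with zero or "
                    "undefined reference mean", len(dropped),
                    extra={"stage": "normalize", "dropped": dropped})
    out = values.loc[~bad].div(ref_mean.loc[~bad], axis=0)
    return OmicsFeatureMatrix(out, matrix.layers.loc[~bad], matrix.samples)
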