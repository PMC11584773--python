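"""Core data containers: sample tables and layered feature-by-sample matrices.

The central object is :class:`OmicsFeatureMatrix`, a feature-by-sample table of
nonnegative abundances (transcript counts, protein intensities, metabolite
levels) where every feature is tagged with the omics layer it came from.
Missing values are encoded as NaN. Features are rows, samples are columns.
"""

from __future__ import annotations

import io
import gzip
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LAYERS",
    "GENOTYPES",
    "TISSUES",
    "OmicsFeatureMatrix",
    "default_sample_table",
    "validate_sample_table",
    "read_matrix_tsv",
    "read_sample_table",
]

LAYERS = ("transcript", "protein", "metab_primary", "metab_secondary", "metab_lipid")
GENOTYPES = ("wildtype", "mutant")
TISSUES = ("green_leaf", "white_leaf", "stem")

# U+2212 appears in published tables; numeric parses normalize it to ASCII.
UNICODE_MINUS = "−"


def normalize_minus(text: str) -> str:
    """Replace the typographic minus sign (U+2212) with ASCII ``-``."""
    return text.replace(UNICODE_MINUS, "-")


def default_sample_table() -> pd.DataFrame:
    """The default 15-sample design: 5 genotype/tissue groups x 3 replicates.

    Mirrors a two-genotype (wild type vs variegated mutant) comparison across
    green leaf, white leaf (mutant only) and stem tissue.
    """
    rows = []
    groups = [
        ("mutant", "white_leaf", "Muwl"),
        ("mutant", "green_leaf", "Mugl"),
        ("wildtype", "green_leaf", "Wtgl"),
        ("mutant", "stem", "Mus"),
        ("wildtype", "stem", "Wts"),
    ]
    for genotype, tissue, prefix in groups:
        for rep in (1, 2, 3):
            rows.append(
                {
                    "sample_id": f"{prefix}{rep}",
                    "genotype": genotype,
                    "tissue": tissue,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def validate_sample_table(samples: pd.DataFrame) -> None:
    """Check sample-table invariants; raise ``ValueError`` on violation."""
    required = {"sample_id", "genotype", "tissue", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    bad_gt = set(samples["genotype"]) - set(GENOTYPES)
    if bad_gt:
        raise ValueError(f"unknown genotypes: {sorted(bad_gt)}")
    bad_ti = set(samples["tissue"]) - set(TISSUES)
    if bad_ti:
        raise ValueError(f"unknown tissues: {sorted(bad_ti)}")
    if (samples["replicate"].astype(int) < 1).any():
        raise ValueError("replicate numbers must be positive integers")
    counts = samples.groupby(["genotype", "tissue"], observed=True).size()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"every (genotype, tissue) group needs >= 2 replicates; got {small.to_dict()}"
        )


class OmicsFeatureMatrix:
    """Layered feature-by-sample abundance matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Feature-by-sample abundances; index is the feature id, columns are the
        sample ids. NaN marks a missing measurement.
    layers : pandas.Series
        Maps each feature id to its omics layer (one of :data:`LAYERS`).
    samples : pandas.DataFrame
        Sample metadata with columns sample_id, genotype, tissue, replicate.
    """

    def __init__(self, values: pd.DataFrame, layers: pd.Series, samples: pd.DataFrame):
        validate_sample_table(samples)
        values = values.astype(float)
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if list(values.columns) != list(samples["sample_id"]):
            # allow any order but require identical sets, then align
            if set(values.columns) != set(samples["sample_id"]):
                raise ValueError("matrix columns do not match the sample table")
            values = values.loc[:, list(samples["sample_id"])]
        layers = layers.reindex(values.index)
        if layers.isna().any():
            missing = layers.index[layers.isna()].tolist()
            raise ValueError(f"features without a layer assignment: {missing[:5]}")
        bad = set(layers.unique()) - set(LAYERS)
        if bad:
            raise ValueError(f"unknown layers: {sorted(bad)}")
        with np.errstate(invalid="ignore"):
            if (values.to_numpy() < 0).any():
                raise ValueError("abundances must be nonnegative where present")
        self.values = values
        self.layers = layers
        self.samples = samples.reset_index(drop=True)

    # -- basic protocol ----------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        per_layer = self.layers.value_counts().to_dict()
        return (
            f"<OmicsFeatureMatrix {self.n_features} features x "
            f"{self.n_samples} samples; layers={per_layer}>"
        )

    def subset(self, feature_ids) -> "OmicsFeatureMatrix":
        """Return a new matrix restricted to ``feature_ids`` (order preserved)."""
        return OmicsFeatureMatrix(
            self.values.loc[feature_ids], self.layers.loc[feature_ids], self.samples
        )

    def layer_mask(self, layers) -> np.ndarray:
        """Boolean row mask selecting features in any of ``layers``."""
        return self.layers.isin(set(layers)).to_numpy()

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: feature_id, layer, then one column per sample; NA for missing."""
        out = self.values.copy()
        out.insert(0, "layer", self.layers)
        out.index.name = "feature_id"
        with _open_text(path, "wt") as handle:
            out.to_csv(handle, sep="\t", na_rep="NA", float_format="%.9g")

    def sample_table_to_tsv(self, path) -> None:
        with _open_text(path, "wt") as handle:
            self.samples.to_csv(handle, sep="\t", index=False)


def _open_text(path, mode):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sample_table(path) -> pd.DataFrame:
    with _open_text(path, "rt") as handle:
        samples = pd.read_csv(handle, sep="\t")
    validate_sample_table(samples)
    return samples


def read_matrix_tsv(path, samples: pd.DataFrame | None = None,
                    samples_path=None, zeros_as_missing: bool = False) -> OmicsFeatureMatrix:
    """Read an :class:`OmicsFeatureMatrix` written by :meth:`OmicsFeatureMatrix.to_tsv`.

    Empty cells and the literal ``NA`` both parse as missing. With
    ``zeros_as_missing`` exact zeros are converted to NaN on ingest, the
    convention used when count matrices encode non-detection as 0.
    """
    if samples is None:
        if samples_path is None:
            raise ValueError("provide either a sample table or a path to one")
        samples = read_sample_table(samples_path)
    with _open_text(path, "rt") as handle:
        text = normalize_minus(handle.read())
    frame = pd.read_csv(io.StringIO(text), sep="\t", na_values=["NA"], keep_default_na=True)
    if list(frame.columns[:2]) != ["feature_id", "layer"]:
        raise ValueError("matrix TSV must start with feature_id and layer columns")
    frame = frame.set_index("feature_id")
    layers = frame.pop("layer")
    if zeros_as_missing:
        frame = frame.mask(frame == 0.0)
    return OmicsFeatureMatrix(frame, layers, samples)
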