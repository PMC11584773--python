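"""Pipeline configuration with the study's threshold constants as defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """End-to-end analysis parameters.

    Defaults follow the analysis this package reimplements: correlations
    below |rho| = 0.75 are prefiltered while streaming, the network itself is
    thresholded at |rho| = 0.95, differential features require
    |log2FC| >= 1 at FDR <= 0.1, and centrality distances use the inverse of
    the |rho| edge weight (stronger correlation = closer).
    """

    prefilter_threshold: float = 0.75
    network_threshold: float = 0.95
    lfc_min: float = 1.0
    alpha: float = 0.1
    distance_mode: str = "inverse_weight"
    impute_layers: tuple = ("protein",)
    reference_genotype: str | None = None   # e.g. "wildtype" to normalize
    reference_tissue: str | None = None
    zeros_as_missing: bool = False
    block_size: int = 512
    seed: int = 0

    def __post_init__(self):
        self.impute_layers = tuple(self.impute_layers)
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.prefilter_threshold < 1.0:
            raise ValueError("prefilter_threshold must lie in [0, 1)")
        if not 0.0 < self.network_threshold <= 1.0:
            raise ValueError("network_threshold must lie in (0, 1]")
        if self.network_threshold < self.prefilter_threshold:
            raise ValueError(
                f"network_threshold ({self.network_threshold}) must be >= "
                f"prefilter_threshold ({self.prefilter_threshold})")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be nonnegative")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.distance_mode not in ("inverse_weight", "raw_weight"):
            raise ValueError("distance_mode must be inverse_weight or raw_weight")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    def to_dict(self) -> dict:
        data = asdict(self)
        data["impute_layers"] = list(self.impute_layers)
        return data

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)
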