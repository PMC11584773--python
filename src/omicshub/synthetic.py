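"""Synthetic multi-omics data with a planted correlated hub module.

The generator emulates the statistical structure the downstream network
analysis assumes: log-normal abundances with genotype/tissue group effects, a
focal feature (a stand-in for a candidate hub transcript such as SCO2) whose
module members track a shared per-sample latent factor, left-censored
missingness in the protein layer, and full determinism under a seed.

Also houses two fixture builders used to validate the exact Spearman
arithmetic: tie-free rank pairs with a prescribed squared rank-difference sum,
and differential-expression result tables with a controlled signal fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import LAYERS, OmicsFeatureMatrix, default_sample_table, validate_sample_table

__all__ = [
    "SyntheticSpec",
    "RankPair",
    "generate_multiomics",
    "generate_rank_pair",
    "generate_de_table",
    "max_d2",
]

DEFAULT_FEATURES_PER_LAYER = {
    "transcript": 150,
    "protein": 80,
    "metab_primary": 40,
    "metab_secondary": 40,
    "metab_lipid": 40,
}


@dataclass
class SyntheticSpec:
    """Full parameterization of a simulated multi-omics study.

    Attributes
    ----------
    n_features_per_layer : dict
        Number of features generated per omics layer.
    group_effect_sd : float
        Standard deviation (log scale) of the per-feature genotype x tissue
        group means; this is the biological signal shared within a group.
    noise_sd : float
        Residual log-scale measurement noise.
    hub_size : int
        Number of module members correlated with the focal feature
        (the focal feature itself is emitted in addition).
    hub_negative_fraction : float
        Fraction of module members loading negatively on the latent factor.
    hub_loading : float
        Loading of module members on the shared latent factor; controls the
        expected |rho| between the focal feature and each member.
    protein_missing_quantile : float
        Per-feature quantile below which protein values are censored to
        missing (left-censoring, the regime half-minimum imputation targets).
    focal_feature_id : str
        Identifier of the focal (planted hub) feature, emitted in the
        transcript layer.
    seed : int
        Seed for all randomness.
    """

    n_features_per_layer: dict = field(default_factory=lambda: dict(DEFAULT_FEATURES_PER_LAYER))
    group_effect_sd: float = 1.0
    noise_sd: float = 0.05
    hub_size: int = 29
    hub_negative_fraction: float = 6 / 29
    hub_loading: float = 0.99
    protein_missing_quantile: float = 0.2
    focal_feature_id: str = "transcript:focal"
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_features_per_layer) - set(LAYERS):
            raise ValueError(f"unknown layers in n_features_per_layer: "
                             f"{sorted(set(self.n_features_per_layer) - set(LAYERS))}")
        if any(n < 0 for n in self.n_features_per_layer.values()):
            raise ValueError("feature counts must be nonnegative")
        if self.group_effect_sd < 0:
            raise ValueError("group_effect_sd must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.hub_size < 1:
            raise ValueError("hub_size must be >= 1")
        total = sum(self.n_features_per_layer.values())
        if self.hub_size > total:
            raise ValueError(f"hub_size {self.hub_size} exceeds feature budget {total}")
        if self.hub_size > self.n_features_per_layer.get("transcript", 0):
            raise ValueError("hub members are transcripts; hub_size exceeds transcript budget")
        if not 0 <= self.hub_negative_fraction <= 1:
            raise ValueError("hub_negative_fraction must lie in [0, 1]")
        if not 0 <= self.hub_loading <= 1:
            raise ValueError("hub_loading must lie in [0, 1]")
        if not 0 <= self.protein_missing_quantile < 1:
            raise ValueError("protein_missing_quantile must lie in [0, 1)")

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as handle:
            return cls(**json.load(handle))


def generate_multiomics(spec: SyntheticSpec,
                        samples: pd.DataFrame | None = None) -> OmicsFeatureMatrix:
    """Generate a layered abundance matrix with a planted hub module.

    Log-abundance model, per feature *i* and sample *s* with group g(s):

    * ordinary feature:  b_i + e_{i,g(s)} + eps,  e ~ N(0, group_effect_sd)
    * module member j:   b_j + s_j (L z_s + sqrt(1 - L^2) u_{j,s}) + eps
    * focal feature:     b_f + z_s + eps

    where z is the shared latent factor, L the hub loading, s_j = -1 for the
    negatively loaded fraction, and eps ~ N(0, noise_sd). Abundance is
    exp(log-abundance). Module members carry the latent factor *instead of* a
    group effect so that the loading directly sets their expected correlation
    with the focal feature.
    """
    spec.validate()
    if samples is None:
        samples = default_sample_table()
    validate_sample_table(samples)
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("sample table is empty")

    rng = np.random.default_rng(spec.seed)
    groups = (samples["genotype"] + "/" + samples["tissue"]).to_numpy()
    group_levels, group_idx = np.unique(groups, return_inverse=True)
    n_groups = len(group_levels)

    feature_ids: list[str] = []
    layer_of: list[str] = []
    for layer in LAYERS:
        count = spec.n_features_per_layer.get(layer, 0)
        for i in range(count):
            feature_ids.append(f"{layer}:{layer[0].upper()}{i:04d}")
            layer_of.append(layer)
    if spec.focal_feature_id in feature_ids:
        raise ValueError(
            f"focal_feature_id {spec.focal_feature_id!r} collides with an auto-generated id")
    feature_ids.append(spec.focal_feature_id)
    layer_of.append("transcript")

    n_features = len(feature_ids)
    ids = np.asarray(feature_ids)
    layer_arr = np.asarray(layer_of)

    # module membership: first hub_size transcripts (focal is the appended last row)
    transcript_rows = np.flatnonzero(layer_arr == "transcript")[:-1]
    member_rows = transcript_rows[: spec.hub_size]
    focal_row = n_features - 1
    n_negative = int(round(spec.hub_negative_fraction * spec.hub_size))
    signs = np.ones(spec.hub_size)
    signs[:n_negative] = -1.0

    baseline = rng.normal(5.0, 1.0, size=n_features)
    group_effects = rng.normal(0.0, spec.group_effect_sd, size=(n_features, n_groups))
    latent = rng.normal(0.0, 1.0, size=n_samples)
    member_noise = rng.normal(0.0, 1.0, size=(spec.hub_size, n_samples))
    eps = rng.normal(0.0, spec.noise_sd, size=(n_features, n_samples))

    log_ab = baseline[:, None] + group_effects[:, group_idx] + eps
    loading = spec.hub_loading
    module_signal = loading * latent[None, :] + math.sqrt(1.0 - loading**2) * member_noise
    log_ab[member_rows, :] = (baseline[member_rows, None]
                              + signs[:, None] * module_signal
                              + eps[member_rows, :])
    log_ab[focal_row, :] = baseline[focal_row] + latent + eps[focal_row, :]

    values = np.exp(log_ab)

    # left-censor the protein layer: per feature, drop values below its
    # empirical missingness quantile
    if spec.protein_missing_quantile > 0:
        protein_rows = np.flatnonzero(layer_arr == "protein")
        if len(protein_rows):
            cutoffs = np.quantile(values[protein_rows, :],
                                  spec.protein_missing_quantile, axis=1)
            censored = values[protein_rows, :] < cutoffs[:, None]
            block = values[protein_rows, :]
            block[censored] = np.nan
            values[protein_rows, :] = block

    frame = pd.DataFrame(values, index=pd.Index(ids, name="feature_id"),
                         columns=list(samples["sample_id"]))
    layers = pd.Series(layer_arr, index=frame.index)
    return OmicsFeatureMatrix(frame, layers, samples)


def hub_member_ids(spec: SyntheticSpec) -> list[str]:
    """Identifiers of the planted module members for ``spec`` (focal excluded)."""
    return [f"transcript:T{i:04d}" for i in range(spec.hub_size)]


# ---------------------------------------------------------------------------
# exact rank pairs
# ---------------------------------------------------------------------------

def max_d2(n: int) -> int:
    """Largest achievable sum of squared rank differences: n(n^2 - 1)/3."""
    return n * (n * n - 1) // 3


@dataclass
class RankPair:
    """A pair of tie-free rank vectors with a known squared-difference sum.

    For tie-free ranks Spearman's rho is 1 - 6 d2_sum / (n (n^2 - 1)), so a
    pair constructed for a given ``d2_sum`` pins the exact correlation value.
    """

    ranks_a: np.ndarray
    ranks_b: np.ndarray
    d2_sum: int

    def __post_init__(self):
        self.ranks_a = np.asarray(self.ranks_a, dtype=int)
        self.ranks_b = np.asarray(self.ranks_b, dtype=int)
        n = len(self.ranks_a)
        for ranks in (self.ranks_a, self.ranks_b):
            if sorted(ranks) != list(range(1, n + 1)):
                raise ValueError("rank vectors must be tie-free permutations of 1..n")
        actual = int(((self.ranks_a - self.ranks_b) ** 2).sum())
        if actual != self.d2_sum:
            raise ValueError(f"d2_sum mismatch: stated {self.d2_sum}, actual {actual}")

    @property
    def n(self) -> int:
        return len(self.ranks_a)

    @property
    def rho(self) -> float:
        """Exact Spearman rho via the classical tie-free identity."""
        n = self.n
        return 1.0 - 6.0 * self.d2_sum / (n * (n * n - 1))


def generate_rank_pair(n: int, target_d2: int) -> RankPair:
    """Build a tie-free rank pair with sum of squared differences ``target_d2``.

    ranks_a is the identity; ranks_b is found by a deterministic backtracking
    assignment with rearrangement-inequality pruning. A fast path first tries
    composing disjoint swaps of elements k apart (each contributing 2 k^2);
    targets that no product of disjoint transpositions can reach (they exist,
    e.g. n=4, target 14, which needs a 3-cycle) fall through to the full
    search. Raises ``ValueError`` for odd, out-of-range, or infeasible targets.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if target_d2 % 2 != 0:
        raise ValueError(f"target_d2 must be even, got {target_d2}")
    if not 0 <= target_d2 <= max_d2(n):
        raise ValueError(f"target_d2 must lie in [0, {max_d2(n)}], got {target_d2}")

    identity = np.arange(1, n + 1)
    perm = _disjoint_swap_greedy(n, target_d2)
    if perm is None:
        perm = _assignment_search(n, target_d2)
    if perm is None:
        raise ValueError(f"no tie-free rank pair of length {n} achieves d2 = {target_d2}")
    return RankPair(identity, np.asarray(perm), target_d2)


def _disjoint_swap_greedy(n: int, target_d2: int):
    """Compose disjoint swaps of elements k apart, largest k first."""
    remaining = target_d2 // 2  # each swap at gap k contributes 2 k^2
    perm = list(range(1, n + 1))
    free = [True] * (n + 1)
    for k in range(n - 1, 0, -1):
        while remaining >= k * k:
            spot = None
            for i in range(1, n - k + 1):
                if free[i] and free[i + k]:
                    spot = i
                    break
            if spot is None:
                break
            perm[spot - 1], perm[spot + k - 1] = perm[spot + k - 1], perm[spot - 1]
            free[spot] = free[spot + k] = False
            remaining -= k * k
    return perm if remaining == 0 else None


def _assignment_search(n: int, target_d2: int):
    """Exact search for a permutation with the requested squared displacement.

    Assigns positions 1..n in order; at each node the residual target is
    checked against the exact min/max achievable by the remaining values
    (rearrangement inequality: sorted-with-sorted minimizes, sorted-with-
    reversed maximizes the sum of squared differences).
    """
    values = list(range(1, n + 1))

    def bounds(pos: int, remaining: list[int]) -> tuple[int, int]:
        m = len(remaining)
        lo = sum((remaining[j] - (pos + j)) ** 2 for j in range(m))
        hi = sum((remaining[j] - (pos + m - 1 - j)) ** 2 for j in range(m))
        return lo, hi

    result: list[int] = []

    def recurse(pos: int, remaining: list[int], target: int) -> bool:
        if not remaining:
            return target == 0
        mid_candidates = sorted(remaining, key=lambda v: -abs(v - pos))
        lo_all, hi_all = bounds(pos, remaining)
        if not lo_all <= target <= hi_all:
            return False
        if target < (lo_all + hi_all) // 2:
            mid_candidates.reverse()  # small residual: try small displacements first
        for v in mid_candidates:
            cost = (v - pos) ** 2
            if cost > target:
                continue
            rest = [w for w in remaining if w != v]
            lo, hi = bounds(pos + 1, rest)
            if lo <= target - cost <= hi:
                result.append(v)
                if recurse(pos + 1, rest, target - cost):
                    return True
                result.pop()
        return False

    if recurse(1, values, target_d2):
        return result
    return None


# ---------------------------------------------------------------------------
# differential-expression fixtures
# ---------------------------------------------------------------------------

def generate_de_table(n: int, frac_up: float, frac_down: float,
                      effect_lfc: float = 2.0, seed: int = 0) -> pd.DataFrame:
    """Simulate a differential-expression result table.

    Null features draw p ~ Uniform(0,1) and small log2 fold-changes; signal
    features draw |log2FC| >= ``effect_lfc`` with very small p-values. Columns:
    feature_id, log2fc, p. Adjusted p-values are added downstream.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if frac_up < 0 or frac_down < 0:
        raise ValueError("fractions must be nonnegative")
    if frac_up + frac_down > 1 + 1e-12:
        raise ValueError("frac_up + frac_down must not exceed 1")
    rng = np.random.default_rng(seed)
    n_up = int(round(frac_up * n))
    n_down = int(round(frac_down * n))
    n_null = n - n_up - n_down

    lfc = np.concatenate([
        effect_lfc + np.abs(rng.normal(0.0, 0.3, size=n_up)),
        -(effect_lfc + np.abs(rng.normal(0.0, 0.3, size=n_down))),
        rng.normal(0.0, 0.2, size=n_null),
    ])
    p = np.concatenate([
        10.0 ** -rng.uniform(4.0, 10.0, size=n_up + n_down),
        rng.uniform(0.0, 1.0, size=n_null),
    ])
    table = pd.DataFrame({
        "feature_id": [f"f{i:05d}" for i in range(n)],
        "log2fc": lfc,
        "p": p,
    })
    return table
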