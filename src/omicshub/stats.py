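"""One-sample Wilcoxon signed-rank machinery and the Hodges-Lehmann estimator.

The signed-rank test here is the workhorse behind the network hub test: the
centrality values of all non-focal nodes are tested against the focal node's
value as the null location. For small samples the null distribution of the
positive-rank sum W+ is enumerated exactly by dynamic programming over the
(tie-averaged) ranks, which remains exact in the presence of tied absolute
differences; larger samples use the normal approximation with tie and
continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, wilcoxon

__all__ = ["SignedRankResult", "signed_rank_test", "hodges_lehmann",
           "AllZeroDifferencesError", "EXACT_MAX_N"]

# exact enumeration up to this many nonzero differences, approximation beyond
EXACT_MAX_N = 25


class AllZeroDifferencesError(ValueError):
    """Every value equals the test location: the signed-rank test is undefined."""


@dataclass(frozen=True)
class SignedRankResult:
    """Two-sided one-sample Wilcoxon signed-rank test outcome."""

    W: float              # positive-rank sum
    p: float              # two-sided p-value
    n_nonzero: int        # differences remaining after dropping zeros
    method: str           # "exact" or "approx"


def signed_rank_test(values, location: float) -> SignedRankResult:
    """Test whether ``values`` are symmetric about ``location``.

    Differences of exactly zero are dropped; tied absolute differences get
    average ranks. W is the sum of ranks of the positive differences. The
    two-sided p-value is 2 * min(P(W+ <= w), P(W+ >= w)) capped at 1,
    computed from the exact null for up to ``EXACT_MAX_N`` nonzero
    differences and from the tie- and continuity-corrected normal
    approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    d = values - float(location)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise AllZeroDifferencesError(
            "all differences are zero; signed-rank test undefined")
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, w)
        method = "exact"
    else:
        p = float(wilcoxon(d, correction=True, method="approx",
                           alternative="two-sided").pvalue)
        method = "approx"
    return SignedRankResult(W=w, p=min(1.0, p), n_nonzero=n, method=method)


def _exact_two_sided_p(ranks: np.ndarray, w: float) -> float:
    """Exact two-sided p via DP over doubled ranks (integers even with ties).

    Builds the distribution of 2*W+ under random independent signs by
    convolving the polynomials (1 + x^(2 r_i)); with average ranks the doubled
    ranks are integers so the DP is exact.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for r in doubled:
        counts[r:top + r + 1] += counts[0:top + 1]
        top += r
    n_patterns = 2.0 ** len(doubled)
    w2 = int(np.rint(2.0 * w))
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return min(1.0, 2.0 * min(p_le, p_ge))


def hodges_lehmann(values, max_exact: int = 2000, seed: int = 0) -> float:
    """Hodges-Lehmann pseudo-median: median of all Walsh averages (x_i+x_j)/2, i<=j.

    Exact for up to ``max_exact`` observations; beyond that the Walsh-average
    median is estimated from a fixed-seed subsample of two million pairs.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    n = v.size
    if n <= max_exact:
        iu, ju = np.triu_indices(n)
        walsh = (v[iu] + v[ju]) / 2.0
    else:
        rng = np.random.default_rng(seed)
        m = 2_000_000
        i = rng.integers(0, n, size=m)
        j = rng.integers(0, n, size=m)
        walsh = (v[i] + v[j]) / 2.0
    return float(np.median(walsh))
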