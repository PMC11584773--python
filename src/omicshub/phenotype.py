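"""Phenotype-level statistics: yield-canalization variability and leaf pigments.

Canalization - the stability of a phenotype across genetically identical
plants - is quantified by the scaled absolute deviation from the median,
|x_i - med(x)| / med(x), a per-observation relative-variability measure
comparable in spirit to the coefficient of variation but robust to the
location estimate. Pigment concentrations (chlorophyll a, chlorophyll b,
total carotenoids) come from microplate absorbances at 470/652/665 nm via
the standard pure-methanol equations, after correcting the short optical
pathlength of a filled 96-well (0.51 cm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CanalizationStats", "PigmentResult", "scaled_abs_dev_median",
           "pigment_concentrations", "PIGMENT_COEFFICIENTS"]

# pure-methanol extinction equations (concentrations in ug/ml):
#   chl_a = 16.72 A665 - 9.16 A652
#   chl_b = 34.09 A652 - 15.28 A665
#   car   = (1000 A470 - 1.63 chl_a - 104.96 chl_b) / 221
PIGMENT_COEFFICIENTS = {
    "chl_a": {"a665": 16.72, "a652": -9.16},
    "chl_b": {"a652": 34.09, "a665": -15.28},
    "carotenoids": {"a470": 1000.0, "chl_a": -1.63, "chl_b": -104.96, "denom": 221.0},
}


@dataclass
class CanalizationStats:
    """Median, per-observation scaled absolute deviations, and the CV."""

    median: float
    scaled_ad: np.ndarray
    cv: float


def scaled_abs_dev_median(values, scale: str = "median") -> CanalizationStats:
    """Per-observation |x_i - med(x)| / med(x) plus the sample CV.

    ``scale`` chooses the denominator ("median", the default, or "mean").
    Requires at least two positive observations and a positive scale value;
    the statistic is invariant to positive rescaling of the data.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 observations")
    if scale not in ("median", "mean"):
        raise ValueError("scale must be 'median' or 'mean'")
    median = float(np.median(values))
    denom = median if scale == "median" else float(np.mean(values))
    if denom <= 0:
        raise ValueError(f"nonpositive {scale}: scaled deviation undefined")
    scaled_ad = np.abs(values - median) / denom
    mean = float(np.mean(values))
    cv = float(np.std(values, ddof=1) / mean) if mean != 0 else float("nan")
    return CanalizationStats(median=median, scaled_ad=scaled_ad, cv=cv)


@dataclass
class PigmentResult:
    """Pigment concentrations in ug/ml of extract (after dilution scaling)."""

    chl_a: float
    chl_b: float
    carotenoids: float
    pathlength: float
    dilution_factor: float
    warnings: list = field(default_factory=list)
    coefficients: dict = field(default_factory=lambda: PIGMENT_COEFFICIENTS)


def pigment_concentrations(a470: float, a652: float, a665: float,
                           pathlength: float = 0.51,
                           dilution: float = 10.0) -> PigmentResult:
    """Chlorophyll a/b and carotenoid concentrations from raw absorbances.

    Measured absorbances are divided by ``pathlength`` (cm) to map microplate
    readings onto the 1-cm-cuvette equations, then the pure-methanol
    equations apply, and all concentrations are scaled by the extract
    ``dilution`` factor. Negative outcomes (possible with noisy readings near
    zero) are reported as computed, with a warning flag.
    """
    if pathlength <= 0:
        raise ValueError("pathlength must be positive")
    if min(a470, a652, a665) < 0:
        raise ValueError("absorbances must be nonnegative")
    s470, s652, s665 = (a / pathlength for a in (a470, a652, a665))
    chl_a = 16.72 * s665 - 9.16 * s652
    chl_b = 34.09 * s652 - 15.28 * s665
    carotenoids = (1000.0 * s470 - 1.63 * chl_a - 104.96 * chl_b) / 221.0
    chl_a, chl_b, carotenoids = (v * dilution for v in (chl_a, chl_b, carotenoids))
    warnings = [name for name, v in
                (("chl_a", chl_a), ("chl_b", chl_b), ("carotenoids", carotenoids))
                if v < 0]
    return PigmentResult(chl_a=chl_a, chl_b=chl_b, carotenoids=carotenoids,
                         pathlength=pathlength, dilution_factor=dilution,
                         warnings=warnings)
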