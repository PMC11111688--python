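"""Biodiversity–biomass power law.

Experimental meta-analysis across primary-producer assemblages supports a
power function Biomass = a · richness^b: each added species raises standing
biomass, but with decelerating returns. Because the monoculture constant *a*
cancels in ratios, a *proportional* change in richness maps to a proportional
change in biomass as p_biomass = p_region^b. The central exponent is
b = 0.26 with a 95% CI of (0.16, 0.37); the CI is carried as the uncertainty
range for envelope sweeps.

b is a single global scalar here, not a spatially varying field: the carried
CI is wider than spatially explicit estimates from forest re-measurement
data, so it already spans plausible spatial variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ParameterError
from .persistence import _scalar_in


@dataclass(frozen=True)
class BEFParams:
    """Biomass–richness exponent b, its 95% CI, and the monoculture constant a."""

    b: float = 0.26
    b_ci: tuple[float, float] = (0.16, 0.37)
    a: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ParameterError(f"b must be positive, got {self.b}")
        lo, hi = self.b_ci
        if not (0 < lo <= hi):
            raise ParameterError(f"b_ci must be ordered positive, got {self.b_ci}")
        if self.a <= 0:
            raise ParameterError(f"a must be positive, got {self.a}")


def biomass_from_richness(richness, a: float, b: float):
    """Standing biomass a · richness^b; richness = 1 is the monoculture baseline a."""
    r = np.asarray(richness, dtype=float)
    if np.any(r < 0):
        raise ParameterError("richness must be >= 0")
    if a <= 0:
        raise ParameterError("a must be positive")
    out = a * np.power(r, b)
    return float(out) if _scalar_in(richness) else out


def biomass_fraction(p_region, b: float = 0.26):
    """Remaining biomass fraction p_region^b; the constant a cancels exactly.

    Persistence > 1 (projected species gains) passes through and yields a
    biomass fraction > 1, i.e. a negative loss.
    """
    p = np.asarray(p_region, dtype=float)
    if np.any(p[~np.isnan(p)] < 0):
        raise ParameterError("p_region must be >= 0")
    out = np.power(p, b)
    return float(out) if _scalar_in(p_region) else out


def loss_percent(fraction_remaining):
    """(1 − fraction) · 100; negative values denote gains. Round only for display."""
    f = np.asarray(fraction_remaining, dtype=float)
    if np.any(f[~np.isnan(f)] < 0):
        raise ParameterError("fraction_remaining must be >= 0")
    out = (1.0 - f) * 100.0
    return float(out) if _scalar_in(fraction_remaining) else out


def jensen_gap(p_regions: np.ndarray, b: float = 0.26,
               weights: np.ndarray | None = None) -> dict[str, float]:
    """Diagnostic: transform-of-mean vs mean-of-transforms across regions.

    The regional transform is applied to each region's persistence; summary
    statistics across regions can either average first and transform
    (``transform_of_mean``) or transform first and average
    (``mean_of_transforms``). The power transform is concave for b < 1, so by
    Jensen's inequality the transform of the mean is the larger of the two;
    the gap quantifies by how much.
    """
    p = np.asarray(p_regions, dtype=float)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    tom = float(biomass_fraction(np.sum(w * p), b))
    mot = float(np.sum(w * biomass_fraction(p, b)))
    return {"transform_of_mean": tom, "mean_of_transforms": mot, "gap": tom - mot}
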