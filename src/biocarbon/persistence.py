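"""Species persistence from effective habitat area and the species-area relationship.

The proportion of species expected to persist in a grid cell is modelled in
three steps:

1. the *present* effective habitat area around a focal cell — the
   compositional-similarity-weighted sum of all cell areas, assuming every
   cell's habitat is in perfect condition;
2. the *scenario* effective area — similarity of the focal cell's present
   environment to every cell's future environment, discounted by that cell's
   projected habitat condition;
3. the ratio of the two pushed through the species-area relationship,
   ``p = ratio**z``.

Per-cell persistence is then aggregated to ecoregions by a weighted geometric
mean, where a cell's weight is the inverse of its present effective area:
cells sitting in rare environments carry more of the region's unique species
and therefore more weight.

Compositional similarity is a pluggable kernel; the default is an
exponential decay in per-dimension-scaled L1 environmental distance, a
monotone stand-in for a fitted generalized dissimilarity model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DataError, ParameterError

ZERO_FLOOR = 1e-9  # geometric-mean clamp: one p=0 cell must not zero a region


def _scalar_in(x) -> bool:
    """True when the caller passed a scalar (so we return float, not 0-d array)."""
    return np.ndim(x) == 0


class SimilarityKernel:
    """Contract: ``pairwise(X, Y)[i, j] = s(x_i, y_j)`` in [0, 1], s(x,x)=1, symmetric."""

    def pairwise(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, xi: np.ndarray, yj: np.ndarray) -> float:
        return float(self.pairwise(np.atleast_2d(xi), np.atleast_2d(yj))[0, 0])


@dataclass(frozen=True)
class ExpL1Kernel(SimilarityKernel):
    """s(x, y) = exp(−Σ_d |x_d − y_d| / σ_d): GDM-like monotone decay."""

    sigma: float | np.ndarray = 1.0

    def pairwise(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        sig = np.broadcast_to(np.asarray(self.sigma, dtype=float), (x.shape[1],))
        if np.any(sig <= 0):
            raise ParameterError("kernel sigma must be positive")
        d = np.abs(x[:, None, :] - y[None, :, :]) / sig
        return np.exp(-d.sum(axis=2))


@dataclass(frozen=True)
class SARParams:
    """Species-area exponent and its uncertainty range."""

    z: float = 0.25
    z_range: tuple[float, float] = (0.1, 0.65)

    def __post_init__(self) -> None:
        if not (0.0 < self.z <= 1.0):
            raise ParameterError(f"z must be in (0, 1], got {self.z}")
        lo, hi = self.z_range
        if not (0.0 < lo <= hi):
            raise ParameterError(f"z_range must be ordered positive, got {self.z_range}")


@dataclass(frozen=True)
class EcoregionPartition:
    """Integer region label per cell; the unit of aggregation."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels))

    @property
    def region_ids(self) -> np.ndarray:
        lab = self.labels[~np.isnan(self.labels.astype(float))]
        return np.unique(lab.astype(int))


@dataclass
class PersistenceResult:
    p_cell: np.ndarray
    p_region: "dict[int, float]"
    weights: np.ndarray
    area_ratio: np.ndarray = field(default=None)  # type: ignore[assignment]


def z_lower_bound(z_fragmentation: float, z_relaxation: float) -> float:
    """Additional-loss exponent: fragmentation z minus relaxation z.

    Intact habitat also relaxes toward a lower equilibrium richness
    (z ≈ 0.15), so the change attributable to climate and land use alone is
    bounded below by the difference from the fragmentation exponent
    (z ≈ 0.25), giving the canonical lower bound of 0.1.
    """
    if not (z_fragmentation > z_relaxation > 0):
        raise ParameterError(
            f"need z_fragmentation > z_relaxation > 0, got {z_fragmentation}, {z_relaxation}"
        )
    return z_fragmentation - z_relaxation


def persistence_sar(area_ratio, z: float):
    """p = area_ratio**z. Ratios > 1 (environmental expansion) pass through unclipped."""
    ratio = np.asarray(area_ratio, dtype=float)
    if np.any(ratio[~np.isnan(ratio)] < 0):
        raise ParameterError("area_ratio must be >= 0")
    out = np.power(ratio, z)
    return float(out) if _scalar_in(area_ratio) else out


def _flat_env(env: np.ndarray) -> np.ndarray:
    """(n_lat, n_lon, d) or (n, d) -> (n, d)."""
    env = np.asarray(env, dtype=float)
    if env.ndim == 2:
        return env
    return env.reshape(-1, env.shape[-1])


def effective_areas_present(env_present: np.ndarray, areas: np.ndarray,
                            kernel: SimilarityKernel) -> np.ndarray:
    """Present effective habitat area for every cell at once.

    E_j = Σ_i s(env_j, env_i) · A_i, all habitat assumed in perfect condition.
    """
    x = _flat_env(env_present)
    a = np.asarray(areas, dtype=float).ravel()
    if np.any(a <= 0):
        raise ParameterError("areas must be strictly positive")
    if np.any(np.isnan(x)):
        raise DataError("env_present contains missing values")
    s = kernel.pairwise(x, x)
    return s @ a


def effective_area_present(cell: int, env_present: np.ndarray, areas: np.ndarray,
                           kernel: SimilarityKernel) -> float:
    """Present effective area for one focal cell (flat index)."""
    x = _flat_env(env_present)
    a = np.asarray(areas, dtype=float).ravel()
    if np.any(np.isnan(x[cell])):
        raise DataError(f"missing environment at focal cell {cell}")
    s = kernel.pairwise(x[cell:cell + 1], x)[0]
    return float(s @ a)


def effective_areas_scenario(env_present: np.ndarray, env_future: np.ndarray,
                             condition_future: np.ndarray, areas: np.ndarray,
                             kernel: SimilarityKernel) -> np.ndarray:
    """Scenario effective area for every cell.

    E*_j = Σ_i s(env_j(present), env_i(future)) · h_i · A_i — the area of
    future environments similar to the focal cell's present environment,
    discounted by projected habitat condition h ∈ [0, 1].
    """
    x = _flat_env(env_present)
    y = _flat_env(env_future)
    h = np.asarray(condition_future, dtype=float).ravel()
    a = np.asarray(areas, dtype=float).ravel()
    if np.any((h < 0) | (h > 1)):
        raise ParameterError("condition_future must lie in [0, 1]")
    s = kernel.pairwise(x, y)
    return s @ (h * a)


def effective_area_scenario(cell: int, env_present: np.ndarray, env_future: np.ndarray,
                            condition_future: np.ndarray, areas: np.ndarray,
                            kernel: SimilarityKernel) -> float:
    x = _flat_env(env_present)
    y = _flat_env(env_future)
    h = np.asarray(condition_future, dtype=float).ravel()
    a = np.asarray(areas, dtype=float).ravel()
    if np.any((h < 0) | (h > 1)):
        raise ParameterError("condition_future must lie in [0, 1]")
    if np.any(np.isnan(x[cell])):
        raise DataError(f"missing environment at focal cell {cell}")
    s = kernel.pairwise(x[cell:cell + 1], y)[0]
    return float(s @ (h * a))


def region_weights(env_present: np.ndarray, areas: np.ndarray, kernel: SimilarityKernel,
                   partition: EcoregionPartition | None = None) -> np.ndarray:
    """Aggregation weight per cell: w_j = 1 / E_j(present).

    Cells in less extensive (rarer) environments get larger weights. If a
    partition is given, weights are normalized to sum to 1 within each region;
    otherwise raw inverse effective areas are returned.
    """
    eff = effective_areas_present(env_present, areas, kernel)
    if np.any(eff <= 0):
        raise RuntimeError("zero effective area encountered; kernel violates s(x,x)=1 or areas<=0")
    w = 1.0 / eff
    if partition is None:
        return w
    return normalize_weights(w, partition)


def normalize_weights(w: np.ndarray, partition: EcoregionPartition) -> np.ndarray:
    """Rescale raw weights to sum to 1 within each region (reporting convention)."""
    w = np.asarray(w, dtype=float).ravel()
    lab = np.asarray(partition.labels).ravel()
    out = np.empty_like(w)
    for rid in partition.region_ids:
        m = lab == rid
        out[m] = w[m] / w[m].sum()
    return out


def ecoregion_persistence(p_cell: np.ndarray, weights: np.ndarray,
                          partition: EcoregionPartition,
                          zero_floor: float = ZERO_FLOOR) -> dict[int, float]:
    """Weighted geometric mean of per-cell persistence within each ecoregion.

    p_region = exp(Σ w ln max(p, ε) / Σ w); invariant to rescaling all
    weights by a constant. ε (``zero_floor``) keeps a single p = 0 cell from
    collapsing the whole region to zero. A region whose cells are all missing
    maps to NaN rather than raising.
    """
    p = np.asarray(p_cell, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(p[~np.isnan(p)] < 0):
        raise ParameterError("p_cell must be >= 0")
    if np.any(w[~np.isnan(p)] <= 0):
        raise ParameterError("weights must be strictly positive")
    lab = np.asarray(partition.labels).ravel()
    out: dict[int, float] = {}
    for rid in partition.region_ids:
        m = (lab == rid) & ~np.isnan(p)
        if not m.any():
            out[int(rid)] = float("nan")
            continue
        logs = np.log(np.maximum(p[m], zero_floor))
        out[int(rid)] = float(np.exp(np.sum(w[m] * logs) / np.sum(w[m])))
    return out


def persistence_pipeline(env_present: np.ndarray, env_future: np.ndarray,
                         condition_future: np.ndarray, areas: np.ndarray,
                         kernel: SimilarityKernel, partition: EcoregionPartition,
                         sar: SARParams = SARParams()) -> PersistenceResult:
    """Full per-cell → per-region persistence computation for one scenario."""
    eff_now = effective_areas_present(env_present, areas, kernel)
    eff_fut = effective_areas_scenario(env_present, env_future, condition_future, areas, kernel)
    ratio = eff_fut / eff_now
    p_cell = persistence_sar(ratio, sar.z)
    w = normalize_weights(1.0 / eff_now, partition)
    p_region = ecoregion_persistence(p_cell, w, partition)
    return PersistenceResult(p_cell=p_cell, p_region=p_region, weights=w, area_ratio=ratio)
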