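"""Regular lat/lon grids, raster fields, spherical cell areas, and resampling.

Conventions (enforced at construction):

* cell-edge registration — ``lat_bounds``/``lon_bounds`` are the outer edges
  and cell edges partition them exactly into ``n_lat`` × ``n_lon`` cells;
* latitude descending row order (row 0 is the northernmost band);
* longitude in [−180, 180), ascending column order;
* missing data is NaN; every raster in one analysis shares one grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

EARTH_RADIUS_M = 6_371_000.0


class ParameterError(ValueError):
    """A constructor or operation argument violates its contract."""


class DataError(ValueError):
    """Input rasters are inconsistent or missing where required."""


@dataclass(frozen=True)
class GridSpec:
    """A regular latitude/longitude grid with cell-edge registration."""

    n_lat: int
    n_lon: int
    lat_bounds: tuple[float, float] = (-90.0, 90.0)
    lon_bounds: tuple[float, float] = (-180.0, 180.0)

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ParameterError(f"n_lat/n_lon must be >= 1, got {self.n_lat}x{self.n_lon}")
        lo, hi = self.lat_bounds
        if not (-90.0 <= lo < hi <= 90.0):
            raise ParameterError(f"lat_bounds must be ordered within [-90, 90], got {self.lat_bounds}")
        lo, hi = self.lon_bounds
        if not (-180.0 <= lo < hi <= 180.0):
            raise ParameterError(f"lon_bounds must be ordered within [-180, 180], got {self.lon_bounds}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def lat_edges(self) -> np.ndarray:
        """Cell edges, northernmost first (descending)."""
        return np.linspace(self.lat_bounds[1], self.lat_bounds[0], self.n_lat + 1)

    @property
    def lon_edges(self) -> np.ndarray:
        return np.linspace(self.lon_bounds[0], self.lon_bounds[1], self.n_lon + 1)

    @property
    def lat_centers(self) -> np.ndarray:
        e = self.lat_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        e = self.lon_edges
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class RasterField:
    """Per-cell numeric values on a :class:`GridSpec`; NaN marks missing.

    ``categorical`` fields hold integer codes stored as floats; they may only
    be resampled with nearest-neighbour.
    """

    grid: GridSpec
    values: np.ndarray
    name: str = "field"
    units: str = ""
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise DataError(
                f"field '{self.name}' has shape {self.values.shape}, grid is {self.grid.shape}"
            )

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterField":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float),
                                   name=self.name if name is None else name)

    @property
    def mask_missing(self) -> np.ndarray:
        return np.isnan(self.values)


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Spherical-Earth cell areas in m², shape ``grid.shape``.

    A = R² · Δλ · (sin φ_top − sin φ_bottom) with R = 6 371 000 m.
    Areas are positive, symmetric about the equator, and shrink poleward.
    """
    lat_e = np.deg2rad(grid.lat_edges)  # descending
    dlon = np.deg2rad((grid.lon_bounds[1] - grid.lon_bounds[0]) / grid.n_lon)
    band = EARTH_RADIUS_M**2 * dlon * (np.sin(lat_e[:-1]) - np.sin(lat_e[1:]))
    return np.repeat(band[:, None], grid.n_lon, axis=1)


def resample(field: RasterField, target: GridSpec, method: str | None = None) -> RasterField:
    """Resample a raster onto ``target``.

    Categorical fields use nearest-neighbour only; continuous fields default
    to bilinear interpolation of cell-centre values. Missing cells (NaN)
    propagate: any bilinear stencil touching a NaN yields NaN. Target centres
    outside the source centre hull are clamped to the hull edge (constant
    extrapolation over the outer half-cell).
    """
    if method is None:
        method = "nearest" if field.categorical else "bilinear"
    if method not in ("nearest", "bilinear"):
        raise ParameterError(f"unknown resampling method {method!r}")
    if field.categorical and method == "bilinear":
        raise ParameterError(f"bilinear resampling requested for categorical field '{field.name}'")
    src, tgt = field.grid, target
    if (src.lat_bounds[0] >= tgt.lat_bounds[1] or tgt.lat_bounds[0] >= src.lat_bounds[1]
            or src.lon_bounds[0] >= tgt.lon_bounds[1] or tgt.lon_bounds[0] >= src.lon_bounds[1]):
        raise DataError("source and target grids do not overlap")

    # interpolate on ascending-latitude axes; flip back at the end
    lat_src = src.lat_centers[::-1]
    lon_src = src.lon_centers
    vals = field.values[::-1, :]
    lat_t = np.clip(tgt.lat_centers[::-1], lat_src[0], lat_src[-1])
    lon_t = np.clip(tgt.lon_centers, lon_src[0], lon_src[-1])

    if src.n_lat == 1 and src.n_lon == 1:
        out = np.full(tgt.shape, vals[0, 0])
        return RasterField(tgt, out, field.name, field.units, field.categorical)

    # RegularGridInterpolator needs >=2 points per axis; pad degenerate axes
    if src.n_lat == 1:
        lat_src = np.array([lat_src[0] - 0.5, lat_src[0] + 0.5])
        vals = np.vstack([vals, vals])
        lat_t = np.clip(lat_t, lat_src[0], lat_src[-1])
    if src.n_lon == 1:
        lon_src = np.array([lon_src[0] - 0.5, lon_src[0] + 0.5])
        vals = np.hstack([vals, vals])
        lon_t = np.clip(lon_t, lon_src[0], lon_src[-1])

    interp = RegularGridInterpolator(
        (lat_src, lon_src), vals,
        method="nearest" if method == "nearest" else "linear",
        bounds_error=False, fill_value=np.nan,
    )
    glat, glon = np.meshgrid(lat_t, lon_t, indexing="ij")
    out = interp(np.stack([glat.ravel(), glon.ravel()], axis=1)).reshape(tgt.shape)
    out = out[::-1, :]  # back to descending-latitude rows
    return RasterField(tgt, out, field.name, field.units, field.categorical)
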