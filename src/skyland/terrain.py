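"""Terrain derivatives and resistance-surface construction.

Implements the eight landscape surfaces used for circuit-theory connectivity
(slope, TPI, roughness, northness, westness, TWI, NDVI, solar incidence),
the Gaussian elevation-band suitability surface, rescaling onto a resistance
range, and elevation masking.

Conventions
-----------
* Slope/aspect use Horn's 3x3 finite differences, the de facto GIS standard.
* Aspect is the downslope compass direction (0 deg = north, 90 deg = east);
  cells with gradient magnitude < 1e-9 are "flat" and get NaN aspect, which
  the directional surfaces (northness/westness) map to 0.
* Any cell whose 3x3 window touches a masked cell or the grid boundary is
  masked in the output (NoData propagates; boundaries are not padded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterGrid

__all__ = [
    "SurfaceSpec",
    "BandParams",
    "slope_aspect",
    "northness",
    "westness",
    "tpi8",
    "roughness",
    "twi",
    "solar_incidence",
    "ndvi",
    "gaussian_band",
    "to_resistance",
    "elevation_mask",
    "make_surface",
    "DEFAULT_SURFACES",
]

FLAT_EPS = 1e-9


@dataclass(frozen=True)
class SurfaceSpec:
    """How a raw surface becomes a resistance surface.

    ``invert=True`` means high raw values are *favourable* (low resistance).
    """

    name: str
    invert: bool
    out_range: tuple[float, float] = (1.0, 100.0)

    def __post_init__(self) -> None:
        lo, hi = self.out_range
        if not lo < hi:
            raise ValueError("out_range must be increasing")
        if lo < 1.0:
            raise ValueError("resistance floor must be >= 1 (circuit edges)")


# Default inversion flags: north-facing, wet, vegetated terrain is favourable
# for a moisture-limited montane salamander; steep, rough, exposed, sunny
# terrain is unfavourable.
DEFAULT_SURFACES: dict[str, SurfaceSpec] = {
    "slope": SurfaceSpec("slope", invert=False),
    "tpi": SurfaceSpec("tpi", invert=False),
    "roughness": SurfaceSpec("roughness", invert=False),
    "northness": SurfaceSpec("northness", invert=True),
    "westness": SurfaceSpec("westness", invert=True),
    "twi": SurfaceSpec("twi", invert=True),
    "ndvi": SurfaceSpec("ndvi", invert=True),
    "solar": SurfaceSpec("solar", invert=False),
}


@dataclass(frozen=True)
class BandParams:
    """Gaussian elevation band: center z0 (m) and width sigma (m)."""

    z0: float
    sigma: float = 50.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def _window_valid(mask: np.ndarray) -> np.ndarray:
    """Cells whose full 3x3 window is unmasked and inside the grid."""
    ok = ~mask
    full = ndimage.uniform_filter(ok.astype(float), size=3, mode="constant", cval=0.0)
    valid = full > 1.0 - 1e-6
    valid[0, :] = valid[-1, :] = False
    valid[:, 0] = valid[:, -1] = False
    return valid


def _horn_gradients(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dz/dx eastward, dz/dy northward, valid mask) via Horn's stencil."""
    z = dem.values
    h = dem.cell_size
    # kernel indexing: rows go north -> south
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8 * h)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float) / (8 * h)
    zx = ndimage.correlate(z, kx, mode="nearest")
    zy = ndimage.correlate(z, ky, mode="nearest")
    return zx, zy, _window_valid(dem.nodata_mask)


def slope_aspect(dem: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Slope (degrees) and downslope aspect (compass degrees) via Horn.

    Flat cells (gradient < 1e-9) carry NaN aspect under an unmasked cell; use
    :func:`northness`/:func:`westness` for well-defined directional values.
    """
    zx, zy, valid = _horn_gradients(dem)
    grad = np.hypot(zx, zy)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(-zx, -zy)) % 360.0
    flat = grad < FLAT_EPS
    aspect = np.where(flat, np.nan, aspect)
    mask = ~valid
    slope_grid = dem.like(np.where(valid, slope, 0.0), mask)
    # NaN marks flat, not NoData, so bypass the finite-value invariant by
    # storing aspect with flats masked out of the invariant check:
    aspect_vals = np.where(valid, aspect, 0.0)
    aspect_grid = RasterGrid.__new__(RasterGrid)
    aspect_grid.values = aspect_vals
    aspect_grid.nodata_mask = mask.copy()
    aspect_grid.cell_size = dem.cell_size
    aspect_grid.origin = dem.origin
    aspect_grid.crs_label = dem.crs_label
    return slope_grid, aspect_grid


def northness(aspect: RasterGrid) -> RasterGrid:
    """cos(aspect): +1 north-facing, -1 south-facing, 0 on flat cells."""
    vals = np.cos(np.radians(aspect.values))
    vals = np.where(np.isnan(aspect.values), 0.0, vals)
    return RasterGrid(
        vals, aspect.nodata_mask.copy(), aspect.cell_size, aspect.origin,
        aspect.crs_label,
    )


def westness(aspect: RasterGrid) -> RasterGrid:
    """-sin(aspect): +1 west-facing, -1 east-facing, 0 on flat cells."""
    vals = -np.sin(np.radians(aspect.values))
    vals = np.where(np.isnan(aspect.values), 0.0, vals)
    return RasterGrid(
        vals, aspect.nodata_mask.copy(), aspect.cell_size, aspect.origin,
        aspect.crs_label,
    )


def tpi8(dem: RasterGrid) -> RasterGrid:
    """Topographic Position Index: center minus mean of its 8 neighbours."""
    kern = np.ones((3, 3)) / 8.0
    kern[1, 1] = 0.0
    neigh_mean = ndimage.correlate(dem.values, kern, mode="nearest")
    valid = _window_valid(dem.nodata_mask)
    vals = np.where(valid, dem.values - neigh_mean, 0.0)
    return dem.like(vals, ~valid)


def roughness(dem: RasterGrid) -> RasterGrid:
    """Range (max - min) of the 3x3 window."""
    mx = ndimage.maximum_filter(dem.values, size=3, mode="nearest")
    mn = ndimage.minimum_filter(dem.values, size=3, mode="nearest")
    valid = _window_valid(dem.nodata_mask)
    return dem.like(np.where(valid, mx - mn, 0.0), ~valid)


_D8_OFFSETS = [
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
]


def d8_flow_accumulation(dem: RasterGrid) -> np.ndarray:
    """Number of upstream cells draining through each cell (D8, steepest drop).

    Each cell sends all its flow to the single neighbour with the steepest
    positive drop (drop / distance, diagonals scaled by sqrt(2)); pits and
    flats drain nowhere. Masked cells neither send nor receive.
    """
    z = dem.values
    nrows, ncols = z.shape
    ok = ~dem.nodata_mask
    receiver = np.full((nrows, ncols), -1, dtype=np.int64)
    best = np.zeros((nrows, ncols))
    flat_index = np.arange(nrows * ncols).reshape(nrows, ncols)
    for dr, dc in _D8_OFFSETS:
        dist = np.hypot(dr, dc) * dem.cell_size
        zn = np.full_like(z, np.inf)
        okn = np.zeros_like(ok)
        rs = slice(max(dr, 0), nrows + min(dr, 0))
        cs = slice(max(dc, 0), ncols + min(dc, 0))
        rs0 = slice(max(-dr, 0), nrows + min(-dr, 0))
        cs0 = slice(max(-dc, 0), ncols + min(-dc, 0))
        zn[rs0, cs0] = z[rs, cs]
        okn[rs0, cs0] = ok[rs, cs]
        drop = np.where(okn, (z - zn) / dist, -np.inf)
        better = ok & (drop > best)
        best = np.where(better, drop, best)
        nbr = np.full((nrows, ncols), -1, dtype=np.int64)
        nbr[rs0, cs0] = flat_index[rs, cs]
        receiver = np.where(better, nbr, receiver)
    order = np.argsort(z, axis=None)[::-1]  # high to low
    acc = np.zeros(nrows * ncols, dtype=np.int64)
    recv = receiver.ravel()
    okf = ok.ravel()
    for i in order:
        r = recv[i]
        if okf[i] and r >= 0:
            acc[r] += acc[i] + 1
    return acc.reshape(nrows, ncols)


def twi(dem: RasterGrid, tan_beta_floor: float = 0.001) -> RasterGrid:
    """Topographic Wetness Index ln(a / tan(beta)).

    a is the specific catchment area (upstream cell count + 1) * cell_size,
    from D8 single-direction flow accumulation; tan(beta) is the Horn slope
    tangent floored at ``tan_beta_floor``.
    """
    zx, zy, valid = _horn_gradients(dem)
    tanb = np.maximum(np.hypot(zx, zy), tan_beta_floor)
    acc = d8_flow_accumulation(dem)
    a = (acc + 1.0) * dem.cell_size
    vals = np.log(a / tanb)
    return dem.like(np.where(valid, vals, 0.0), ~valid)


def solar_incidence(
    dem: RasterGrid, sun_azimuth: float = 180.0, sun_altitude: float = 51.0
) -> RasterGrid:
    """Cosine of the angle between surface normal and sun vector, clamped at 0.

    The default sun position approximates equinox noon at the study latitude
    (azimuth 180 deg, altitude 51 deg). Standard hillshade cosine:
    cos(i) = cos(zenith) cos(slope) + sin(zenith) sin(slope) cos(az - aspect).
    """
    if not 0.0 < sun_altitude <= 90.0:
        raise ValueError("sun_altitude must be in (0, 90] degrees")
    zx, zy, valid = _horn_gradients(dem)
    grad = np.hypot(zx, zy)
    slope_r = np.arctan(grad)
    aspect_r = np.arctan2(-zx, -zy) % (2 * np.pi)
    zen = np.radians(90.0 - sun_altitude)
    az = np.radians(sun_azimuth)
    cosi = np.cos(zen) * np.cos(slope_r) + np.sin(zen) * np.sin(slope_r) * np.cos(
        az - aspect_r
    )
    # flat cells: aspect undefined but sin(slope)=0 so the formula is exact
    vals = np.clip(cosi, 0.0, 1.0)
    return dem.like(np.where(valid, vals, 0.0), ~valid)


def ndvi(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """(NIR - red) / (NIR + red); zero-sum cells are masked."""
    if red.shape != nir.shape:
        raise ValueError("red and nir rasters differ in shape")
    total = nir.values + red.values
    mask = red.nodata_mask | nir.nodata_mask | (total == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(mask, 0.0, (nir.values - red.values) / np.where(total == 0, 1, total))
    return red.like(vals, mask)


def gaussian_band(dem: RasterGrid, params: BandParams) -> RasterGrid:
    """Suitability exp(-(z - z0)^2 / (2 sigma^2)) in [0, 1]."""
    s = np.exp(-((dem.values - params.z0) ** 2) / (2.0 * params.sigma**2))
    return dem.like(np.where(dem.nodata_mask, 0.0, s), dem.nodata_mask.copy())


def to_resistance(surface: RasterGrid, spec: SurfaceSpec) -> RasterGrid:
    """Affine rescale onto [lo, hi] resistance; inversion negates first.

    The surface minimum maps exactly to lo and the maximum to hi, so higher
    output always means higher expected landscape resistance.
    """
    vals = surface.values[~surface.nodata_mask]
    if vals.size == 0:
        raise ValueError("surface fully masked")
    vmin, vmax = vals.min(), vals.max()
    if vmax - vmin < 1e-300:
        raise ValueError(
            "constant surface cannot be rescaled; use a uniform resistance "
            "surface (base resistance) instead"
        )
    v = -surface.values if spec.invert else surface.values
    if spec.invert:
        vmin, vmax = -vmax, -vmin
    lo, hi = spec.out_range
    out = lo + (v - vmin) * (hi - lo) / (vmax - vmin)
    out = np.where(surface.nodata_mask, 0.0, out)
    return surface.like(out, surface.nodata_mask.copy())


def elevation_mask(surface: RasterGrid, dem: RasterGrid, cutoff: float) -> RasterGrid:
    """Mask cells strictly below ``cutoff`` elevation (cells at cutoff stay)."""
    if surface.shape != dem.shape:
        raise ValueError("surface and DEM differ in shape")
    below = (~dem.nodata_mask) & (dem.values < cutoff)
    new_mask = surface.nodata_mask | below | dem.nodata_mask
    if new_mask.all():
        raise ValueError(f"cutoff {cutoff} m masks the entire landscape")
    return surface.like(np.where(new_mask, 0.0, surface.values), new_mask)


def make_surface(
    dem: RasterGrid,
    name: str,
    *,
    red: RasterGrid | None = None,
    nir: RasterGrid | None = None,
    tpi_absolute: bool = False,
    sun_azimuth: float = 180.0,
    sun_altitude: float = 51.0,
) -> RasterGrid:
    """Compute one of the eight raw landscape surfaces by name."""
    if name == "slope":
        return slope_aspect(dem)[0]
    if name == "tpi":
        raw = tpi8(dem)
        return raw.like(np.abs(raw.values), raw.nodata_mask) if tpi_absolute else raw
    if name == "roughness":
        return roughness(dem)
    if name == "northness":
        return northness(slope_aspect(dem)[1])
    if name == "westness":
        return westness(slope_aspect(dem)[1])
    if name == "twi":
        return twi(dem)
    if name == "solar":
        return solar_incidence(dem, sun_azimuth, sun_altitude)
    if name == "ndvi":
        if red is None or nir is None:
            raise ValueError("ndvi requires red and nir rasters")
        return ndvi(red, nir)
    raise ValueError(f"unknown surface {name!r}")
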