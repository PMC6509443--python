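"""Corridor-level comparison of circuit resistances.

The three population transitions are named after the study system: the
northern corridor (C-N), the southern corridor (C-S), and the complete
corridor (N-S, bypassing the central mountain). The comparison layer is
deliberately descriptive — with only three populations there are too few
pairs for model-based inference — and consists of:

* the normalized corridor difference
  (r_north - r_south) / ((r_north + r_south) / 2), negative when the
  northern corridor has the lower resistance;
* the stepwise-dispersal check: is the complete corridor strictly costlier
  than both single-step corridors?
* the elevation sweep: Gaussian suitability bands at a range of center
  elevations, each turned into a resistance surface and solved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuits import pairwise_resistance
from .raster import RasterGrid
from .terrain import BandParams, SurfaceSpec, elevation_mask, gaussian_band, to_resistance

__all__ = [
    "CorridorResult",
    "normalized_difference",
    "corridor_result",
    "corridor_table",
    "stepwise_check",
    "elevation_sweep",
]


@dataclass(frozen=True)
class CorridorResult:
    surface_name: str
    r_north: float  # C <-> N
    r_south: float  # C <-> S
    r_complete: float  # N <-> S
    masked: bool
    norm_diff: float

    @property
    def combined_mean(self) -> float:
        """Mean of the two single-step corridor resistances."""
        return 0.5 * (self.r_north + self.r_south)


def normalized_difference(r_north: float, r_south: float) -> float:
    """(r_north - r_south) / mean(r_north, r_south); NaN if either is infinite.

    Antisymmetric under swapping the corridors, scale-invariant, bounded in
    [-2, 2] for positive inputs; negative means the northern corridor is the
    easier one.
    """
    if not (math.isfinite(r_north) and math.isfinite(r_south)):
        return float("nan")
    if r_north <= 0 or r_south <= 0:
        raise ValueError("corridor resistances must be positive")
    return (r_north - r_south) / ((r_north + r_south) / 2.0)


def corridor_result(
    surface_name: str,
    resist: pd.DataFrame,
    masked: bool,
) -> CorridorResult:
    """Package a 3x3 pairwise-resistance matrix into corridor terms."""
    r_n = float(resist.loc["C", "N"])
    r_s = float(resist.loc["C", "S"])
    r_c = float(resist.loc["N", "S"])
    return CorridorResult(
        surface_name=surface_name,
        r_north=r_n,
        r_south=r_s,
        r_complete=r_c,
        masked=masked,
        norm_diff=normalized_difference(r_n, r_s),
    )


def corridor_table(
    surfaces: dict[str, RasterGrid],
    dem: RasterGrid,
    localities: pd.DataFrame,
    cutoff: float | None = 500.0,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Corridor resistances for each surface on the full and masked extents.

    Per-surface failures (for instance a corridor severed by the elevation
    mask) are recorded in the output rather than aborting the run.
    """
    rows = []
    extents: list[tuple[str, bool]] = [("full", False)]
    if cutoff is not None:
        extents.append(("masked", True))
    for name in sorted(surfaces):
        for extent, use_mask in extents:
            try:
                surf = surfaces[name]
                if use_mask:
                    surf = elevation_mask(surf, dem, cutoff)
                res = corridor_result(
                    name, pairwise_resistance(surf, localities, connectivity), use_mask
                )
                rows.append(
                    {
                        "surface": name,
                        "extent": extent,
                        "r_north": res.r_north,
                        "r_south": res.r_south,
                        "r_complete": res.r_complete,
                        "norm_diff": res.norm_diff,
                        "error": "",
                    }
                )
            except Exception as exc:  # keep going; record the failure
                rows.append(
                    {
                        "surface": name,
                        "extent": extent,
                        "r_north": np.nan,
                        "r_south": np.nan,
                        "r_complete": np.nan,
                        "norm_diff": np.nan,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)


def stepwise_check(result: CorridorResult) -> tuple[bool, dict]:
    """True when the complete corridor is strictly costlier than both steps.

    A True outcome supports stepwise dispersal (N <-> S gene flow routed
    through C). The report carries the ratios of the complete-corridor
    resistance to each single-step corridor.
    """
    vals = (result.r_north, result.r_south, result.r_complete)
    if not all(math.isfinite(v) for v in vals):
        return False, {"disconnected": True}
    ok = result.r_complete > max(result.r_north, result.r_south)
    return ok, {
        "disconnected": False,
        "ratio_vs_north": result.r_complete / result.r_north,
        "ratio_vs_south": result.r_complete / result.r_south,
    }


def elevation_sweep(
    dem: RasterGrid,
    localities: pd.DataFrame,
    centers: np.ndarray | None = None,
    sigma: float = 50.0,
    mask_cutoff: float | None = 500.0,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Gaussian elevation-band sweep.

    For each band center: suitability exp(-(z - z0)^2 / 2 sigma^2), rescaled
    (inverted) onto [1, 100] resistance, optionally restricted to elevations
    at or above ``mask_cutoff``, then solved for the three corridor
    resistances. The per-band rows are independent of processing order.
    """
    if centers is None:
        centers = np.arange(800.0, 1_201.0, 50.0)
    unmasked = dem.values[~dem.nodata_mask]
    if centers.min() < unmasked.min() or centers.max() > unmasked.max():
        raise ValueError("band centers must lie within the DEM elevation range")
    spec = SurfaceSpec("band", invert=True)
    rows = []
    for z0 in centers:
        surf = to_resistance(gaussian_band(dem, BandParams(float(z0), sigma)), spec)
        if mask_cutoff is not None:
            surf = elevation_mask(surf, dem, mask_cutoff)
        resist = pairwise_resistance(surf, localities, connectivity)
        res = corridor_result(f"band_{int(z0)}", resist, mask_cutoff is not None)
        rows.append(
            {
                "center": float(z0),
                "r_north": res.r_north,
                "r_south": res.r_south,
                "r_complete": res.r_complete,
                "norm_diff": res.norm_diff,
                "combined_mean": res.combined_mean,
                "disconnected": not (
                    math.isfinite(res.r_north) and math.isfinite(res.r_south)
                ),
            }
        )
    return pd.DataFrame(rows)
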