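"""Indicator preprocessing: scale/offset conversion, tasseled-cap wetness,
zonal aggregation, and observation bookkeeping for MODIS-style composites.

MODIS products store physical quantities as scaled integers; the
conversions used here are the standard product conventions (LST: digital
number x 0.02 K then -273.15 to Celsius; NDVI and surface reflectance:
x 0.0001), all overridable through :class:`ScaleSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from shapely import intersects_xy

from .data_model import RasterGrid, Region


@dataclass(frozen=True)
class ScaleSpec:
    """Affine conversion out = in * scale + offset, with a post-conversion
    validity envelope; cells falling outside become nodata."""

    scale: float = 1.0
    offset: float = 0.0
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.scale == 0:
            raise ValueError("scale must be nonzero")
        if self.valid_range is not None and self.valid_range[0] > self.valid_range[1]:
            raise ValueError(f"invalid valid_range {self.valid_range}")


#: Default conversions per indicator (MODIS product conventions).  The LST
#: envelope [0, 69] degC mirrors the observed study-area extrema.
DEFAULT_SCALES: dict[str, ScaleSpec] = {
    "LST": ScaleSpec(scale=0.02, offset=-273.15, valid_range=(0.0, 69.0)),
    "NDVI": ScaleSpec(scale=0.0001, offset=0.0, valid_range=(-0.2, 1.0)),
    "reflectance": ScaleSpec(scale=0.0001, offset=0.0, valid_range=(-0.01, 1.6)),
    "LAI": ScaleSpec(scale=0.1, offset=0.0, valid_range=(0.0, 7.0)),
    "GPP": ScaleSpec(scale=0.0001, offset=0.0, valid_range=(0.0, 30.0)),
}

#: 7-band MODIS tasseled-cap wetness coefficients (bands 1-7 of the
#: surface-reflectance product).
MODIS_WETNESS_COEFFICIENTS: tuple[float, ...] = (
    0.1147, 0.2489, 0.2408, 0.3132, -0.3122, -0.6416, -0.5087,
)


def apply_scale(raster: RasterGrid, spec: ScaleSpec) -> RasterGrid:
    """Convert a raster to physical units; the nodata mask only grows."""
    out = raster.values * spec.scale + spec.offset
    mask = raster.nodata_mask.copy()
    if spec.valid_range is not None:
        lo, hi = spec.valid_range
        with np.errstate(invalid="ignore"):
            mask |= (out < lo) | (out > hi)
    return _dc_replace(raster, values=np.where(mask, np.nan, out), nodata_mask=mask)


def tct_wetness(bands: list[RasterGrid],
                coefficients=MODIS_WETNESS_COEFFICIENTS) -> RasterGrid:
    """Tasseled-cap wetness: pixelwise dot product of reflectance bands.

    Nodata wherever any input band is nodata.
    """
    if len(bands) != len(coefficients):
        raise ValueError(f"{len(bands)} bands but {len(coefficients)} coefficients")
    shapes = {b.values.shape for b in bands}
    if len(shapes) != 1:
        raise ValueError(f"band shape mismatch: {sorted(shapes)}")
    mask = np.zeros(bands[0].values.shape, dtype=bool)
    for b in bands:
        mask |= b.nodata_mask
    wet = np.zeros(bands[0].values.shape)
    for b, c in zip(bands, coefficients):
        wet += c * np.where(b.nodata_mask, 0.0, b.values)
    return RasterGrid(values=np.where(mask, np.nan, wet), nodata_mask=mask,
                      transform=bands[0].transform, variable="Wet",
                      timepoint=bands[0].timepoint)


def zonal_mean(raster: RasterGrid, regions: list[Region]) -> dict[str, float]:
    """Per-region mean over unmasked pixels whose centers fall inside the
    region polygon.

    A pixel belongs to at most one region (first region in order wins on
    boundary ties).  Regions with no valid pixel map to NaN; if no region
    receives any pixel the raster and geometry do not overlap → error.
    """
    xs, ys = raster.pixel_centers()
    flat_x, flat_y = xs.ravel(), ys.ravel()
    vals = raster.values.ravel()
    ok = ~raster.nodata_mask.ravel()
    claimed = np.zeros(flat_x.shape, dtype=bool)
    out: dict[str, float] = {}
    any_hit = False
    for r in regions:
        inside = intersects_xy(r.geometry, flat_x, flat_y) & ~claimed
        claimed |= inside
        if inside.any():
            any_hit = True
        use = inside & ok
        out[r.id] = float(vals[use].mean()) if use.any() else float("nan")
    if not any_hit:
        raise ValueError("no region intersects the raster")
    return out


def composites_per_year(cadence_days: int) -> int:
    """Number of composite observations per year for a fixed revisit
    cadence: ceil(365 / cadence) → 46 for 8-day products, 23 for 16-day."""
    if cadence_days <= 0:
        raise ValueError("cadence must be positive")
    return math.ceil(365 / cadence_days)


def annual_observations(cadence_days: int, n_regions: int) -> int:
    """Total per-year observation count over all regions: composites per
    year times region count (e.g. 46 x 16 = 736 for 8-day products)."""
    return composites_per_year(cadence_days) * n_regions
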