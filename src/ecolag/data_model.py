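"""Core domain containers and plain-text I/O.

The study object is a small panel: a handful of regions (cities or
prefectures), a few census timepoints, and one variable per table
(an ecological indicator, the composite ecological index CEI, or life
expectancy LE).  ``PanelTable`` wraps a region x timepoint matrix with an
explicit missing mask; ``Region`` carries an id, a display name and an
optional planar polygon used only for contiguity; ``RasterGrid`` is a
masked 2-D field with an optional affine georeference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import shape, mapping
from shapely.geometry.base import BaseGeometry


@dataclass
class Region:
    """A study unit: a city or prefecture with an optional polygon."""

    id: str
    name: str = ""
    geometry: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if self.geometry is not None and self.geometry.geom_type not in (
            "Polygon",
            "MultiPolygon",
        ):
            raise ValueError(
                f"region {self.id!r}: geometry must be Polygon or MultiPolygon, "
                f"got {self.geometry.geom_type}"
            )


@dataclass
class PanelTable:
    """Region x timepoint matrix of one variable.

    ``timepoints`` are labels whose numeric year values drive all time
    arithmetic (interpolation, Sen slopes, lag offsets), so a 5- or
    10-year lag is explicit rather than positional.
    """

    variable: str
    region_ids: list[str]
    timepoints: list[int]
    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    filled_mask: np.ndarray | None = None  # provenance of interpolated cells

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, t = len(self.region_ids), len(self.timepoints)
        if self.values.shape != (n, t):
            raise ValueError(
                f"values shape {self.values.shape} != ({n} regions, {t} timepoints)"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        if len(set(self.region_ids)) != n:
            dupes = sorted({r for r in self.region_ids if self.region_ids.count(r) > 1})
            raise ValueError(f"duplicate region ids: {dupes}")
        tp = [float(t_) for t_ in self.timepoints]
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError(f"timepoints not strictly increasing: {self.timepoints}")
        # a cell is either finite or flagged missing, never both
        bad = ~np.isfinite(self.values) & ~self.missing_mask
        if bad.any():
            raise ValueError("non-finite cell not flagged missing")
        self.values = np.where(self.missing_mask, np.nan, self.values)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def column(self, timepoint: int) -> np.ndarray:
        """Values for one timepoint, NaN where missing."""
        return self.values[:, self.timepoints.index(timepoint)].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.region_ids, name="region_id"),
            columns=self.timepoints,
        )


@dataclass
class RasterGrid:
    """2-D field with a nodata mask; masked cells enter no statistic."""

    values: np.ndarray
    nodata_mask: np.ndarray
    transform: tuple[float, float, float, float, float, float] | None = None
    variable: str = ""
    timepoint: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every pixel center.

        transform = (a, b, c, d, e, f): x = a*col + b*row + c, y = d*col +
        e*row + f, evaluated at col+0.5, row+0.5.  Identity when absent.
        """
        nrow, ncol = self.values.shape
        a, b, c, d, e, f = self.transform or (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)
        cols, rows = np.meshgrid(np.arange(ncol) + 0.5, np.arange(nrow) + 0.5)
        return a * cols + b * rows + c, d * cols + e * rows + f


# ---------------------------------------------------------------------------
# Panel CSV I/O: first column region_id, remaining columns timepoint labels.

def read_panel_csv(path, variable: str) -> PanelTable:
    """Read a region x timepoint CSV into a :class:`PanelTable`.

    Empty/NA cells become missing; column order defines timepoint order;
    finite cells round-trip bit-exactly through :func:`write_panel_csv`.
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValueError(f"{path}: empty or header-only panel CSV")
    ids = df.iloc[:, 0].tolist()
    dup = sorted({r for r in ids if ids.count(r) > 1})
    if dup:
        raise ValueError(f"{path}: duplicate region ids {dup}")
    timepoints = [int(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    values = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            if pd.isna(cell) or (isinstance(cell, str) and cell.strip() == ""):
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {ids[i]!r}, "
                    f"column {col!r}"
                ) from None
    return PanelTable(variable=variable, region_ids=ids,
                      timepoints=timepoints, values=values)


def write_panel_csv(panel: PanelTable, path) -> None:
    """Inverse of :func:`read_panel_csv`; missing cells written empty."""
    df = panel.to_frame()
    # repr round-trips float64 exactly
    df.to_csv(path, float_format=None, na_rep="")


def read_regions_geojson(path) -> list[Region]:
    """Read an RFC 7946 FeatureCollection of (multi)polygons.

    Each feature needs an ``id`` (or ``name``) property; file order is
    preserved and ids must be unique.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a FeatureCollection")
    regions: list[Region] = []
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        rid = props.get("id", feat.get("id"))
        if rid is None:
            rid = props.get("name")
        if rid is None:
            raise ValueError(f"{path}: feature {k} has no id or name property")
        geom = shape(feat["geometry"])
        regions.append(Region(id=str(rid), name=str(props.get("name", rid)),
                              geometry=geom))
    ids = [r.id for r in regions]
    dup = sorted({r for r in ids if ids.count(r) > 1})
    if dup:
        raise ValueError(f"{path}: duplicate region ids {dup}")
    return regions


def write_regions_geojson(regions: list[Region], path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"id": r.id, "name": r.name},
                "geometry": mapping(r.geometry),
            }
            for r in regions
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


# ---------------------------------------------------------------------------
# Text-grid raster I/O: "NCOLS/NROWS/NODATA" header, whitespace-delimited.

def read_text_grid(path, variable: str = "", timepoint: int | None = None) -> RasterGrid:
    """Read the plain-text grid dialect: header lines ``NCOLS n``, ``NROWS n``,
    ``NODATA v``, optional ``TRANSFORM a b c d e f``, then the rows."""
    header: dict[str, list[float]] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].upper() in ("NCOLS", "NROWS", "NODATA", "TRANSFORM"):
                header[parts[0].upper()] = [float(p) for p in parts[1:]]
            else:
                rows.append([float(p) for p in parts])
    if "NODATA" not in header:
        raise ValueError(f"{path}: missing NODATA header")
    values = np.asarray(rows, dtype=float)
    nodata = header["NODATA"][0]
    mask = values == nodata
    transform = tuple(header["TRANSFORM"]) if "TRANSFORM" in header else None
    return RasterGrid(values=np.where(mask, np.nan, values), nodata_mask=mask,
                      transform=transform, variable=variable, timepoint=timepoint)


def write_text_grid(raster: RasterGrid, path, nodata: float = -9999.0) -> None:
    with open(path, "w") as fh:
        nrow, ncol = raster.values.shape
        fh.write(f"NCOLS {ncol}\nNROWS {nrow}\nNODATA {nodata}\n")
        if raster.transform is not None:
            fh.write("TRANSFORM "
                     + " ".join(repr(float(v)) for v in raster.transform) + "\n")
        out = np.where(raster.nodata_mask, nodata, raster.values)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Shipped reference tables.

def load_le_table() -> PanelTable:
    """Published life-expectancy table for the 16 study regions
    (years 2010/2015/2020, in years of LE at birth)."""
    from importlib.resources import files

    path = files("ecolag.data").joinpath("le_belt_road.csv")
    with path.open("rb") as fh:  # type: ignore[union-attr]
        return read_panel_csv(fh, "LE")


def load_pca_contributions() -> dict:
    """Published per-year PCA variance-contribution rates (percent) for the
    five-indicator index, with their published cumulative sums."""
    from importlib.resources import files

    path = files("ecolag.data").joinpath("pca_contributions.json")
    return json.loads(path.read_text())


# ---------------------------------------------------------------------------

def interpolate_missing(panel: PanelTable) -> PanelTable:
    """Fill missing cells by piecewise-linear interpolation in numeric time.

    Interior gaps are linearly interpolated between the bracketing
    observations; leading/trailing gaps are linearly extrapolated from the
    two nearest observed points (constant fill when only one observation
    exists).  Observed cells are untouched and ``filled_mask`` records
    which cells were synthesised.  Idempotent, and exact on affine ramps.
    """
    times = np.array([float(t) for t in panel.timepoints])
    values = panel.values.copy()
    filled = panel.missing_mask.copy()
    for i, rid in enumerate(panel.region_ids):
        obs = ~panel.missing_mask[i]
        if not obs.any():
            raise ValueError(f"region {rid!r} has no observed timepoints")
        if obs.all():
            continue
        to, vo = times[obs], values[i, obs]
        if len(to) == 1:
            values[i, ~obs] = vo[0]
        else:
            # np.interp handles interiors; edges get two-point extrapolation
            values[i, ~obs] = np.interp(times[~obs], to, vo)
            lo_slope = (vo[1] - vo[0]) / (to[1] - to[0])
            hi_slope = (vo[-1] - vo[-2]) / (to[-1] - to[-2])
            before, after = times < to[0], times > to[-1]
            values[i, before & ~obs] = vo[0] + lo_slope * (times[before & ~obs] - to[0])
            values[i, after & ~obs] = vo[-1] + hi_slope * (times[after & ~obs] - to[-1])
    prior = panel.filled_mask if panel.filled_mask is not None else np.zeros_like(filled)
    return replace(
        panel,
        values=values,
        missing_mask=np.zeros_like(panel.missing_mask),
        filled_mask=filled | prior,
    )
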