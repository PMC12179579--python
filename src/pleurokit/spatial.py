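"""Pseudo-occurrence ranges, occupancy grids and area-weighted trait surfaces.

Species in this group mostly lack georeferenced occurrences; what exists is
a list of botanical recording regions (TDWG-style region ids) plus an
elevation band per taxon.  A taxon's pseudo-occurrence range is therefore
the set of fine raster cells whose region id is in the taxon's region list
and whose elevation falls inside the band (bounds inclusive).  Ranges are
aggregated onto a coarse grid (default 0.5 arc degree) as per-taxon
occupied area, with presence scored when the occupied area exceeds 5% of
the cell area; trait surfaces are occupied-area-weighted means over the
taxa present in each coarse cell.

Rasters are plain lon/lat arrays (row 0 = north) with an ESRI ASCII grid
text representation; cell areas use the spherical approximation
area ∝ cos(latitude of the cell-row center).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Raster",
    "TaxonRange",
    "OccupancyGrid",
    "EARTH_KM_PER_DEG",
    "PRESENCE_AREA_FRACTION",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_range_table",
    "cell_area_km2",
    "reconstruct_range",
    "grid_occupancy",
    "build_occupancy",
    "weighted_trait_surface",
    "species_density",
    "ecoregion_summary",
    "taxon_env_stats",
]

EARTH_KM_PER_DEG = 111.32  # km per arc degree along a meridian
PRESENCE_AREA_FRACTION = 0.05  # strict ">" rule


@dataclass
class Raster:
    """Rectangular lon/lat grid; data[0, :] is the northernmost row."""

    data: np.ndarray
    west: float
    south: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.cellsize

    def row_lats(self) -> np.ndarray:
        """Latitude of each row center, north to south."""
        return self.north - (np.arange(self.nrows) + 0.5) * self.cellsize

    def valid_mask(self) -> np.ndarray:
        return ~(np.isnan(self.data) | (self.data == self.nodata))

    def same_grid_as(self, other: "Raster") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.west, other.west)
            and np.isclose(self.south, other.south)
            and np.isclose(self.cellsize, other.cellsize)
        )


def _require_same_grid(*rasters: Raster) -> None:
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid_as(r):
            raise ValueError("rasters are not co-registered (shape/origin/cellsize differ)")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: Dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split() and not _is_number(lines[i].split()[0]):
        key, value = lines[i].split()[:2]
        header[key.lower()] = float(value)
        i += 1
    data = np.loadtxt(lines[i:])
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", -9999.0)
    west = header.get("xllcorner")
    south = header.get("yllcorner")
    cs = header.get("cellsize")
    if west is None or south is None or cs is None:
        raise ValueError("ASCII grid header missing xllcorner/yllcorner/cellsize")
    data = np.where(data == nodata, np.nan, data)
    return Raster(data=data, west=west, south=south, cellsize=cs, nodata=nodata)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_ascii_grid(raster: Raster, path) -> None:
    data = np.where(np.isnan(raster.data), raster.nodata, raster.data)
    with open(path, "w") as fh:
        fh.write("ncols %d\n" % raster.ncols)
        fh.write("nrows %d\n" % raster.nrows)
        fh.write("xllcorner %.10g\n" % raster.west)
        fh.write("yllcorner %.10g\n" % raster.south)
        fh.write("cellsize %.10g\n" % raster.cellsize)
        fh.write("NODATA_value %.10g\n" % raster.nodata)
        np.savetxt(fh, data, fmt="%.8g")


@dataclass(frozen=True)
class TaxonRange:
    taxon: str
    region_ids: frozenset
    elev_min: float
    elev_max: float

    def __post_init__(self):
        object.__setattr__(self, "region_ids", frozenset(int(r) for r in self.region_ids))
        if not self.region_ids:
            raise ValueError("taxon %r has no regions" % self.taxon)
        if self.elev_min > self.elev_max:
            raise ValueError("taxon %r: elev_min > elev_max" % self.taxon)


def read_range_table(path) -> List[TaxonRange]:
    """TSV columns: taxon, regions (comma-separated ids), elev_min, elev_max."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(TaxonRange(
            taxon=row["taxon"],
            region_ids=frozenset(int(x) for x in str(row["regions"]).split(",")),
            elev_min=float(row["elev_min"]),
            elev_max=float(row["elev_max"]),
        ))
    return out


def cell_area_km2(raster: Raster) -> np.ndarray:
    """Per-cell area (km^2), constant within each row: (111.32 * cs)^2 cos(lat)."""
    lats = np.radians(raster.row_lats())
    row_area = (EARTH_KM_PER_DEG * raster.cellsize) ** 2 * np.cos(lats)
    return np.repeat(row_area[:, None], raster.ncols, axis=1)


def reconstruct_range(tr: TaxonRange, region_mask: Raster, dem: Raster) -> Raster:
    """Boolean in-range mask: region id matches and elevation in band.

    Cells lacking region or elevation data are out of range.
    """
    _require_same_grid(region_mask, dem)
    valid = region_mask.valid_mask() & dem.valid_mask()
    in_region = np.isin(region_mask.data, list(tr.region_ids))
    in_band = (dem.data >= tr.elev_min) & (dem.data <= tr.elev_max)
    mask = (valid & in_region & in_band).astype(float)
    return Raster(mask, region_mask.west, region_mask.south, region_mask.cellsize,
                  nodata=region_mask.nodata)


@dataclass
class OccupancyGrid:
    """Per-taxon occupied area (km^2) and presence on a coarse grid."""

    west: float
    south: float
    cellsize: float
    cell_area: np.ndarray  # total (fine-cell-summed) area per coarse cell
    occupied_area: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.cell_area.shape

    def presence(self, taxon: str) -> np.ndarray:
        """Presence by the strict 5%-of-cell-area rule."""
        return self.occupied_area[taxon] > PRESENCE_AREA_FRACTION * self.cell_area

    def taxa(self) -> List[str]:
        return sorted(self.occupied_area)


def _coarse_factor(fine: Raster, coarse_cellsize: float) -> int:
    factor = coarse_cellsize / fine.cellsize
    if abs(factor - round(factor)) > 1e-8:
        raise ValueError("coarse cell size must be an integer multiple of fine cell size")
    factor = int(round(factor))
    if fine.nrows % factor or fine.ncols % factor:
        raise ValueError("fine raster extent is not a whole number of coarse cells")
    return factor


def _block_sum(a: np.ndarray, factor: int) -> np.ndarray:
    nr, nc = a.shape
    return a.reshape(nr // factor, factor, nc // factor, factor).sum(axis=(1, 3))


def grid_occupancy(mask: Raster, coarse_cellsize: float = 0.5) -> Tuple[np.ndarray, np.ndarray]:
    """Aggregate a fine in-range mask to coarse occupied area.

    Returns (occupied_area, cell_area) in km^2 on the coarse grid.
    """
    factor = _coarse_factor(mask, coarse_cellsize)
    fine_area = cell_area_km2(mask)
    in_range = np.nan_to_num(mask.data, nan=0.0)
    occupied = _block_sum(fine_area * in_range, factor)
    total = _block_sum(fine_area, factor)
    return occupied, total


def build_occupancy(
    ranges: Sequence[TaxonRange],
    region_mask: Raster,
    dem: Raster,
    coarse_cellsize: float = 0.5,
) -> OccupancyGrid:
    """Reconstruct every taxon's range and aggregate onto one coarse grid."""
    _require_same_grid(region_mask, dem)
    factor = _coarse_factor(dem, coarse_cellsize)
    fine_area = cell_area_km2(dem)
    cell_area = _block_sum(fine_area, factor)
    grid = OccupancyGrid(
        west=dem.west, south=dem.south, cellsize=coarse_cellsize, cell_area=cell_area
    )
    for tr in ranges:
        mask = reconstruct_range(tr, region_mask, dem)
        occupied = _block_sum(fine_area * np.nan_to_num(mask.data, nan=0.0), factor)
        grid.occupied_area[tr.taxon] = occupied
    return grid


def _coarse_raster(grid: OccupancyGrid, data: np.ndarray) -> Raster:
    return Raster(data, grid.west, grid.south, grid.cellsize, nodata=-9999.0)


def weighted_trait_surface(grid: OccupancyGrid, traits: Dict[str, float]) -> Raster:
    """Occupied-area-weighted mean trait over present taxa, nodata elsewhere."""
    missing = [t for t in grid.taxa() if t not in traits]
    if missing:
        raise ValueError("missing trait values for: %s" % ", ".join(missing))
    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    for taxon in grid.taxa():
        present = grid.presence(taxon)
        w = np.where(present, grid.occupied_area[taxon], 0.0)
        num += w * traits[taxon]
        den += w
    with np.errstate(invalid="ignore"):
        surface = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return _coarse_raster(grid, surface)


def species_density(
    grid: OccupancyGrid, endo_type: Dict[str, str]
) -> Dict[str, Raster]:
    """Presence counts: total, PE, CE, and the PE:CE ratio (nodata when CE=0)."""
    total = np.zeros(grid.shape)
    pe = np.zeros(grid.shape)
    ce = np.zeros(grid.shape)
    for taxon in grid.taxa():
        present = grid.presence(taxon).astype(float)
        total += present
        kind = endo_type.get(taxon)
        if kind == "PE":
            pe += present
        elif kind == "CE":
            ce += present
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(ce > 0, pe / np.where(ce > 0, ce, 1.0), np.nan)
    ratio = np.where(total > 0, ratio, np.nan)
    t = np.where(total > 0, total, np.nan)
    return {
        "total": _coarse_raster(grid, t),
        "PE": _coarse_raster(grid, np.where(total > 0, pe, np.nan)),
        "CE": _coarse_raster(grid, np.where(total > 0, ce, np.nan)),
        "PE_CE_ratio": _coarse_raster(grid, ratio),
    }


def ecoregion_summary(surface: Raster, ecoregions: Raster) -> Dict[int, np.ndarray]:
    """Per-ecoregion distribution of surface values (nodata cells excluded)."""
    _require_same_grid(surface, ecoregions)
    valid = surface.valid_mask() & ecoregions.valid_mask()
    out: Dict[int, np.ndarray] = {}
    for rid in np.unique(ecoregions.data[ecoregions.valid_mask()]):
        sel = valid & (ecoregions.data == rid)
        out[int(rid)] = np.sort(surface.data[sel])
    return out


def taxon_env_stats(
    mask: Raster,
    env: Raster,
    percentiles: Sequence[float] = (10, 25, 50, 75, 90),
    uncertainty_bounds: Sequence[Tuple[float, float]] = ((47.5, 52.5), (45.0, 55.0)),
) -> Dict[str, float]:
    """Percentiles, mean, sd of an environmental layer over a range mask.

    Also returns the percentile-bound pairs used for predictor-uncertainty
    resampling (median +/- 2.5% and +/- 5% by default), as keys
    "p<lo>"/"p<hi>" plus ("lo_2.5", "hi_2.5") style bound entries.
    """
    _require_same_grid(mask, env)
    sel = (np.nan_to_num(mask.data, nan=0.0) > 0) & env.valid_mask()
    values = env.data[sel]
    if values.size == 0:
        raise ValueError("taxon range covers no valid environmental cells")
    out: Dict[str, float] = {}
    for p in percentiles:
        out["p%g" % p] = float(np.percentile(values, p))
    out["mean"] = float(np.mean(values))
    out["sd"] = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    for lo, hi in uncertainty_bounds:
        half_width = (hi - lo) / 2.0
        out["lo_%g" % half_width] = float(np.percentile(values, lo))
        out["hi_%g" % half_width] = float(np.percentile(values, hi))
    return out
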