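"""Species-range gridding, breeding-season climate and insularity.

The workflow mirrors the standard range-map protocol for comparative
analyses of birds:

1. filter range polygons to native, extant, breeding/resident presence;
2. intersect the surviving polygons with a regular lon/lat grid
   (0.5 degree by default) to obtain a species x cell presence-absence
   matrix;
3. take the unweighted mean of occupied-cell centers as the range
   midpoint, classify hemisphere and climate zone (tropics bounded at
   |lat| = 23.5);
4. average monthly temperature/precipitation rasters over the
   breeding-season months of the zone (Mar-Jun in the northern temperate
   zone, Sep-Dec in the southern, all year in the tropics) and over the
   occupied cells;
5. classify a species as insular when more than 90% (strict) of its
   occupied cells fall on marine islands within the area bounds
   (1 km^2 < area < 2,000,000 km^2 by default; 2,000 km^2 as the
   small-island alternative upper bound).

Vector geometries are shapely objects (GeoJSON I/O helpers included);
rasters are plain numpy arrays aligned to the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape
from shapely.prepared import prep
from shapely.validation import make_valid

from .errors import GeoError

__all__ = [
    "RangePolygon", "Grid", "PresenceMatrix", "IslandLayer", "ClimateStack",
    "SpeciesGeoSummary", "filter_ranges", "rasterize_presence",
    "range_midpoint", "climate_months", "species_climate",
    "classify_insularity", "summarize_geography",
    "read_ranges_geojson", "write_ranges_geojson",
]

TROPIC_LAT = 23.5
INSULARITY_SHARE = 0.9
ISLAND_MIN_KM2 = 1.0
ISLAND_MAX_KM2 = 2_000_000.0
ISLAND_MAX_KM2_SMALL = 2_000.0


@dataclass
class RangePolygon:
    """One range polygon with its BirdLife-style attribute codes.

    seasonal: 1 resident, 2 breeding season, 3 non-breeding, 4 passage;
    origin: 1 native, 2 reintroduced, 3 introduced; presence: 1 extant.
    """

    species_id: str
    geometry: object
    seasonal: int = 1
    origin: int = 1
    presence: int = 1

    def repaired(self) -> "RangePolygon":
        geom = self.geometry
        if not geom.is_valid:
            geom = make_valid(geom)
        return RangePolygon(self.species_id, geom, self.seasonal, self.origin, self.presence)


@dataclass(frozen=True)
class Grid:
    """Regular lon/lat grid of half-open cells [west, east) x [south, north)."""

    resolution: float = 0.5
    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -90.0
    lat_max: float = 90.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GeoError("grid resolution must be positive")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.resolution * (np.arange(self.n_lat) + 0.5)

    def cell_box(self, i_lat: int, i_lon: int):
        w = self.lon_min + i_lon * self.resolution
        s = self.lat_min + i_lat * self.resolution
        return box(w, s, w + self.resolution, s + self.resolution)

    def cells_intersecting(self, geom, min_cover: float = 0.0) -> set[tuple[int, int]]:
        """Cells whose intersection with ``geom`` has positive area
        (or covers at least ``min_cover`` of the cell)."""
        out: set[tuple[int, int]] = set()
        minx, miny, maxx, maxy = geom.bounds
        i0 = max(0, int(np.floor((miny - self.lat_min) / self.resolution)))
        i1 = min(self.n_lat - 1, int(np.floor((maxy - self.lat_min) / self.resolution)))
        j0 = max(0, int(np.floor((minx - self.lon_min) / self.resolution)))
        j1 = min(self.n_lon - 1, int(np.floor((maxx - self.lon_min) / self.resolution)))
        prepared = prep(geom)
        cell_area = self.resolution ** 2
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                cell = self.cell_box(i, j)
                if not prepared.intersects(cell):
                    continue
                inter = geom.intersection(cell).area
                if inter > 0 and inter >= min_cover * cell_area:
                    out.add((i, j))
        return out


@dataclass
class PresenceMatrix:
    """Binary species x cell occupancy on a grid."""

    grid: Grid
    cells: dict[str, set[tuple[int, int]]]
    #: species whose filtered range produced no occupied cells
    empty_species: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return sorted(self.cells)

    def occupied(self, species_id: str) -> set[tuple[int, int]]:
        return self.cells.get(species_id, set())

    def to_triplets(self) -> pd.DataFrame:
        rows = [
            {"species_id": sp, "lat_index": i, "lon_index": j}
            for sp, cc in sorted(self.cells.items())
            for i, j in sorted(cc)
        ]
        return pd.DataFrame(rows, columns=["species_id", "lat_index", "lon_index"])

    def write_triplets(self, path) -> None:
        self.to_triplets().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_triplets(cls, path, grid: Grid) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t")
        cells: dict[str, set[tuple[int, int]]] = {}
        for sp, g in df.groupby("species_id"):
            cells[str(sp)] = set(zip(g["lat_index"].astype(int), g["lon_index"].astype(int)))
        return cls(grid=grid, cells=cells)


@dataclass
class IslandLayer:
    """Marine island polygons with their areas (km^2)."""

    polygons: list
    areas_km2: list[float]

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.areas_km2):
            raise GeoError("island polygons and areas differ in length")
        for a in self.areas_km2:
            if a is None or not np.isfinite(a):
                raise GeoError("island polygon missing area attribute")

    def within_bounds(self, upper_km2: float, lower_km2: float = ISLAND_MIN_KM2) -> "IslandLayer":
        keep = [(p, a) for p, a in zip(self.polygons, self.areas_km2)
                if lower_km2 < a < upper_km2]
        return IslandLayer([p for p, _ in keep], [a for _, a in keep])


@dataclass
class ClimateStack:
    """Monthly climate rasters aligned to a grid: arrays (12, n_lat, n_lon)."""

    grid: Grid
    temperature: np.ndarray
    precipitation: np.ndarray

    def __post_init__(self) -> None:
        expect = (12, self.grid.n_lat, self.grid.n_lon)
        for name, arr in [("temperature", self.temperature), ("precipitation", self.precipitation)]:
            if arr.shape != expect:
                raise GeoError(f"{name} raster shape {arr.shape} != {expect}")


@dataclass
class SpeciesGeoSummary:
    """Per-species geographic and climatic covariates for the models."""

    species_id: str
    midpoint_lat: float
    midpoint_lon: float
    hemisphere: Literal["north", "south"]
    climate_zone: Literal["north_temperate", "south_temperate", "tropical"]
    mean_temperature: float
    mean_precipitation: float
    insular_large_threshold: bool
    insular_small_threshold: bool
    insular_proportion: float
    n_cells: int


# ---------------------------------------------------------------------------
# operations

def filter_ranges(ranges: Iterable[RangePolygon]) -> tuple[list[RangePolygon], list[str]]:
    """Keep native (origin 1-2), extant (presence 1), breeding-or-resident
    (seasonal 1-2) polygons.  Returns (kept, species that lost all polygons)."""
    ranges = list(ranges)
    kept = [r.repaired() for r in ranges
            if r.seasonal in (1, 2) and r.origin in (1, 2) and r.presence == 1]
    all_sp = {r.species_id for r in ranges}
    kept_sp = {r.species_id for r in kept}
    return kept, sorted(all_sp - kept_sp)


def rasterize_presence(
    ranges: Iterable[RangePolygon], grid: Grid, min_cover: float = 0.0
) -> PresenceMatrix:
    """Species x cell occupancy: a cell counts as occupied when any retained
    polygon intersects it with positive area (any-overlap rule; raise
    ``min_cover`` for sensitivity checks)."""
    cells: dict[str, set[tuple[int, int]]] = {}
    for r in ranges:
        cc = grid.cells_intersecting(r.geometry, min_cover=min_cover)
        cells.setdefault(r.species_id, set()).update(cc)
    empty = sorted([sp for sp, cc in cells.items() if not cc])
    return PresenceMatrix(grid=grid, cells=cells, empty_species=empty)


def range_midpoint(
    cells: set[tuple[int, int]], grid: Grid
) -> tuple[float, float, str, str]:
    """Unweighted mean of occupied-cell centers; hemisphere (equator ties
    go north) and climate zone (tropics within |lat| <= 23.5)."""
    if not cells:
        raise GeoError("no occupied cells")
    lats = grid.lat_centers
    lons = grid.lon_centers
    lat = float(np.mean([lats[i] for i, _ in cells]))
    lon = float(np.mean([lons[j] for _, j in cells]))
    hemisphere = "north" if lat >= 0 else "south"
    if lat > TROPIC_LAT:
        zone = "north_temperate"
    elif lat < -TROPIC_LAT:
        zone = "south_temperate"
    else:
        zone = "tropical"
    return lat, lon, hemisphere, zone


def climate_months(zone: str) -> list[int]:
    """Breeding-season month window per climate zone (1-based months)."""
    if zone == "north_temperate":
        return [3, 4, 5, 6]
    if zone == "south_temperate":
        return [9, 10, 11, 12]
    if zone == "tropical":
        return list(range(1, 13))
    raise GeoError(f"unknown climate zone {zone!r}")


def species_climate(
    cells: set[tuple[int, int]], climate: ClimateStack, months: Sequence[int]
) -> tuple[float, float]:
    """Mean of the month-window average per occupied cell, then the
    unweighted mean over cells; NaN cells are excluded from the cell
    average.  Returns (temperature, precipitation), NaN when no cell has
    data."""
    if not cells:
        raise GeoError("no occupied cells")
    m_idx = [m - 1 for m in months]
    out = []
    for arr in (climate.temperature, climate.precipitation):
        vals = []
        for i, j in cells:
            sl = arr[m_idx, i, j]
            finite = sl[np.isfinite(sl)]
            if finite.size:
                vals.append(float(finite.mean()))
        out.append(float(np.mean(vals)) if vals else float("nan"))
    return out[0], out[1]


def classify_insularity(
    cells: set[tuple[int, int]],
    islands: IslandLayer,
    grid: Grid,
    upper_area_threshold: float = ISLAND_MAX_KM2,
) -> tuple[bool, float]:
    """Insularity flag and the insular share of the species' occupied cells.

    Islands are filtered to 1 km^2 < area < ``upper_area_threshold``; a
    cell is insular when the filtered island layer covers any positive
    fraction of it; the species is insular when the insular share strictly
    exceeds 90%.
    """
    if not cells:
        raise GeoError("no occupied cells")
    selected = islands.within_bounds(upper_area_threshold)
    insular_cells: set[tuple[int, int]] = set()
    for poly in selected.polygons:
        insular_cells |= grid.cells_intersecting(poly)
    share = len(cells & insular_cells) / len(cells)
    return share > INSULARITY_SHARE, share


def summarize_geography(
    ranges: Iterable[RangePolygon],
    islands: IslandLayer,
    climate: ClimateStack,
    grid: Grid | None = None,
    min_cover: float = 0.0,
) -> tuple[pd.DataFrame, PresenceMatrix]:
    """Run the full per-species pipeline; returns a tidy summary table and
    the presence matrix (species with empty filtered ranges are dropped
    from the table)."""
    if grid is None:
        grid = climate.grid
    kept, dropped = filter_ranges(ranges)
    pam = rasterize_presence(kept, grid, min_cover=min_cover)
    pam.empty_species = sorted(set(pam.empty_species) | set(dropped))
    rows = []
    for sp in pam.species:
        cc = pam.occupied(sp)
        if not cc:
            continue
        lat, lon, hemi, zone = range_midpoint(cc, grid)
        months = climate_months(zone)
        temp, precip = species_climate(cc, climate, months)
        ins_large, share = classify_insularity(cc, islands, grid, ISLAND_MAX_KM2)
        ins_small, _ = classify_insularity(cc, islands, grid, ISLAND_MAX_KM2_SMALL)
        rows.append(SpeciesGeoSummary(
            species_id=sp, midpoint_lat=lat, midpoint_lon=lon, hemisphere=hemi,
            climate_zone=zone, mean_temperature=temp, mean_precipitation=precip,
            insular_large_threshold=ins_large, insular_small_threshold=ins_small,
            insular_proportion=share, n_cells=len(cc),
        ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df, pam


# ---------------------------------------------------------------------------
# antimeridian handling and GeoJSON I/O

def split_antimeridian(geom):
    """Split a polygon whose longitudes run past 180 into the two wrapped
    pieces on [-180, 180]."""
    minx, _, maxx, _ = geom.bounds
    if maxx <= 180.0 and minx >= -180.0:
        return geom
    from shapely.ops import unary_union
    from shapely.affinity import translate

    east = geom.intersection(box(-180.0, -90.0, 180.0, 90.0))
    beyond = geom.intersection(box(180.0, -90.0, 540.0, 90.0))
    pieces = [east]
    if not beyond.is_empty:
        pieces.append(translate(beyond, xoff=-360.0))
    west_beyond = geom.intersection(box(-540.0, -90.0, -180.0, 90.0))
    if not west_beyond.is_empty:
        pieces.append(translate(west_beyond, xoff=360.0))
    return unary_union([p for p in pieces if not p.is_empty])


def read_ranges_geojson(path) -> list[RangePolygon]:
    """Read range polygons from a GeoJSON FeatureCollection with
    ``species_id``/``seasonal``/``origin``/``presence`` properties."""
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj["features"]:
        props = feat.get("properties", {})
        out.append(RangePolygon(
            species_id=str(props["species_id"]),
            geometry=shape(feat["geometry"]),
            seasonal=int(props.get("seasonal", 1)),
            origin=int(props.get("origin", 1)),
            presence=int(props.get("presence", 1)),
        ))
    return out


def write_ranges_geojson(ranges: Sequence[RangePolygon], path) -> None:
    feats = [{
        "type": "Feature",
        "geometry": mapping(r.geometry),
        "properties": {"species_id": r.species_id, "seasonal": r.seasonal,
                       "origin": r.origin, "presence": r.presence},
    } for r in ranges]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
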