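"""0.5-degree density composites, biomass conversion and regional series.

Per-scene fractional-coverage rasters are averaged onto a 0.5x0.5-degree
grid per calendar month or year: each cell's value is the arithmetic
mean fractional coverage over every valid 1-km pixel falling in the cell
across all scenes of the period (non-detected valid pixels count as 0;
pixels lost to the land/cloud masks are excluded from numerator and
denominator).  Cell fractional coverage times spherical cell area times
the 3.34 kg m^-2 wet-biomass factor gives regional biomass in metric
tons, which is organised on an ecological-year (March-February) axis.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, shape
from shapely.prepared import prep

from .constants import EARTH_RADIUS_M, WET_BIOMASS_KG_PER_M2
from .scene import GeoTransform

CELL_DEG = 0.5

SEASONS = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
    12: "winter", 1: "winter", 2: "winter",
}


@dataclass
class FractionRaster:
    """One scene's fractional-coverage raster (NaN = not observed)."""

    fraction: np.ndarray
    geotransform: GeoTransform
    date: _dt.date


@dataclass
class DensityComposite:
    """Mean fractional coverage on the 0.5-degree grid for one period.

    Cells are half-open [lon, lon+0.5) x [lat, lat+0.5) anchored at
    half-integer degrees; ``lon_edges``/``lat_edges`` give the west/south
    edges.  ``count`` is the number of valid pixel observations per
    cell; a count of 0 means the cell was never observed (mean NaN).
    """

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    mean: np.ndarray  # (lat, lon)
    count: np.ndarray
    period: str  # "YYYY-MM" or "YYYY"


@dataclass
class RegionSpec:
    """Named analysis region with a polygon geometry (lon/lat degrees)."""

    name: str
    geometry: Polygon

    @classmethod
    def from_mapping(cls, obj: dict) -> "RegionSpec":
        geom = obj.get("geometry")
        if geom is not None:
            return cls(name=obj["name"], geometry=shape(geom))
        lon0, lat0, lon1, lat1 = obj["bbox"]
        return cls(name=obj["name"], geometry=Polygon(
            [(lon0, lat0), (lon1, lat0), (lon1, lat1), (lon0, lat1)]))


@dataclass
class BiomassSeries:
    """Monthly regional wet-biomass series in metric tons."""

    region: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: year, month, biomass_t, ecological_year, season


def ecological_year(date: _dt.date) -> int:
    """Ecological (March-February) year of a date.

    The annual cycle starts with the March bloom onset, so January and
    February belong to the previous year's cycle.
    """
    return date.year - 1 if date.month in (1, 2) else date.year


def season(date: _dt.date) -> str:
    """Season label: spring MAM, summer JJA, fall SON, winter DJF."""
    return SEASONS[date.month]


def _cell_index(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (np.floor(lon / CELL_DEG).astype(np.int64),
            np.floor(lat / CELL_DEG).astype(np.int64))


def cell_area_m2(lat_south_deg: np.ndarray) -> np.ndarray:
    """Spherical area of a 0.5-degree cell whose south edge is at lat."""
    lat0 = np.radians(np.asarray(lat_south_deg, dtype=np.float64))
    lat1 = np.radians(np.asarray(lat_south_deg, dtype=np.float64) + CELL_DEG)
    dlam = np.radians(CELL_DEG)
    return EARTH_RADIUS_M**2 * dlam * (np.sin(lat1) - np.sin(lat0))


def composite_period(rasters: list[FractionRaster], period: str = "month") -> list[DensityComposite]:
    """Average fraction rasters into 0.5-degree composites per period.

    ``period`` is ``"month"`` (calendar month) or ``"year"`` (calendar
    year).  Returns one composite per period present in the input.
    """
    if not rasters:
        raise ValueError("composite_period: no input rasters")
    if period not in ("month", "year"):
        raise ValueError(f"unknown period {period!r}")

    def key(d: _dt.date) -> str:
        return f"{d.year:04d}-{d.month:02d}" if period == "month" else f"{d.year:04d}"

    groups: dict[str, list[FractionRaster]] = {}
    for ras in rasters:
        groups.setdefault(key(ras.date), []).append(ras)

    out = []
    for pkey in sorted(groups):
        sums: dict[tuple[int, int], float] = {}
        counts: dict[tuple[int, int], int] = {}
        for ras in groups[pkey]:
            n_rows, n_cols = ras.fraction.shape
            lat, lon = ras.geotransform.pixel_centers(n_rows, n_cols)
            lon2d, lat2d = np.meshgrid(lon, lat)
            obs = np.isfinite(ras.fraction)
            ci, cj = _cell_index(lon2d[obs], lat2d[obs])
            vals = ras.fraction[obs]
            df = pd.DataFrame({"ci": ci, "cj": cj, "v": vals})
            agg = df.groupby(["ci", "cj"])["v"].agg(["sum", "count"])
            for (a, b), row in agg.iterrows():
                sums[(a, b)] = sums.get((a, b), 0.0) + row["sum"]
                counts[(a, b)] = counts.get((a, b), 0) + int(row["count"])
        # contiguous bounding grid: interior never-observed cells stay
        # explicit missing records rather than silently vanishing
        cis = list(range(min(k[0] for k in counts), max(k[0] for k in counts) + 1))
        cjs = list(range(min(k[1] for k in counts), max(k[1] for k in counts) + 1))
        lon_edges = np.array(cis, dtype=np.float64) * CELL_DEG
        lat_edges = np.array(cjs, dtype=np.float64) * CELL_DEG
        mean = np.full((len(cjs), len(cis)), np.nan)
        count = np.zeros((len(cjs), len(cis)), dtype=np.int64)
        ci_pos = {c: i for i, c in enumerate(cis)}
        cj_pos = {c: j for j, c in enumerate(cjs)}
        for (a, b), n in counts.items():
            i, j = ci_pos[a], cj_pos[b]
            count[j, i] = n
            mean[j, i] = sums[(a, b)] / n
        out.append(DensityComposite(lon_edges=lon_edges, lat_edges=lat_edges,
                                    mean=mean, count=count, period=pkey))
    return out


def to_biomass(comp: DensityComposite, region: RegionSpec) -> float:
    """Wet biomass in metric tons within a region for one composite.

    Cell membership is by cell centre; missing (never-observed) cells
    contribute 0.  Biomass = sum over member cells of mean fraction x
    spherical cell area x 3.34 kg m^-2, reported in metric tons.
    """
    lon_c = comp.lon_edges + CELL_DEG / 2
    lat_c = comp.lat_edges + CELL_DEG / 2
    prepared = prep(region.geometry)
    inside = np.array(
        [[prepared.contains(Point(x, y)) for x in lon_c] for y in lat_c], dtype=bool
    )
    if comp.mean.size == 0 or not inside.any():
        raise ValueError(f"region {region.name!r} does not intersect the composite grid")
    area = cell_area_m2(comp.lat_edges)[:, None]  # (lat, 1)
    frac = np.where(np.isfinite(comp.mean), comp.mean, 0.0)
    kg = float(np.sum(frac * area * WET_BIOMASS_KG_PER_M2 * inside))
    return kg / 1000.0


def regional_series(
    monthly: list[DensityComposite],
    region: RegionSpec,
    exclude_years: set[int] | None = None,
) -> BiomassSeries:
    """Monthly biomass series for a region, on the ecological-year axis.

    ``exclude_years`` removes whole calendar years (the anomalous-year
    exclusion used for maps; period statistics normally keep them).
    """
    exclude_years = exclude_years or set()
    rows = []
    for comp in monthly:
        year, month = (int(p) for p in comp.period.split("-"))
        if year in exclude_years:
            continue
        d = _dt.date(year, month, 15)
        rows.append({
            "year": year,
            "month": month,
            "biomass_t": to_biomass(comp, region),
            "ecological_year": ecological_year(d),
            "season": season(d),
        })
    table = pd.DataFrame(rows, columns=["year", "month", "biomass_t",
                                        "ecological_year", "season"])
    return BiomassSeries(region=region.name, table=table)


def annual_means(series: BiomassSeries) -> pd.DataFrame:
    """Mean monthly biomass per ecological year."""
    return (series.table.groupby("ecological_year")["biomass_t"]
            .mean().rename("biomass_t").reset_index())


def composite_to_dataset(comp: DensityComposite):
    """DensityComposite as an xarray Dataset (`fraction_mean`, `n_obs`)."""
    import xarray as xr

    return xr.Dataset(
        {
            "fraction_mean": (("lat", "lon"), comp.mean),
            "n_obs": (("lat", "lon"), comp.count.astype(np.int32)),
        },
        coords={"lat": comp.lat_edges + CELL_DEG / 2,
                "lon": comp.lon_edges + CELL_DEG / 2},
        attrs={"period": comp.period, "cell_deg": CELL_DEG},
    )


def days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1]
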