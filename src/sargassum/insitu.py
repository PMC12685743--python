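"""Neuston-tow parsing and weighted Sargassum density summaries.

A neuston tow samples the sea surface with a 1.0 m x 0.5 m frame net
towed at ~2 knots for ~30 minutes (~1 nautical mile), yielding wet mass
per morphotype over a swept area of tow distance x 1.0 m mouth width.

The density statistic is the *weighted arithmetic mean*: total mass
divided by total swept area over all tows in a group (a ratio of sums,
not a mean of per-tow ratios), scaled to kg km^-2.  This weights each
tow by its swept area and is invariant to how the effort is split into
individual tows.  Groups are region x ecological year (or period) x
season pair (spring/summer vs fall/winter); groups with no tows are
reported as explicit no-data records, never as zero density.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composite import RegionSpec, ecological_year, season
from .constants import EARTH_RADIUS_M, MORPHOTYPES

SEASON_GROUPS = {
    "spring": "spring/summer",
    "summer": "spring/summer",
    "fall": "fall/winter",
    "winter": "fall/winter",
}

TOW_CSV_COLUMNS = [
    "tow_id", "datetime_utc", "lat_start", "lon_start", "lat_end", "lon_end",
    "distance_m", "net_width_m", "mass_Sn_n_g", "mass_Sf_g", "mass_Sn_w_g",
]


@dataclass
class NeustonTow:
    """One net tow: when, where, swept geometry and wet mass caught.

    ``masses_g`` maps morphotype code to wet mass in grams.  If
    ``distance_m`` is None it is derived from the start/end GPS fix via
    the great-circle (haversine) distance on a 6371-km sphere.
    """

    tow_id: str
    datetime_utc: _dt.datetime
    lat_start: float
    lon_start: float
    lat_end: float
    lon_end: float
    masses_g: dict[str, float] = field(default_factory=dict)
    distance_m: float | None = None
    net_width_m: float = 1.0

    def __post_init__(self) -> None:
        if self.net_width_m <= 0:
            raise ValueError(f"tow {self.tow_id}: net width must be positive")
        for k, v in self.masses_g.items():
            if v < 0:
                raise ValueError(f"tow {self.tow_id}: negative mass for {k}")
        if self.distance_m is None:
            self.distance_m = haversine_m(
                self.lat_start, self.lon_start, self.lat_end, self.lon_end
            )

    @property
    def total_mass_g(self) -> float:
        return float(sum(self.masses_g.values()))

    def midpoint(self) -> tuple[float, float]:
        """(lon, lat) midpoint used for region assignment."""
        return ((self.lon_start + self.lon_end) / 2,
                (self.lat_start + self.lat_end) / 2)


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres on the mean sphere."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def track_distance_m(track: list[tuple[float, float]]) -> float:
    """Sum of consecutive great-circle legs of a (lat, lon) track."""
    return sum(haversine_m(*track[i], *track[i + 1]) for i in range(len(track) - 1))


def tow_area_m2(tow: NeustonTow) -> float:
    """Swept area: tow distance times the 1.0-m net mouth width."""
    if tow.distance_m is None or tow.distance_m <= 0:
        raise ValueError(f"tow {tow.tow_id}: non-positive tow distance")
    return tow.distance_m * tow.net_width_m


def weighted_density(tows: list[NeustonTow], morphotype: str | None = None) -> float:
    """Weighted arithmetic mean density in kg km^-2.

    Sum of mass (kg) over sum of swept area (m^2), times 1e6.  With a
    ``morphotype`` only that morphotype's mass enters the numerator; the
    denominator is always the full group's swept area.
    """
    if not tows:
        raise ValueError("weighted_density: empty tow list")
    mass_g = sum(
        t.total_mass_g if morphotype is None else t.masses_g.get(morphotype, 0.0)
        for t in tows
    )
    area = sum(tow_area_m2(t) for t in tows)
    return (mass_g / 1000.0) / area * 1e6


def assign_region(tow: NeustonTow, regions: list[RegionSpec]) -> str:
    """Name of the first region containing the tow midpoint, else 'unclassified'."""
    from shapely.geometry import Point

    pt = Point(*tow.midpoint())
    for reg in regions:
        if reg.geometry.contains(pt):
            return reg.name
    return "unclassified"


def summarize(
    tows: list[NeustonTow],
    regions: list[RegionSpec],
    grouping: str = "ecological_year",
    periods: dict[str, range] | None = None,
    season_split: bool = True,
) -> pd.DataFrame:
    """Weighted densities and morphotype proportions per group.

    ``grouping`` is ``"ecological_year"`` or ``"period"``; with
    ``"period"``, ``periods`` maps period labels to ranges of ecological
    years.  With ``season_split`` groups are additionally split into
    spring/summer vs fall/winter.  Every region x group x season-pair
    combination spanned by the data is reported; combinations with zero
    tows appear as no-data records (``n_tows`` 0, densities NaN).
    """
    if grouping not in ("ecological_year", "period"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if grouping == "period" and not periods:
        raise ValueError("grouping='period' requires a periods mapping")

    def group_label(t: NeustonTow) -> str | None:
        ey = ecological_year(t.datetime_utc.date())
        if grouping == "ecological_year":
            return str(ey)
        for label, years in periods.items():
            if ey in years:
                return label
        return None

    buckets: dict[tuple[str, str, str], list[NeustonTow]] = {}
    labels, region_names = set(), set()
    for tow in tows:
        label = group_label(tow)
        if label is None:
            continue
        reg = assign_region(tow, regions)
        sg = SEASON_GROUPS[season(tow.datetime_utc.date())] if season_split else "all"
        buckets.setdefault((reg, label, sg), []).append(tow)
        labels.add(label)
        region_names.add(reg)

    season_groups = ("spring/summer", "fall/winter") if season_split else ("all",)
    rows = []
    for reg in sorted(region_names):
        for label in sorted(labels):
            for sg in season_groups:
                group = buckets.get((reg, label, sg), [])
                row = {"region": reg, "group": label, "season_group": sg,
                       "n_tows": len(group)}
                if not group:
                    for m in MORPHOTYPES:
                        row[f"density_{m}"] = np.nan
                        row[f"prop_{m}"] = np.nan
                    row["density_total"] = np.nan
                else:
                    total = weighted_density(group)
                    row["density_total"] = total
                    total_mass = sum(t.total_mass_g for t in group)
                    for m in MORPHOTYPES:
                        row[f"density_{m}"] = weighted_density(group, morphotype=m)
                        mass_m = sum(t.masses_g.get(m, 0.0) for t in group)
                        row[f"prop_{m}"] = mass_m / total_mass if total_mass > 0 else np.nan
                rows.append(row)
    cols = (["region", "group", "season_group", "n_tows", "density_total"]
            + [f"density_{m}" for m in MORPHOTYPES]
            + [f"prop_{m}" for m in MORPHOTYPES])
    return pd.DataFrame(rows, columns=cols)


# -------------------------------------------------------------------- I/O

def tows_to_csv(tows: list[NeustonTow], path) -> None:
    rows = []
    for t in tows:
        rows.append({
            "tow_id": t.tow_id,
            "datetime_utc": t.datetime_utc.isoformat(),
            "lat_start": t.lat_start, "lon_start": t.lon_start,
            "lat_end": t.lat_end, "lon_end": t.lon_end,
            "distance_m": t.distance_m, "net_width_m": t.net_width_m,
            "mass_Sn_n_g": t.masses_g.get("Sn_n", 0.0),
            "mass_Sf_g": t.masses_g.get("Sf", 0.0),
            "mass_Sn_w_g": t.masses_g.get("Sn_w", 0.0),
        })
    pd.DataFrame(rows, columns=TOW_CSV_COLUMNS).to_csv(path, index=False)


def tows_from_csv(path) -> list[NeustonTow]:
    df = pd.read_csv(path)
    tows = []
    for _, r in df.iterrows():
        tows.append(NeustonTow(
            tow_id=str(r["tow_id"]),
            datetime_utc=_dt.datetime.fromisoformat(str(r["datetime_utc"])),
            lat_start=float(r["lat_start"]), lon_start=float(r["lon_start"]),
            lat_end=float(r["lat_end"]), lon_end=float(r["lon_end"]),
            distance_m=float(r["distance_m"]) if np.isfinite(r["distance_m"]) else None,
            net_width_m=float(r["net_width_m"]),
            masses_g={"Sn_n": float(r["mass_Sn_n_g"]),
                      "Sf": float(r["mass_Sf_g"]),
                      "Sn_w": float(r["mass_Sn_w_g"])},
        ))
    return tows
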