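"""Synthetic Rrc scenes with known truth and synthetic neuston tow logs.

The scene generator is the *forward model* inverted by the
quantification pipeline: it lays down a flat per-band background
reflectance and, for each injected raft pixel with sub-pixel coverage
``f``, raises only the 748-nm band by ``f * 4.41e-2``.  Because AFAI is
linear in Rrc(748) with unit slope, the noiseless AFAI excess over the
background equals ``f * 4.41e-2`` exactly, so the linear unmixing
recovers ``f`` bit-for-bit — every downstream stage can be tested
against known ground truth without any satellite download.  The single
band injection is a testability device, not a radiative-transfer claim:
real sub-pixel mixing perturbs several bands.

The tow generator emulates the spatial patchiness of Sargassum rafts
with a log-normal per-tow mass whose mean is the regional density times
the swept area; an optional encounter probability adds zero inflation.
Both generators are bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AFAI_FULL_COVERAGE,
    KNOT_M_PER_H,
    METERS_PER_DEGREE,
    MORPHOTYPES,
    RRC_BANDS,
    WET_BIOMASS_KG_PER_M2,
)
from .insitu import NeustonTow
from .scene import GeoTransform, RrcScene

#: Flat clear-water background Rrc used when the config gives none;
#: a gentle red-to-NIR decrease typical of open-ocean Rayleigh-corrected
#: reflectance.
DEFAULT_BACKGROUND = {
    412: 0.028, 443: 0.025, 488: 0.020, 547: 0.015,
    667: 0.010, 678: 0.010, 748: 0.009, 869: 0.008,
}

SEASON_MONTHS = {
    "spring": (3, 4, 5), "summer": (6, 7, 8),
    "fall": (9, 10, 11), "winter": (12, 1, 2),
}


@dataclass
class PatchSpec:
    """One injected raft: top-left anchor, boolean footprint, coverage.

    ``footprint`` may be an int (side of a filled square) or a 2-D
    boolean array; ``fraction`` is the per-pixel sub-pixel coverage.
    """

    row: int
    col: int
    footprint: int | np.ndarray = 3
    fraction: float = 0.5

    def mask(self) -> np.ndarray:
        if isinstance(self.footprint, (int, np.integer)):
            return np.ones((self.footprint, self.footprint), dtype=bool)
        return np.asarray(self.footprint, dtype=bool)


@dataclass
class LandSpec:
    """A land strip along one border of the grid ('none' disables it)."""

    side: str = "none"  # none|west|east|north|south
    width_px: int = 0


@dataclass
class CloudSpec:
    """Random filled-disc cloud blobs."""

    n_blobs: int = 0
    radius_px: float = 3.0


#: Native pixel size of the simulated "1-km" cylindrical-equidistant
#: product.  Real plate-carree products are defined on an angular grid;
#: 1/112 degree (~992.8 m on the mean sphere) keeps the nominal 1-km
#: resolution while letting a 0.5-degree composite cell hold exactly
#: 56 x 56 pixels, as a degree-defined grid does.
DEFAULT_PIXEL_SIZE_M = METERS_PER_DEGREE / 112.0


@dataclass
class SceneConfig:
    grid_rows: int = 256
    grid_cols: int = 256
    pixel_size_m: float = DEFAULT_PIXEL_SIZE_M
    # defaults sit on the 0.5-degree composite-grid lines near the equator,
    # where plate-carree pixel area matches spherical cell area closely
    origin_lon: float = -60.0
    origin_lat: float = 1.0
    background_rrc: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    band_noise_sd: float | dict[int, float] = 0.0
    land_spec: LandSpec = field(default_factory=LandSpec)
    cloud_spec: CloudSpec = field(default_factory=CloudSpec)
    patch_spec: list[PatchSpec] = field(default_factory=list)
    date: _dt.date = field(default_factory=lambda: _dt.date(2000, 3, 15))
    #: keep random cloud blobs from landing within this many pixels of a
    #: patch so injected truth stays quantifiable (0 disables).
    cloud_keepout_px: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        for w, v in self.background_rrc.items():
            if not (0.0 < v < 1.0):
                raise ValueError(f"background Rrc({w}) must be in (0, 1), got {v}")
        for i, p in enumerate(self.patch_spec):
            if not (0.0 <= p.fraction <= 1.0):
                raise ValueError(f"patch {i}: fraction {p.fraction} outside [0, 1]")

    def noise_sd(self, band: int) -> float:
        if isinstance(self.band_noise_sd, dict):
            return float(self.band_noise_sd.get(band, 0.0))
        return float(self.band_noise_sd)


@dataclass
class TruthMap:
    """Per-pixel injected coverage and the implied total wet biomass."""

    fraction: np.ndarray
    pixel_size_m: float

    @property
    def total_truth_biomass_kg(self) -> float:
        """Sum of fraction x pixel area x 3.34 kg m^-2."""
        area = self.pixel_size_m**2
        return float(np.sum(self.fraction) * area * WET_BIOMASS_KG_PER_M2)


def _land_mask(cfg: SceneConfig) -> np.ndarray:
    land = np.zeros((cfg.grid_rows, cfg.grid_cols), dtype=bool)
    w = cfg.land_spec.width_px
    if cfg.land_spec.side == "none" or w <= 0:
        return land
    if cfg.land_spec.side == "west":
        land[:, :w] = True
    elif cfg.land_spec.side == "east":
        land[:, -w:] = True
    elif cfg.land_spec.side == "north":
        land[:w, :] = True
    elif cfg.land_spec.side == "south":
        land[-w:, :] = True
    else:
        raise ValueError(f"unknown land side {cfg.land_spec.side!r}")
    return land


def generate_scene(cfg: SceneConfig) -> tuple[RrcScene, TruthMap]:
    """Render a synthetic Rrc scene and its ground-truth coverage map.

    Raises ``ValueError`` naming the patch index if a patch falls on
    land or outside the grid.  The same seed reproduces the scene
    bit-for-bit.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.grid_rows, cfg.grid_cols)
    land = _land_mask(cfg)

    truth = np.zeros(shape, dtype=np.float64)
    for i, p in enumerate(cfg.patch_spec):
        m = p.mask()
        r1, c1 = p.row + m.shape[0], p.col + m.shape[1]
        if p.row < 0 or p.col < 0 or r1 > cfg.grid_rows or c1 > cfg.grid_cols:
            raise ValueError(f"patch {i} extends outside the grid")
        if land[p.row:r1, p.col:c1][m].any():
            raise ValueError(f"patch {i} is placed on land")
        truth[p.row:r1, p.col:c1][m] = p.fraction

    cloud = np.zeros(shape, dtype=bool)
    if cfg.cloud_spec.n_blobs > 0:
        rr, cc = np.mgrid[0:cfg.grid_rows, 0:cfg.grid_cols]
        placed = 0
        attempts = 0
        while placed < cfg.cloud_spec.n_blobs and attempts < 100 * cfg.cloud_spec.n_blobs:
            attempts += 1
            r0 = rng.uniform(0, cfg.grid_rows)
            c0 = rng.uniform(0, cfg.grid_cols)
            rad = cfg.cloud_spec.radius_px
            if cfg.cloud_keepout_px and truth.any():
                pr, pc = np.nonzero(truth)
                d2 = (pr - r0) ** 2 + (pc - c0) ** 2
                if d2.min() < (rad + cfg.cloud_keepout_px) ** 2:
                    continue
            cloud |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            placed += 1
    cloud &= ~land

    bands: dict[int, np.ndarray] = {}
    for w in RRC_BANDS:
        base = cfg.background_rrc.get(w, DEFAULT_BACKGROUND[w])
        grid = np.full(shape, base, dtype=np.float64)
        if w == 748:
            grid += truth * AFAI_FULL_COVERAGE
        sd = cfg.noise_sd(w)
        if sd > 0:
            grid = np.maximum(grid + rng.normal(0.0, sd, size=shape), 0.0)
        bands[w] = grid

    gt = GeoTransform(origin_lon=cfg.origin_lon, origin_lat=cfg.origin_lat,
                      pixel_size_m=cfg.pixel_size_m)
    scene = RrcScene(bands=bands, land=land, cloud=cloud, geotransform=gt,
                     date=cfg.date)
    return scene, TruthMap(fraction=truth, pixel_size_m=cfg.pixel_size_m)


# ---------------------------------------------------------------- tow logs


@dataclass
class TowRegion:
    """A simulated sampling region: name, lon/lat bbox and mean densities.

    ``density_kg_km2`` maps season name to the regional mean Sargassum
    density the tows should recover.
    """

    name: str
    bbox: tuple[float, float, float, float]  # lon0, lat0, lon1, lat1
    density_kg_km2: dict[str, float] = field(default_factory=dict)


@dataclass
class TowSimConfig:
    regions: list[TowRegion] = field(default_factory=list)
    morphotype_mix: tuple[float, float, float] = (0.45, 0.45, 0.10)
    patchiness_cv: float = 1.0
    n_tows: int = 20
    tow_speed_kn: float = 2.0
    tow_minutes: float = 30.0
    net_width_m: float = 1.0
    encounter_prob: float = 1.0
    duration_jitter_frac: float = 0.0
    years: tuple[int, ...] = (2022,)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.morphotype_mix) - 1.0) > 1e-12:
            raise ValueError("morphotype mix proportions must sum to 1")
        if any(p < 0 for p in self.morphotype_mix):
            raise ValueError("morphotype proportions must be non-negative")
        for reg in self.regions:
            for s, d in reg.density_kg_km2.items():
                if d < 0:
                    raise ValueError(f"region {reg.name}: negative density for {s}")
        if not (0.0 < self.encounter_prob <= 1.0):
            raise ValueError("encounter_prob must be in (0, 1]")
        if self.patchiness_cv < 0:
            raise ValueError("patchiness_cv must be non-negative")

    @property
    def nominal_distance_m(self) -> float:
        """Nominal tow distance: speed x duration (1 kn = 1852 m/h)."""
        return self.tow_speed_kn * KNOT_M_PER_H * self.tow_minutes / 60.0


def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and CV."""
    if mean <= 0:
        return np.zeros(size)
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_tow_log(cfg: TowSimConfig) -> list[NeustonTow]:
    """Simulate ``n_tows`` per region-season with known mean densities.

    Each tow's distance is speed x duration (with optional duration
    jitter); its total mass is log-normal around regional density x
    swept area with CV ``patchiness_cv``, zero-inflated by the
    encounter probability, and split across morphotypes by the
    configured mix.  Seeded and reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    tows: list[NeustonTow] = []
    mix = np.asarray(cfg.morphotype_mix)
    for reg in cfg.regions:
        lon0, lat0, lon1, lat1 = reg.bbox
        for season_name, density in sorted(reg.density_kg_km2.items()):
            months = SEASON_MONTHS[season_name]
            minutes = cfg.tow_minutes * (
                1.0 + rng.uniform(-cfg.duration_jitter_frac, cfg.duration_jitter_frac,
                                  size=cfg.n_tows)
            )
            dist = cfg.tow_speed_kn * KNOT_M_PER_H * minutes / 60.0
            area_km2 = dist * cfg.net_width_m / 1e6
            mean_mass = density * area_km2  # kg
            mass = np.array([
                _lognormal_mean_cv(rng, m / cfg.encounter_prob, cfg.patchiness_cv, 1)[0]
                for m in mean_mass
            ])
            if cfg.encounter_prob < 1.0:
                mass *= rng.random(cfg.n_tows) < cfg.encounter_prob
            lats = rng.uniform(lat0, lat1, size=cfg.n_tows)
            lons = rng.uniform(lon0, lon1, size=cfg.n_tows)
            headings = rng.uniform(0, 2 * np.pi, size=cfg.n_tows)
            years = rng.choice(cfg.years, size=cfg.n_tows)
            for k in range(cfg.n_tows):
                month = months[int(rng.integers(len(months)))]
                day = int(rng.integers(1, 29))
                hour = int(rng.choice([0, 12]))
                dlat = dist[k] * np.cos(headings[k]) / METERS_PER_DEGREE
                dlon = (dist[k] * np.sin(headings[k])
                        / (METERS_PER_DEGREE * max(np.cos(np.radians(lats[k])), 1e-6)))
                masses = {m: float(mass[k] * p * 1000.0) for m, p in zip(MORPHOTYPES, mix)}
                tows.append(NeustonTow(
                    tow_id=f"{reg.name}-{season_name}-{k:04d}",
                    datetime_utc=_dt.datetime(int(years[k]), month, day, hour, 0),
                    lat_start=float(lats[k]), lon_start=float(lons[k]),
                    lat_end=float(lats[k] + dlat), lon_end=float(lons[k] + dlon),
                    distance_m=float(dist[k]),
                    net_width_m=cfg.net_width_m,
                    masses_g=masses,
                ))
    return tows
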