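"""Rayleigh-corrected reflectance (Rrc) scene container and NetCDF I/O.

A scene is a stack of per-waveband 2-D reflectance grids on a 1-km
cylindrical-equidistant (plate carree) grid, together with land and
cloud/ice flags and a simple geotransform.  Scenes are the raw input of
the quantification pipeline; they are read and written as NetCDF with
one ``rrc_<nm>`` variable per band, byte flag variables ``land`` and
``cloud`` and CF-style ``lat``/``lon`` pixel-centre coordinates.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .constants import AFAI_BANDS, METERS_PER_DEGREE


@dataclass(frozen=True)
class GeoTransform:
    """North-west corner of the grid plus square pixel size.

    ``origin_lon``/``origin_lat`` locate the outer corner of pixel
    (0, 0); rows increase southward, columns eastward.  The angular
    pixel step is ``pixel_size_m`` converted at the plate-carree scale
    (mean-sphere metres per degree), the natural reading of a 1-km
    cylindrical-equidistant product.
    """

    origin_lon: float
    origin_lat: float
    pixel_size_m: float = 1000.0

    def __post_init__(self) -> None:
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")

    @property
    def pixel_size_deg(self) -> float:
        return self.pixel_size_m / METERS_PER_DEGREE

    def pixel_centers(self, n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (lat, lon) 1-D arrays of pixel-centre coordinates."""
        step = self.pixel_size_deg
        lat = self.origin_lat - (np.arange(n_rows) + 0.5) * step
        lon = self.origin_lon + (np.arange(n_cols) + 0.5) * step
        return lat, lon


@dataclass
class RrcScene:
    """Multi-band Rrc raster with land/cloud flags.

    ``bands`` maps wavelength in nm to a 2-D float array of
    dimensionless Rayleigh-corrected reflectance.  Missing reflectance
    is NaN.  Flags are boolean grids of the same shape.
    """

    bands: dict[int, np.ndarray]
    land: np.ndarray
    cloud: np.ndarray
    geotransform: GeoTransform
    date: _dt.date = field(default_factory=lambda: _dt.date(2000, 3, 1))

    def __post_init__(self) -> None:
        missing = [w for w in AFAI_BANDS if w not in self.bands]
        if missing:
            raise ValueError(
                f"scene is missing required waveband(s): {missing} nm"
            )
        shapes = {a.shape for a in self.bands.values()}
        shapes |= {self.land.shape, self.cloud.shape}
        if len(shapes) != 1:
            raise ValueError(f"band/flag grids have mismatched shapes: {shapes}")
        self.land = np.asarray(self.land, dtype=bool)
        self.cloud = np.asarray(self.cloud, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.land.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return self.geotransform.pixel_centers(*self.shape)

    # ----------------------------------------------------------------- I/O

    def to_dataset(self, true_fraction: np.ndarray | None = None) -> xr.Dataset:
        lat, lon = self.pixel_centers()
        data = {
            f"rrc_{w}": (("lat", "lon"), np.asarray(g, dtype=np.float64))
            for w, g in sorted(self.bands.items())
        }
        data["land"] = (("lat", "lon"), self.land.astype(np.int8))
        data["cloud"] = (("lat", "lon"), self.cloud.astype(np.int8))
        if true_fraction is not None:
            data["true_fraction"] = (
                ("lat", "lon"),
                np.asarray(true_fraction, dtype=np.float64),
            )
        ds = xr.Dataset(
            data,
            coords={"lat": lat, "lon": lon},
            attrs={
                "origin_lon": self.geotransform.origin_lon,
                "origin_lat": self.geotransform.origin_lat,
                "pixel_size_m": self.geotransform.pixel_size_m,
                "date": self.date.isoformat(),
            },
        )
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        return ds

    def to_netcdf(self, path, true_fraction: np.ndarray | None = None) -> None:
        self.to_dataset(true_fraction).to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "RrcScene":
        bands = {
            int(name[4:]): ds[name].values.astype(np.float64)
            for name in ds.data_vars
            if name.startswith("rrc_")
        }
        gt = GeoTransform(
            origin_lon=float(ds.attrs["origin_lon"]),
            origin_lat=float(ds.attrs["origin_lat"]),
            pixel_size_m=float(ds.attrs["pixel_size_m"]),
        )
        return cls(
            bands=bands,
            land=ds["land"].values.astype(bool),
            cloud=ds["cloud"].values.astype(bool),
            geotransform=gt,
            date=_dt.date.fromisoformat(str(ds.attrs["date"])),
        )

    @classmethod
    def from_netcdf(cls, path) -> "RrcScene":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())
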