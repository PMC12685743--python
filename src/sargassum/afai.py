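"""Alternate Floating Algae Index (AFAI), 8-bit scalings and valid mask.

AFAI measures the reflectance excess at 748 nm above a linear baseline
interpolated between the 667 nm and 869 nm bands:

    AFAI = Rrc(748) - [Rrc(667) + (Rrc(869) - Rrc(667)) * (748-667)/(869-667)]

Floating vegetation has a strong red-edge signal at 748 nm, so AFAI is
elevated over Sargassum rafts and near zero over clear water.  The index
is invariant to a flat spectral offset and linear in Rrc(748) with unit
slope, which is what makes the downstream sub-pixel unmixing linear.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .constants import (
    AFAI_SCALE_MAX,
    AFAI_SCALE_MIN,
    CLOUD_BUFFER_KM,
    LAND_BUFFER_KM,
    RRC_LOG_MAX,
    RRC_LOG_MIN,
)
from .scene import RrcScene

# Baseline interpolation weight (748-667)/(869-667) = 81/202.
_BASELINE_W = (748.0 - 667.0) / (869.0 - 667.0)


@dataclass
class AfaiGrid:
    """AFAI values with a finite-input validity mask; invalid pixels are NaN."""

    values: np.ndarray
    valid_mask: np.ndarray


class PixelStatus(IntEnum):
    """Per-pixel provenance of the exclusion mask."""

    OK = 0
    LAND = 1
    NEAR_LAND = 2
    CLOUD = 3
    NEAR_CLOUD = 4


@dataclass
class MaskGrid:
    """Valid-pixel mask with per-pixel exclusion provenance.

    ``valid`` is True exactly where ``provenance == PixelStatus.OK``.
    """

    valid: np.ndarray
    provenance: np.ndarray


def compute_afai(scene: RrcScene) -> AfaiGrid:
    """Compute AFAI for every pixel of an Rrc scene.

    Missing (NaN) input reflectance in any of the three bands propagates
    to a NaN index value and a False entry in the validity mask.
    """
    for w in (667, 748, 869):
        if w not in scene.bands:
            raise ValueError(f"cannot compute AFAI: band {w} nm missing from scene")
    r667 = scene.bands[667]
    r748 = scene.bands[748]
    r869 = scene.bands[869]
    baseline = r667 + (r869 - r667) * _BASELINE_W
    values = r748 - baseline
    valid = np.isfinite(values)
    return AfaiGrid(values=values, valid_mask=valid)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def scale_afai_8bit(afai) -> np.ndarray:
    """Linearly quantise AFAI to bytes over [-0.001, 0.003].

    Out-of-range values are clipped; ties round half-up.
    """
    x = np.clip(np.asarray(afai, dtype=np.float64), AFAI_SCALE_MIN, AFAI_SCALE_MAX)
    span = AFAI_SCALE_MAX - AFAI_SCALE_MIN
    b = _round_half_up((x - AFAI_SCALE_MIN) / span * 255.0)
    return b.astype(np.uint8)


def unscale_afai_8bit(byte) -> np.ndarray:
    """Inverse of :func:`scale_afai_8bit` up to quantisation."""
    b = np.asarray(byte, dtype=np.float64)
    span = AFAI_SCALE_MAX - AFAI_SCALE_MIN
    return AFAI_SCALE_MIN + b * (span / 255.0)


def scale_rrc_log(rrc) -> np.ndarray:
    """Logarithmically quantise Rrc to bytes over [0.0075, 0.2]."""
    x = np.clip(np.asarray(rrc, dtype=np.float64), RRC_LOG_MIN, RRC_LOG_MAX)
    b = _round_half_up(
        255.0 * (np.log(x) - np.log(RRC_LOG_MIN)) / (np.log(RRC_LOG_MAX) - np.log(RRC_LOG_MIN))
    )
    return b.astype(np.uint8)


def build_valid_mask(
    scene: RrcScene,
    land_buffer_km: float = LAND_BUFFER_KM,
    cloud_buffer_km: float = CLOUD_BUFFER_KM,
) -> MaskGrid:
    """Mask land/cloud pixels and everything within the stated buffers.

    A pixel is excluded when it is flagged, or when its centre lies
    within ``land_buffer_km`` of a land-flagged pixel centre or within
    ``cloud_buffer_km`` of a cloud-flagged pixel centre (Euclidean
    distance on the projected grid).  The two buffers are independent
    and their exclusions are union-ed.
    """
    if land_buffer_km <= 0 or cloud_buffer_km <= 0:
        raise ValueError("buffer distances must be positive")
    px_km = scene.geotransform.pixel_size_m / 1000.0
    prov = np.full(scene.shape, PixelStatus.OK, dtype=np.uint8)

    def _near(flag: np.ndarray, buffer_km: float) -> np.ndarray:
        if not flag.any():
            return np.zeros_like(flag)
        # EDT measures centre-to-centre distance to the nearest flagged pixel.
        dist = ndimage.distance_transform_edt(~flag, sampling=px_km)
        return dist <= buffer_km

    near_cloud = _near(scene.cloud, cloud_buffer_km)
    near_land = _near(scene.land, land_buffer_km)
    # Later assignments win: land > cloud > near-land > near-cloud.
    prov[near_cloud] = PixelStatus.NEAR_CLOUD
    prov[near_land] = PixelStatus.NEAR_LAND
    prov[scene.cloud] = PixelStatus.CLOUD
    prov[scene.land] = PixelStatus.LAND
    valid = prov == PixelStatus.OK
    return MaskGrid(valid=valid, provenance=prov)


def mask_to_dataset(afai: AfaiGrid, mask: MaskGrid, scene: RrcScene):
    """Bundle AFAI and mask as an xarray Dataset (`afai`, `valid`)."""
    import xarray as xr

    lat, lon = scene.pixel_centers()
    return xr.Dataset(
        {
            "afai": (("lat", "lon"), afai.values),
            "valid": (("lat", "lon"), mask.valid.astype(np.int8)),
            "provenance": (("lat", "lon"), mask.provenance.astype(np.int8)),
        },
        coords={"lat": lat, "lon": lon},
        attrs={"date": scene.date.isoformat()},
    )
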