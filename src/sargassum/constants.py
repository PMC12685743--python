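"""Physical constants and fixed processing parameters of the pipeline."""

import math

#: AFAI excess corresponding to 100% sub-pixel fractional coverage of
#: floating Sargassum (dimensionless reflectance index units).
AFAI_FULL_COVERAGE = 4.41e-2

#: Mean areal wet-biomass conversion factor for Sargassum rafts.
WET_BIOMASS_KG_PER_M2 = 3.34

#: Mean Earth radius used for all spherical geometry.
EARTH_RADIUS_M = 6_371_000.0

#: Metres per degree of arc on the mean sphere (plate-carree scale).
METERS_PER_DEGREE = EARTH_RADIUS_M * math.pi / 180.0

#: Linear 8-bit scaling range for the AFAI product.
AFAI_SCALE_MIN = -0.001
AFAI_SCALE_MAX = 0.003

#: Logarithmic 8-bit scaling range for Rrc products.
RRC_LOG_MIN = 0.0075
RRC_LOG_MAX = 0.2

#: Exclusion buffers around flagged pixels.
LAND_BUFFER_KM = 10.0
CLOUD_BUFFER_KM = 2.0

#: Minimum retained patch size (pixels) and background dilation radius
#: (Chebyshev radius of the square structuring element, pixels).
MIN_PATCH_PIXELS = 3
DILATION_RADIUS = 13

#: Default side of the tiling used for detector background statistics.
DETECTOR_TILE = 256

#: One knot, metres per hour (1 nautical mile per hour).
KNOT_M_PER_H = 1852.0

#: MODIS wavebands carried by an Rrc scene (nm).
RRC_BANDS = (412, 443, 488, 547, 667, 678, 748, 869)

#: Bands the AFAI computation requires (nm).
AFAI_BANDS = (667, 748, 869)

#: Holopelagic Sargassum morphotype codes: S. natans var. natans,
#: S. fluitans, S. natans var. wingei.
MORPHOTYPES = ("Sn_n", "Sf", "Sn_w")
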