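"""Sargassum pixel detection, patch extraction and sub-pixel unmixing.

Detection is deliberately pluggable: the production segmentation model
used for the operational product is a learned network, but the
quantification chain downstream of the detection mask is fully
deterministic.  The default detector flags valid pixels whose AFAI
exceeds the median AFAI of the valid pixels in the enclosing 256x256
tile by more than a user threshold.  Any callable
``(afai_values, valid_mask) -> bool array`` can be slotted in instead.

Quantification follows the operational product rules: detected pixels
are grouped into 8-connected patches, patches smaller than 3 pixels are
discarded, each retained patch gets a local background level (the median
AFAI of valid non-Sargassum pixels within a 13-pixel dilation of the
patch), and each patch pixel's background-corrected index

    dAFAI = AFAI - background_median

is linearly unmixed into a sub-pixel fractional coverage

    f = clamp(dAFAI / 4.41e-2, 0, 1)

where 4.41e-2 is the AFAI excess of a fully covered pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import measure

from .afai import AfaiGrid, MaskGrid
from .constants import AFAI_FULL_COVERAGE, DETECTOR_TILE, DILATION_RADIUS, MIN_PATCH_PIXELS

logger = logging.getLogger(__name__)

Detector = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class DetectionResult:
    """Boolean Sargassum mask over valid pixels plus detector label."""

    sargassum_mask: np.ndarray
    detector_id: str


@dataclass
class SargassumPatch:
    """A connected set of detected pixels and its quantification.

    ``pixels`` is a list of (row, col).  ``delta_afai`` and ``fraction``
    are filled by :func:`compute_delta_afai` / :func:`fractional_density`
    and are empty until then.  ``no_background`` marks patches with no
    eligible background pixel; they are excluded from quantification.
    """

    pixels: list[tuple[int, int]]
    delta_afai: np.ndarray = field(default_factory=lambda: np.empty(0))
    fraction: np.ndarray = field(default_factory=lambda: np.empty(0))
    background_median: float = np.nan
    no_background: bool = False

    def __len__(self) -> int:
        return len(self.pixels)


def threshold_detector(threshold: float, tile: int = DETECTOR_TILE) -> Detector:
    """Build the default tiled-median threshold detector.

    Each ``tile``-sized subregion gets its own background statistic (the
    median AFAI of its valid pixels); a valid pixel is flagged when its
    AFAI exceeds that statistic by more than ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("detection threshold must be positive")

    def detect(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
        out = np.zeros(values.shape, dtype=bool)
        n_rows, n_cols = values.shape
        for r0 in range(0, n_rows, tile):
            for c0 in range(0, n_cols, tile):
                sl = np.s_[r0 : r0 + tile, c0 : c0 + tile]
                v = values[sl]
                ok = valid[sl] & np.isfinite(v)
                if not ok.any():
                    continue
                med = np.median(v[ok])
                out[sl] = ok & (v > med + threshold)
        return out

    return detect


def detect_pixels(
    afai: AfaiGrid,
    mask: MaskGrid,
    detector: Detector | None = None,
    threshold: float | None = None,
) -> DetectionResult:
    """Identify Sargassum-containing pixels among the valid ones.

    Either pass a ``detector`` callable or a ``threshold`` for the
    default tiled-median detector.  Detections never occur on invalid
    pixels regardless of the detector's output.
    """
    if detector is None:
        if threshold is None:
            raise ValueError("provide a detector or a threshold")
        detector = threshold_detector(threshold)
        detector_id = f"tiled_median_threshold({threshold:g})"
    else:
        detector_id = getattr(detector, "__name__", "custom")
    valid = mask.valid & afai.valid_mask
    flagged = np.asarray(detector(afai.values, valid), dtype=bool)
    return DetectionResult(sargassum_mask=flagged & valid, detector_id=detector_id)


def extract_patches(det: DetectionResult, min_pixels: int = MIN_PATCH_PIXELS) -> list[SargassumPatch]:
    """Group detections into 8-connected patches, dropping tiny ones.

    Components with fewer than ``min_pixels`` pixels are discarded (and
    counted in a log record); the operational product excludes patches
    smaller than 3 pixels as likely noise.
    """
    labels = measure.label(det.sargassum_mask, connectivity=2)
    patches: list[SargassumPatch] = []
    n_dropped = 0
    for region in measure.regionprops(labels):
        coords = [(int(r), int(c)) for r, c in region.coords]
        coords.sort()
        if len(coords) < min_pixels:
            n_dropped += 1
            continue
        patches.append(SargassumPatch(pixels=coords))
    if n_dropped:
        logger.info("extract_patches: dropped %d component(s) smaller than %d pixels",
                    n_dropped, min_pixels)
    patches.sort(key=lambda p: p.pixels[0])
    return patches


def compute_delta_afai(
    patch: SargassumPatch,
    afai: AfaiGrid,
    det: DetectionResult,
    mask: MaskGrid,
    dilation_radius: int = DILATION_RADIUS,
    per_pixel: bool = False,
) -> SargassumPatch:
    """Fill a patch's background-corrected AFAI.

    The background sample consists of pixels that are (a) inside the
    patch's dilation footprint — the patch dilated by a square
    structuring element of Chebyshev radius ``dilation_radius`` —
    (b) valid, and (c) not Sargassum-flagged anywhere in the scene.  The
    patch-level ``background_median`` is the median AFAI of that sample;
    every patch pixel's dAFAI is its AFAI minus that median.

    With ``per_pixel=True`` each pixel instead uses the median within
    its own (2r+1)-square window, the alternative reading of the
    product's background rule.

    Patches with an empty background sample are flagged ``no_background``
    and excluded from quantification.
    """
    rows, cols = zip(*patch.pixels)
    rows = np.array(rows)
    cols = np.array(cols)
    eligible = mask.valid & afai.valid_mask & ~det.sargassum_mask
    size = 2 * dilation_radius + 1

    if per_pixel:
        deltas = np.full(len(patch.pixels), np.nan)
        medians = []
        for i, (r, c) in enumerate(patch.pixels):
            r0, r1 = max(0, r - dilation_radius), r + dilation_radius + 1
            c0, c1 = max(0, c - dilation_radius), c + dilation_radius + 1
            win = eligible[r0:r1, c0:c1]
            if not win.any():
                continue
            med = np.median(afai.values[r0:r1, c0:c1][win])
            medians.append(med)
            deltas[i] = afai.values[r, c] - med
        if not medians:
            patch.no_background = True
            logger.info("compute_delta_afai: patch at %s has no background sample",
                        patch.pixels[0])
            return patch
        patch.background_median = float(np.median(medians))
        patch.delta_afai = deltas
        return patch

    patch_mask = np.zeros(afai.values.shape, dtype=bool)
    patch_mask[rows, cols] = True
    footprint = ndimage.binary_dilation(patch_mask, structure=np.ones((size, size), dtype=bool))
    sample = eligible & footprint
    if not sample.any():
        patch.no_background = True
        logger.info("compute_delta_afai: patch at %s has no background sample",
                    patch.pixels[0])
        return patch
    med = float(np.median(afai.values[sample]))
    patch.background_median = med
    patch.delta_afai = afai.values[rows, cols] - med
    return patch


def fractional_density(delta_afai) -> np.ndarray:
    """Linearly unmix dAFAI into sub-pixel fractional coverage in [0, 1]."""
    f = np.asarray(delta_afai, dtype=np.float64) / AFAI_FULL_COVERAGE
    return np.clip(f, 0.0, 1.0)


def format_coverage(fraction, decimals: int = 2) -> str:
    """Render a fractional coverage as a percentage string (1e-4 -> '0.01%')."""
    return f"{float(fraction) * 100:.{decimals}f}%"


def quantify_scene(
    afai: AfaiGrid,
    mask: MaskGrid,
    detector: Detector | None = None,
    threshold: float | None = None,
    dilation_radius: int = DILATION_RADIUS,
    per_pixel: bool = False,
) -> tuple[list[SargassumPatch], np.ndarray]:
    """Run detection through unmixing; return patches and a fraction raster.

    The returned raster holds the sub-pixel fraction at quantified patch
    pixels, 0 at other valid pixels, and NaN at invalid pixels — the form
    the compositing stage consumes.
    """
    det = detect_pixels(afai, mask, detector=detector, threshold=threshold)
    patches = extract_patches(det)
    fraction = np.where(mask.valid & afai.valid_mask, 0.0, np.nan)
    kept: list[SargassumPatch] = []
    for patch in patches:
        compute_delta_afai(patch, afai, det, mask,
                           dilation_radius=dilation_radius, per_pixel=per_pixel)
        if patch.no_background:
            continue
        patch.fraction = fractional_density(patch.delta_afai)
        rows, cols = zip(*patch.pixels)
        fraction[np.array(rows), np.array(cols)] = patch.fraction
        kept.append(patch)
    return kept, fraction


def patches_to_table(patches: list[SargassumPatch], afai: AfaiGrid):
    """Flatten quantified patches to a tidy per-pixel DataFrame."""
    import pandas as pd

    records = []
    for pid, patch in enumerate(patches):
        for i, (r, c) in enumerate(patch.pixels):
            records.append(
                {
                    "patch_id": pid,
                    "row": r,
                    "col": c,
                    "afai": afai.values[r, c],
                    "delta_afai": patch.delta_afai[i] if patch.delta_afai.size else np.nan,
                    "fraction": patch.fraction[i] if patch.fraction.size else np.nan,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["patch_id", "row", "col", "afai", "delta_afai", "fraction"]
    )
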