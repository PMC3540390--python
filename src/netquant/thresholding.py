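"""Binarization: Bernsen local threshold, global threshold, moment-preserving
(Tsai) auto-threshold, and the chromatin-channel calibration rule.

The DNA (Hoechst) channel is binarized with the Bernsen local adaptive
threshold: each pixel is compared against the mid-gray of its circular
neighborhood, with a low-contrast fallback that assigns whole flat regions
to foreground or background depending on whether the local mid-gray sits
above half the dynamic range.  The chromatin channel uses a single global
threshold, either set explicitly, found by the moment-preserving (Tsai)
auto-threshold, or — for NET counting — calibrated as the minimum level at
which a designated early-activation field shows no objects at or above the
NET size cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from skimage.measure import label as _sklabel

from .errors import CalibrationError, ConfigurationError, DegenerateImageError
from .image_model import ImageField


@dataclass
class BinaryMask:
    """Foreground/background mask with the provenance of its thresholding."""

    pixels: np.ndarray  # bool, same shape as the source image
    source_field_id: str = ""
    method: str = ""  # "bernsen" | "global" | "moments"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class CalibrationResult:
    """Outcome of the chromatin-threshold calibration.

    ``threshold`` is the minimal integer level at which the calibration
    image contains at most ``tolerated_large_object_count`` connected
    components with area >= the NET size cutoff.
    """

    threshold: int
    largest_object_area_at_threshold: int
    tolerated_large_object_count: int
    calibration_field_id: str = ""


def _disk_offsets(radius: int) -> list[tuple[int, int]]:
    """Per-row half-widths of the disk footprint: (dy, wx) pairs."""
    return [
        (dy, int(np.floor(np.sqrt(radius * radius - dy * dy))))
        for dy in range(-radius, radius + 1)
    ]


def _local_extrema_disk(pixels: np.ndarray, radius: int, max_value: int):
    """Local min and max over a disk neighborhood truncated at the borders.

    The disk is expressed as a union of centered rectangles: for each
    distinct per-row half-width ``w`` the rows with at least that width
    form a contiguous band, so ``disk = union of (2w+1) x (2*dmax(w)+1)``
    rectangles, each of which separates into two 1-D passes.  Constant
    padding with the neutral element (0 for max, saturation for min)
    reproduces neighborhood truncation exactly because every neighborhood
    contains its own center pixel.
    """
    width_to_height: dict[int, int] = {}
    for dy, wx in _disk_offsets(radius):
        width_to_height[wx] = max(width_to_height.get(wx, -1), abs(dy))
    lmax = np.zeros_like(pixels)
    lmin = np.full_like(pixels, max_value)
    for w, dmax in width_to_height.items():
        hmax = maximum_filter1d(pixels, size=2 * w + 1, axis=1, mode="constant", cval=0)
        hmin = minimum_filter1d(
            pixels, size=2 * w + 1, axis=1, mode="constant", cval=max_value
        )
        if dmax > 0:
            hmax = maximum_filter1d(hmax, size=2 * dmax + 1, axis=0, mode="constant", cval=0)
            hmin = minimum_filter1d(
                hmin, size=2 * dmax + 1, axis=0, mode="constant", cval=max_value
            )
        np.maximum(lmax, hmax, out=lmax)
        np.minimum(lmin, hmin, out=lmin)
    return lmin, lmax


def bernsen_binarize(
    image: ImageField, radius: int = 15, contrast_threshold: float = 35.0
) -> BinaryMask:
    """Bernsen local adaptive threshold over a circular neighborhood.

    For each pixel, with ``local_min``/``local_max`` taken over the disk of
    the given radius (truncated at image borders), ``mid = (local_max +
    local_min) / 2`` and ``contrast = local_max - local_min``:

    * ``contrast < contrast_threshold`` (flat region): the pixel is
      foreground iff ``mid >= 2**(bit_depth-1)`` (128 for 8-bit).
    * otherwise: foreground iff the pixel value ``>= mid``.

    The radius parameterization follows the thresholding plugin the
    protocol was run with, whose size field is a radius (default 15)
    despite often being described as a diameter; pass ``radius=7`` to
    approximate a literal 15 px diameter.
    """
    if radius < 1:
        raise ConfigurationError("bernsen radius must be >= 1")
    if contrast_threshold < 0:
        raise ConfigurationError("bernsen contrast threshold must be >= 0")
    rows, cols = image.shape
    if radius > rows and radius > cols:
        raise ConfigurationError(
            f"bernsen radius {radius} exceeds both image dimensions {image.shape}"
        )
    px = image.pixels
    lmin, lmax = _local_extrema_disk(px, radius, image.max_value)
    mid = (lmax.astype(np.float64) + lmin.astype(np.float64)) / 2.0
    contrast = lmax.astype(np.float64) - lmin.astype(np.float64)
    half_range = float(2 ** (image.bit_depth - 1))
    low_contrast = contrast < contrast_threshold
    fg = np.where(low_contrast, mid >= half_range, px >= mid)
    return BinaryMask(
        pixels=fg,
        source_field_id=image.field_id,
        method="bernsen",
        parameters={"radius": radius, "contrast_threshold": contrast_threshold},
    )


def global_binarize(image: ImageField, threshold: int) -> BinaryMask:
    """Global threshold: foreground iff pixel value >= threshold (inclusive)."""
    if not 0 < threshold <= image.max_value:
        raise ConfigurationError(
            f"threshold {threshold} outside the dynamic range (1..{image.max_value})"
        )
    return BinaryMask(
        pixels=image.pixels >= threshold,
        source_field_id=image.field_id,
        method="global",
        parameters={"threshold": int(threshold)},
    )


def moments_threshold(image: ImageField) -> int:
    """Moment-preserving (Tsai) global threshold from the gray-level histogram.

    Solves for the two-level image that preserves the first three gray-level
    moments of the input: the moment equations give the background fraction
    ``p0``, and the returned level ``t`` is the gray level whose cumulative
    histogram fraction best matches ``p0`` (first level attaining the
    minimum absolute difference).  Depends only on the histogram, so it is
    invariant to any spatial rearrangement of the pixels.
    """
    px = image.pixels
    n_levels = image.max_value + 1
    hist = np.bincount(px.ravel(), minlength=n_levels).astype(np.float64)
    total = hist.sum()
    p = hist / total
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError(
            "moments threshold undefined: image has fewer than two distinct gray levels"
        )
    levels = np.arange(n_levels, dtype=np.float64)
    m1 = float(np.sum(levels * p))
    m2 = float(np.sum(levels**2 * p))
    m3 = float(np.sum(levels**3 * p))
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateImageError("moments threshold undefined: zero gray-level variance")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise DegenerateImageError("moments threshold undefined: complex representative levels")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise DegenerateImageError("moments threshold undefined: coincident representative levels")
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    t = int(np.argmin(np.abs(cum - p0)))
    return t


def _count_large_objects(
    fg: np.ndarray, area_cutoff: int, connectivity: int
) -> tuple[int, int]:
    """(number of components with area >= cutoff, largest component area)."""
    lab, n = _sklabel(fg, connectivity=1 if connectivity == 4 else 2, return_num=True)
    if n == 0:
        return 0, 0
    areas = np.bincount(lab.ravel())[1:]
    return int(np.count_nonzero(areas >= area_cutoff)), int(areas.max())


def calibrate_chromatin_threshold(
    calibration_image: ImageField,
    net_area_cutoff: int = 75,
    connectivity: int = 8,
    tolerated_large_object_count: int = 0,
) -> CalibrationResult:
    """Minimum global threshold leaving no over-cutoff object on a calibration field.

    Mechanizes the protocol's interactive step: on an image of briefly
    (10 min) activated cells, find the smallest integer threshold ``t`` such
    that global binarization at ``t`` followed by connected-component
    labeling yields at most ``tolerated_large_object_count`` components of
    area >= ``net_area_cutoff``.  The tolerance exists because genuinely
    spontaneous NETs larger than the cutoff may be present and accepted.

    The scan walks the distinct gray levels in ascending order (the mask,
    hence the component structure, only changes at those levels), which
    returns exactly the threshold an exhaustive linear scan over every
    integer level would.
    """
    if net_area_cutoff < 1:
        raise ConfigurationError("net_area_cutoff must be >= 1")
    if connectivity not in (4, 8):
        raise ConfigurationError("connectivity must be 4 or 8")
    if tolerated_large_object_count < 0:
        raise ConfigurationError("tolerated_large_object_count must be >= 0")
    px = calibration_image.pixels
    uniq = np.unique(px)
    smallest_count = None
    prev = 0
    for v in uniq:
        v = int(v)
        if v < 1:
            continue
        # mask(t) is constant = (px >= v) for every t in (prev, v]
        n_large, max_area = _count_large_objects(px >= v, net_area_cutoff, connectivity)
        if n_large <= tolerated_large_object_count:
            return CalibrationResult(
                threshold=prev + 1,
                largest_object_area_at_threshold=max_area,
                tolerated_large_object_count=tolerated_large_object_count,
                calibration_field_id=calibration_image.field_id,
            )
        smallest_count = n_large if smallest_count is None else min(smallest_count, n_large)
        prev = v
    # above the brightest pixel the foreground is empty
    t_empty = int(uniq[-1]) + 1
    if t_empty <= calibration_image.max_value:
        return CalibrationResult(
            threshold=t_empty,
            largest_object_area_at_threshold=0,
            tolerated_large_object_count=tolerated_large_object_count,
            calibration_field_id=calibration_image.field_id,
        )
    raise CalibrationError(smallest_count if smallest_count is not None else 0)
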