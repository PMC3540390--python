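"""Per-field dual-channel counting, the NET-rate statistic, per-specimen
aggregation, and RGB overlay control images.

The headline statistic is

    NET-rate [%] = 100 x (objects counted in the chromatin channel)
                       / (objects counted in the DNA channel)

where DNA objects come from Bernsen binarization + particle analysis with
a 20 px minimum size, and chromatin objects from a calibrated global
threshold + particle analysis with a 75 px size cutoff.  Rates above 100%
are reported as computed (clamping would hide segmentation failures the
overlay images exist to expose).  Per specimen, rates of the individual
fields are averaged and their sample standard deviation (n-1 denominator)
reported; the fields are treated as a sample of the coverslip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.segmentation import find_boundaries

from .errors import (
    ChannelMismatchError,
    ConfigurationError,
    DimensionMismatchError,
    UndefinedRateError,
)
from .image_model import ImageField, SegmentationParams
from .particles import ParticleSet, filter_by_area, label_particles
from .thresholding import bernsen_binarize, global_binarize


@dataclass
class FieldResult:
    """Counts and NET-rate of one microscope field."""

    field_id: str
    specimen_id: str
    nuclei_count: int
    net_event_count: int
    net_rate_pct: float
    params: SegmentationParams | None = None


@dataclass
class SpecimenResult:
    """Mean +/- SD of the per-field NET-rates of one specimen.

    ``sd_rate_pct`` is ``None`` (reported as missing) when fewer than two
    fields are available; with >= 2 fields it is the sample SD (n-1).
    """

    specimen_id: str
    field_rates: list[float]
    mean_rate_pct: float
    sd_rate_pct: float | None
    n_fields: int


def count_nuclei(
    dna_image: ImageField, params: SegmentationParams
) -> tuple[int, ParticleSet]:
    """Count nuclei in the DNA (Hoechst) channel.

    Bernsen local threshold (radius / contrast from ``params``) ->
    connected-component labeling -> inclusive minimum-size filter
    (``nucleus_min_area``, default 20 px, no upper bound).
    """
    if dna_image.channel != "dna":
        raise ChannelMismatchError(
            f"count_nuclei needs a dna-channel image, got {dna_image.channel!r}"
        )
    mask = bernsen_binarize(dna_image, params.bernsen_radius, params.bernsen_contrast)
    particles = label_particles(mask, params.connectivity)
    particles = filter_by_area(particles, params.nucleus_min_area)
    return len(particles), particles


def count_net_events(
    chromatin_image: ImageField, params: SegmentationParams
) -> tuple[int, ParticleSet]:
    """Count NETotic events in the anti-chromatin channel.

    Global threshold at ``params.chromatin_threshold`` (which must have
    been set, normally by calibration) -> labeling -> inclusive size
    cutoff (``net_area_cutoff``, default 75 px).
    """
    if chromatin_image.channel != "chromatin":
        raise ChannelMismatchError(
            f"count_net_events needs a chromatin-channel image, got {chromatin_image.channel!r}"
        )
    if params.chromatin_threshold is None:
        raise ConfigurationError(
            "chromatin_threshold is not set; run calibrate_chromatin_threshold "
            "on a calibration field or set it explicitly"
        )
    mask = global_binarize(chromatin_image, params.chromatin_threshold)
    particles = label_particles(mask, params.connectivity)
    particles = filter_by_area(particles, params.net_area_cutoff)
    return len(particles), particles


def net_rate(net_event_count: int, nuclei_count: int) -> float:
    """NET-rate [%] = 100 x net events / nuclei; undefined at zero nuclei.

    The value is not clamped: rates above 100% are possible (e.g. released
    NETs without a countable nucleus) and are reported as computed.
    """
    if nuclei_count <= 0:
        raise UndefinedRateError(
            f"NET-rate undefined: nuclei count is {nuclei_count} (must be > 0)"
        )
    return 100.0 * net_event_count / nuclei_count


def quantify_field(
    dna: ImageField, chromatin: ImageField, params: SegmentationParams
) -> FieldResult:
    """Run both channel counts on one field and compute its NET-rate."""
    if dna.shape != chromatin.shape:
        raise DimensionMismatchError(
            f"channel dimensions differ: dna {dna.shape} vs chromatin {chromatin.shape}"
        )
    if dna.field_id != chromatin.field_id:
        raise DimensionMismatchError(
            f"field ids differ: {dna.field_id!r} vs {chromatin.field_id!r}"
        )
    nuclei, _ = count_nuclei(dna, params)
    events, _ = count_net_events(chromatin, params)
    if nuclei == 0:
        raise UndefinedRateError(
            f"NET-rate undefined for field {dna.field_id!r}: zero nuclei counted"
        )
    return FieldResult(
        field_id=dna.field_id,
        specimen_id=dna.specimen_id,
        nuclei_count=nuclei,
        net_event_count=events,
        net_rate_pct=net_rate(events, nuclei),
        params=params.snapshot(),
    )


def quantify_specimen(fields: list[FieldResult]) -> SpecimenResult:
    """Aggregate per-field rates of one specimen into mean +/- sample SD."""
    if not fields:
        raise ValueError("quantify_specimen needs at least one field result")
    specimen_ids = {f.specimen_id for f in fields}
    if len(specimen_ids) != 1:
        raise ValueError(f"mixed specimen ids: {sorted(specimen_ids)}")
    rates = [f.net_rate_pct for f in fields]
    mean = float(np.mean(rates))
    sd = float(np.std(rates, ddof=1)) if len(rates) >= 2 else None
    return SpecimenResult(
        specimen_id=fields[0].specimen_id,
        field_rates=rates,
        mean_rate_pct=mean,
        sd_rate_pct=sd,
        n_fields=len(rates),
    )


def _scale_to_u8(pixels: np.ndarray) -> np.ndarray:
    lo, hi = int(pixels.min()), int(pixels.max())
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.uint8)
    return ((pixels.astype(np.float64) - lo) / (hi - lo) * 255.0).astype(np.uint8)


#: outline colors for the overlay (RGB): cyan for DNA objects, yellow for NETs
DNA_OUTLINE = (0, 255, 255)
NET_OUTLINE = (255, 255, 0)


def render_overlay(
    dna: ImageField,
    chromatin: ImageField,
    dna_particles: ParticleSet,
    net_particles: ParticleSet,
    path: str | Path,
    elastase: ImageField | None = None,
) -> None:
    """Write an RGB control image: channels merged plus segmentation outlines.

    DNA maps to blue, chromatin to red, elastase (if given) to green, each
    min-max scaled; the outer 1 px boundary of every counted DNA object is
    drawn in cyan and of every NET object in yellow.  Purely for visual
    quality control — nothing downstream ever reads these files back.
    """
    if dna.shape != chromatin.shape or (elastase is not None and elastase.shape != dna.shape):
        raise DimensionMismatchError("overlay channels must share dimensions")
    rgb = np.zeros((*dna.shape, 3), dtype=np.uint8)
    rgb[..., 2] = _scale_to_u8(dna.pixels)
    rgb[..., 0] = _scale_to_u8(chromatin.pixels)
    if elastase is not None:
        rgb[..., 1] = _scale_to_u8(elastase.pixels)
    for pset, color in ((dna_particles, DNA_OUTLINE), (net_particles, NET_OUTLINE)):
        if len(pset) == 0:
            continue
        if pset.label_map.shape != dna.shape:
            raise DimensionMismatchError("particle label map does not match overlay dimensions")
        outline = find_boundaries(pset.label_map > 0, mode="outer")
        rgb[outline] = color
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb, photometric="rgb")
    else:
        iio.imwrite(path, rgb)
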