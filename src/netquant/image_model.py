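"""Core image and configuration types plus grayscale/tabular I/O.

The quantification pipeline works on single-channel grayscale micrographs:
one DNA-stain (Hoechst) image and one anti-chromatin immunofluorescence
image per microscope field, optionally a third elastase channel used only
for overlay rendering.  Images are 8- or 16-bit; RGB input is rejected
rather than converted, because silent conversion would shift every
threshold in the procedure (the acquisition camera is monochrome).

All sizes and cutoffs are expressed in pixels throughout; ``pixel_size_um``
is carried as metadata only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, ImageFormatError

CHANNELS = ("dna", "chromatin", "elastase")

#: CSV column order shared by per-field and per-specimen result rows.
RESULT_COLUMNS = (
    "record_type",
    "specimen_id",
    "field_id",
    "nuclei_count",
    "net_event_count",
    "net_rate_pct",
    "mean_rate_pct",
    "sd_rate_pct",
    "n_fields",
)


@dataclass
class ImageField:
    """One single-channel grayscale micrograph with provenance metadata.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer intensities (uint8 or uint16).
    bit_depth
        8 or 16; all intensities must lie in ``[0, 2**bit_depth - 1]``.
    channel
        One of ``"dna"``, ``"chromatin"``, ``"elastase"``.
    field_id, specimen_id
        Free-text labels that travel into every result row (traceability).
    pixel_size_um
        Optional microns-per-pixel scale; metadata only, never used to
        convert the pixel-based size cutoffs.
    """

    pixels: np.ndarray
    bit_depth: int
    channel: str
    field_id: str = ""
    specimen_id: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ImageFormatError(
                f"pixels must be a 2-D grid of at least 1x1, got shape {self.pixels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ImageFormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.channel not in CHANNELS:
            raise ImageFormatError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ImageFormatError(f"pixels must be integer-typed, got {self.pixels.dtype}")
        if self.pixels.min() < 0 or self.pixels.max() > self.max_value:
            raise ImageFormatError(
                f"intensities outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )
        # canonical dtype for the declared depth
        self.pixels = self.pixels.astype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Saturation level of the dynamic range (255 or 65535)."""
        return 2**self.bit_depth - 1


@dataclass
class ChannelStack:
    """Ordered fields of one channel, grouped by specimen.

    The acquisition design takes five fields per specimen (coverslip), but
    any count >= 1 is accepted.
    """

    fields: list[ImageField]
    specimen_map: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fields:
            raise ImageFormatError("a ChannelStack needs at least one field")
        channels = {f.channel for f in self.fields}
        depths = {f.bit_depth for f in self.fields}
        if len(channels) != 1:
            raise ImageFormatError(f"mixed channels in stack: {sorted(channels)}")
        if len(depths) != 1:
            raise ImageFormatError(f"mixed bit depths in stack: {sorted(depths)}")
        if not self.specimen_map:
            groups: dict[str, list[int]] = {}
            for i, f in enumerate(self.fields):
                groups.setdefault(f.specimen_id, []).append(i)
            self.specimen_map = groups

    @property
    def channel(self) -> str:
        return self.fields[0].channel

    def __len__(self) -> int:
        return len(self.fields)


@dataclass
class SegmentationParams:
    """All thresholds and size cutoffs of the quantification procedure.

    Defaults follow the published batch protocol: Bernsen local threshold
    at radius 15 with contrast threshold 35 for the DNA channel, a 20 px
    minimum nucleus size, and a 75 px size cutoff for chromatin (NET)
    events.  ``chromatin_threshold`` is normally produced by
    :func:`netquant.thresholding.calibrate_chromatin_threshold` on a
    designated calibration field and must be set before NET events can be
    counted.
    """

    bernsen_radius: int = 15
    bernsen_contrast: float = 35.0
    nucleus_min_area: int = 20
    net_area_cutoff: int = 75
    chromatin_threshold: int | None = None
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.bernsen_radius < 1:
            raise ConfigurationError("bernsen_radius must be >= 1")
        if self.bernsen_contrast < 0:
            raise ConfigurationError("bernsen_contrast must be >= 0")
        if self.nucleus_min_area < 1 or self.net_area_cutoff < 1:
            raise ConfigurationError("size cutoffs must be strictly positive")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")
        if self.chromatin_threshold is not None and self.chromatin_threshold < 1:
            raise ConfigurationError("chromatin_threshold must be >= 1 when set")

    def snapshot(self) -> "SegmentationParams":
        """Independent copy frozen into each FieldResult."""
        return dataclasses.replace(self)


def read_field(
    path: str | Path,
    channel: str,
    bit_depth: int | None = None,
    field_id: str = "",
    specimen_id: str = "",
    pixel_size_um: float | None = None,
) -> ImageField:
    """Read a single-channel grayscale TIFF or PNG into an :class:`ImageField`.

    Intensities are preserved bit-exactly.  RGB/multi-channel and multi-page
    files are rejected, not converted; bit depths other than 8 or 16 are
    rejected.  ``bit_depth`` acts as a hint that must match the file when
    given.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except ImageFormatError:
        raise
    except Exception as exc:  # decoding failure of any flavor
        raise ImageFormatError(f"could not decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ImageFormatError(
            f"multi-channel input: {path} has shape {arr.shape}; "
            "expected a single-channel grayscale image"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ImageFormatError(f"unsupported sample type {arr.dtype} in {path}; need uint8/uint16")
    if bit_depth is not None and bit_depth != depth:
        raise ImageFormatError(f"{path} is {depth}-bit, caller expected {bit_depth}-bit")
    if not field_id:
        field_id = path.stem
    return ImageField(
        pixels=arr,
        bit_depth=depth,
        channel=channel,
        field_id=field_id,
        specimen_id=specimen_id,
        pixel_size_um=pixel_size_um,
    )


def write_field(image: ImageField, path: str | Path) -> None:
    """Write an :class:`ImageField` as grayscale TIFF or PNG, bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)


def write_results_table(results: Sequence[object], path: str | Path) -> None:
    """Serialize FieldResult and/or SpecimenResult records to CSV.

    One row per record with a ``record_type`` discriminator column; columns
    are :data:`RESULT_COLUMNS` in fixed order, numbers formatted with a dot
    decimal separator regardless of locale (pandas default).
    """
    if not results:
        raise ValueError("write_results_table needs a non-empty result list")
    rows = [result_row(r) for r in results]
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    for col in ("nuclei_count", "net_event_count", "n_fields"):
        df[col] = df[col].astype("Int64")  # keep counts integral next to missing cells
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def result_row(record: object) -> dict:
    """Flatten one result record into the shared CSV schema."""
    # imported lazily to avoid a circular module dependency
    from .quantify import FieldResult, SpecimenResult

    if isinstance(record, FieldResult):
        return {
            "record_type": "field",
            "specimen_id": record.specimen_id,
            "field_id": record.field_id,
            "nuclei_count": record.nuclei_count,
            "net_event_count": record.net_event_count,
            "net_rate_pct": record.net_rate_pct,
            "mean_rate_pct": None,
            "sd_rate_pct": None,
            "n_fields": None,
        }
    if isinstance(record, SpecimenResult):
        return {
            "record_type": "specimen",
            "specimen_id": record.specimen_id,
            "field_id": None,
            "nuclei_count": None,
            "net_event_count": None,
            "net_rate_pct": None,
            "mean_rate_pct": record.mean_rate_pct,
            "sd_rate_pct": record.sd_rate_pct,
            "n_fields": record.n_fields,
        }
    raise TypeError(f"cannot serialize {type(record).__name__} into a result row")
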