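"""Synthetic two-channel fluorescence fields with known ground truth.

The generator stands in for fields of stained neutrophils and emulates the
phenomenology the quantification method relies on:

* **resting cells** — small (~10 µm) lobulated nuclei drawn as 3–4
  overlapping soft ellipses, bright in the DNA (Hoechst) channel and dim
  in the anti-chromatin channel;
* **NETotic cells** — expanded (~22 µm) soft-edged disks, dim in DNA and
  bright in chromatin (antibody access to decondensed chromatin inverts
  the channel ratio);
* **released NETs** — large irregular chromatin-only blobs with no
  countable nucleus;
* confounders: sub-nucleus-size bright DNA specks (bacterial DNA) and a
  confluence mode in which NETotic cells are placed in overlapping
  clusters so their chromatin footprints merge into single particles.

The default pixel scale is 0.64 µm/px, calibrated so the procedure's pixel
cutoffs are meaningful at 10x magnification: a 10 µm resting nucleus spans
~16 px (area ≈ 190 px, above the 20 px nucleus filter) and a 22 µm NETotic
cell ~34 px (area ≈ 900 px, above the 75 px NET cutoff).  Noise is additive
Gaussian read noise plus gain-scaled Poisson shot noise, clipped to the
dynamic range.  Everything is deterministic given the scene seed.

A dedicated calibration preset emulates the briefly (10 min) activated
calibration specimen: chromatin staining already brighter than in truly
resting cells but with no expanded footprints, so the calibrated threshold
lands above every resting-cell chromatin signal while staying far below
NETotic signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnplaceableSceneError
from .image_model import ChannelStack, ImageField, write_field

RESTING = "resting"
NETOTIC = "netotic"
NET = "net"


@dataclass
class SceneSpec:
    """Parameters of one synthetic field.

    Intensity bands are (low, high) peak ranges on the native gray scale;
    defaults target 8-bit images.  The resting chromatin band must lie
    entirely below the NETotic chromatin band — the separability the real
    staining provides and the method depends on.
    """

    shape: tuple[int, int] = (1024, 1024)
    bit_depth: int = 8
    pixel_size_um: float = 0.64
    n_resting: int = 70
    n_netotic: int = 30
    n_nets: int = 0
    resting_diameter_um: float = 10.0
    netotic_diameter_um: float = 22.0
    net_diameter_um: float = 30.0
    dna_band_resting: tuple[float, float] = (170.0, 220.0)
    dna_band_netotic: tuple[float, float] = (60.0, 95.0)
    chromatin_band_resting: tuple[float, float] = (35.0, 55.0)
    chromatin_band_netotic: tuple[float, float] = (150.0, 210.0)
    chromatin_band_net: tuple[float, float] = (150.0, 210.0)
    background_dna: float = 8.0
    background_chromatin: float = 6.0
    read_noise_sigma: float = 2.0
    shot_noise_gain: float = 0.25
    dna_specks: int = 0
    speck_max_area_px: int = 12
    speck_intensity: float = 230.0
    confluent_nets: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        if min(self.n_resting, self.n_netotic, self.n_nets, self.dna_specks) < 0:
            raise ConfigurationError("counts must be >= 0")
        if min(self.resting_diameter_um, self.netotic_diameter_um, self.net_diameter_um) <= 0:
            raise ConfigurationError("diameters must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.chromatin_band_resting[1] >= self.chromatin_band_netotic[0]:
            raise ConfigurationError(
                "resting chromatin band must lie entirely below the netotic band: "
                f"{self.chromatin_band_resting} vs {self.chromatin_band_netotic}"
            )
        max_val = 2**self.bit_depth - 1
        for band in (
            self.dna_band_resting,
            self.dna_band_netotic,
            self.chromatin_band_resting,
            self.chromatin_band_netotic,
            self.chromatin_band_net,
        ):
            if not (0 <= band[0] <= band[1] <= max_val):
                raise ConfigurationError(f"intensity band {band} invalid for {self.bit_depth}-bit")


@dataclass
class CellTruth:
    """Ground-truth record of one rendered cell or NET blob."""

    cell_class: str  # resting | netotic | net
    center: tuple[float, float]  # (row, col)
    diameter_px: float
    dna_peak: float
    chromatin_peak: float


@dataclass
class GroundTruth:
    """True inventory of a synthetic field."""

    cells: list[CellTruth]
    n_resting: int
    n_netotic: int
    n_nets: int
    speck_centers: list[tuple[float, float]] = dc_field(default_factory=list)

    @property
    def true_fraction(self) -> float:
        """True NETosis fraction = netotic / (resting + netotic); 0 if no cells."""
        denom = self.n_resting + self.n_netotic
        return self.n_netotic / denom if denom else 0.0


# ---------------------------------------------------------------------------
# placement

def _collides(row, col, radius, placed: list[tuple[float, float, float]], gap: float) -> bool:
    if not placed:
        return False
    arr = np.asarray(placed)
    d2 = (arr[:, 0] - row) ** 2 + (arr[:, 1] - col) ** 2
    return bool(np.any(d2 < (arr[:, 2] + radius + gap) ** 2))


def _place(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radius: float,
    placed: list[tuple[float, float, float]],
    gap: float = 3.0,
    max_tries: int = 4000,
) -> tuple[float, float]:
    margin = radius + 2.0
    if shape[0] - 2 * margin <= 0 or shape[1] - 2 * margin <= 0:
        raise UnplaceableSceneError(
            f"field {shape} too small for an object of radius {radius:.1f}"
        )
    for _ in range(max_tries):
        row = rng.uniform(margin, shape[0] - margin)
        col = rng.uniform(margin, shape[1] - margin)
        if not _collides(row, col, radius, placed, gap):
            placed.append((row, col, radius))
            return row, col
    raise UnplaceableSceneError(
        f"could not place an object of radius {radius:.1f} after {max_tries} tries; "
        "the field is too crowded for non-overlapping placement"
    )


# ---------------------------------------------------------------------------
# rendering primitives (all compose by elementwise maximum)

def _window(canvas: np.ndarray, row: float, col: float, reach: float):
    r0 = max(int(np.floor(row - reach)), 0)
    r1 = min(int(np.ceil(row + reach)) + 1, canvas.shape[0])
    c0 = max(int(np.floor(col - reach)), 0)
    c1 = min(int(np.ceil(col + reach)) + 1, canvas.shape[1])
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return (slice(r0, r1), slice(c0, c1)), yy - row, xx - col


def _soft_disk(dist: np.ndarray, r_full: float, r_zero: float) -> np.ndarray:
    """1 inside r_full, linear ramp to 0 at r_zero."""
    if r_zero <= r_full:
        return (dist <= r_full).astype(float)
    return np.clip((r_zero - dist) / (r_zero - r_full), 0.0, 1.0)


def _paint(canvas: np.ndarray, win, values: np.ndarray) -> None:
    np.maximum(canvas[win], values, out=canvas[win])


def _render_resting(dna, chrom, rng, row, col, radius, dna_peak, chrom_peak) -> None:
    win, dy, dx = _window(dna, row, col, radius + 3)
    n_lobes = int(rng.integers(3, 5))
    coverage = np.zeros(dy.shape)
    for _ in range(n_lobes):
        ang = rng.uniform(0, np.pi)
        off = rng.uniform(0, 0.45 * radius)
        oang = rng.uniform(0, 2 * np.pi)
        lr = rng.uniform(0.55, 0.70) * radius
        ratio = rng.uniform(0.70, 1.0)
        cy, cx = off * np.sin(oang), off * np.cos(oang)
        u = (dy - cy) * np.cos(ang) + (dx - cx) * np.sin(ang)
        v = -(dy - cy) * np.sin(ang) + (dx - cx) * np.cos(ang)
        de = np.sqrt((u / lr) ** 2 + (v / (lr * ratio)) ** 2)  # 1 at the ellipse edge
        coverage = np.maximum(coverage, np.clip((1.15 - de) / 0.30, 0.0, 1.0))
    _paint(dna, win, dna_peak * coverage)
    # chromatin: smooth dome over the nucleus (dim, graded signal)
    dist = np.hypot(dy, dx)
    dome = np.clip(1.0 - (dist / radius) ** 2, 0.0, 1.0)
    _paint(chrom, win, chrom_peak * dome)


def _render_netotic(dna, chrom, row, col, radius, dna_peak, chrom_peak) -> None:
    win, dy, dx = _window(dna, row, col, 1.05 * radius + 3)
    dist = np.hypot(dy, dx)
    # chromatin cloud extends beyond the residual DNA signal
    _paint(chrom, win, chrom_peak * _soft_disk(dist, 0.85 * radius, 1.05 * radius))
    _paint(dna, win, dna_peak * _soft_disk(dist, 0.60 * radius, 0.72 * radius))


def _render_net_blob(chrom, rng, row, col, radius, chrom_peak) -> None:
    win, dy, dx = _window(chrom, row, col, 1.45 * radius + 3)
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_theta = np.full(theta.shape, float(radius))
    for k in range(2, 5):
        amp = rng.uniform(0.05, 0.15) * radius
        phase = rng.uniform(0, 2 * np.pi)
        r_theta = r_theta + amp * np.cos(k * theta + phase)
    _paint(chrom, win, chrom_peak * np.clip((r_theta - dist) / 2.0 + 0.5, 0.0, 1.0))


def _speck_radius(max_area_px: int) -> float:
    """Largest disk radius whose pixelized area stays within max_area_px."""
    best = 0.5
    for r in np.arange(0.5, 4.01, 0.05):
        k = int(np.ceil(r))
        yy, xx = np.mgrid[-k : k + 1, -k : k + 1]
        if np.count_nonzero(yy**2 + xx**2 <= r * r) <= max_area_px:
            best = float(r)
    return best


def _render_speck(dna, row, col, radius, peak) -> None:
    win, dy, dx = _window(dna, row, col, radius + 2)
    inside = (dy * dy + dx * dx) <= radius * radius
    _paint(dna, win, np.where(inside, peak, 0.0))


def _finish(canvas: np.ndarray, background: float, spec: SceneSpec, rng) -> np.ndarray:
    expected = canvas + background
    if spec.shot_noise_gain > 0:
        img = rng.poisson(expected / spec.shot_noise_gain).astype(np.float64)
        img *= spec.shot_noise_gain
    else:
        img = expected
    if spec.read_noise_sigma > 0:
        img = img + rng.normal(0.0, spec.read_noise_sigma, size=img.shape)
    max_val = 2**spec.bit_depth - 1
    img = np.clip(np.rint(img), 0, max_val)
    return img.astype(np.uint8 if spec.bit_depth == 8 else np.uint16)


# ---------------------------------------------------------------------------
# public generators

def generate_field(
    spec: SceneSpec, field_id: str = "field", specimen_id: str = "specimen"
) -> tuple[ImageField, ImageField, GroundTruth]:
    """Render one two-channel field plus its ground truth, deterministically.

    With ``confluent_nets`` off, every object is placed without overlap
    (an :class:`UnplaceableSceneError` is raised if the field is too small);
    with it on, NETotic cells are placed in overlapping clusters of 2–3 so
    their chromatin blobs merge.
    """
    rng = np.random.default_rng(spec.seed)
    scale = 1.0 / spec.pixel_size_um  # px per µm
    rest_r = 0.5 * spec.resting_diameter_um * scale
    neto_r = 0.5 * spec.netotic_diameter_um * scale
    net_r = 0.5 * spec.net_diameter_um * scale

    dna = np.zeros(spec.shape)
    chrom = np.zeros(spec.shape)
    placed: list[tuple[float, float, float]] = []
    cells: list[CellTruth] = []

    # NETotic cells first (largest non-blob objects pack hardest)
    if spec.confluent_nets and spec.n_netotic > 0:
        remaining = spec.n_netotic
        while remaining > 0:
            size = int(min(remaining, rng.integers(2, 4)))
            remaining -= size
            members: list[tuple[float, float, float]] = []
            for j in range(size):
                r_jit = neto_r * rng.uniform(0.92, 1.08)
                place_r = 1.05 * r_jit + 1.5
                if j == 0:
                    row, col = _place(rng, spec.shape, place_r, placed)
                    members.append((row, col, place_r))
                else:
                    row = col = None
                    for _ in range(2000):
                        base = members[int(rng.integers(0, len(members)))]
                        d = rng.uniform(1.15, 1.55) * neto_r
                        ang = rng.uniform(0, 2 * np.pi)
                        rr_, cc_ = base[0] + d * np.sin(ang), base[1] + d * np.cos(ang)
                        margin = place_r + 2.0
                        if not (
                            margin <= rr_ <= spec.shape[0] - margin
                            and margin <= cc_ <= spec.shape[1] - margin
                        ):
                            continue
                        others = [p for p in placed if p not in members]
                        if _collides(rr_, cc_, place_r, others, 3.0):
                            continue
                        row, col = rr_, cc_
                        members.append((row, col, place_r))
                        placed.append((row, col, place_r))
                        break
                    if row is None:
                        raise UnplaceableSceneError("could not place a confluent cluster member")
                cells.append(
                    CellTruth(
                        NETOTIC,
                        (row, col),
                        2 * r_jit,
                        rng.uniform(*spec.dna_band_netotic),
                        rng.uniform(*spec.chromatin_band_netotic),
                    )
                )
    else:
        for _ in range(spec.n_netotic):
            r_jit = neto_r * rng.uniform(0.92, 1.08)
            row, col = _place(rng, spec.shape, 1.05 * r_jit + 1.5, placed)
            cells.append(
                CellTruth(
                    NETOTIC,
                    (row, col),
                    2 * r_jit,
                    rng.uniform(*spec.dna_band_netotic),
                    rng.uniform(*spec.chromatin_band_netotic),
                )
            )

    for _ in range(spec.n_nets):
        r_jit = net_r * rng.uniform(0.85, 1.15)
        row, col = _place(rng, spec.shape, 1.35 * r_jit + 1.5, placed)
        cells.append(
            CellTruth(NET, (row, col), 2 * r_jit, 0.0, rng.uniform(*spec.chromatin_band_net))
        )

    for _ in range(spec.n_resting):
        r_jit = rest_r * rng.uniform(0.92, 1.08)
        row, col = _place(rng, spec.shape, r_jit + 1.5, placed)
        cells.append(
            CellTruth(
                RESTING,
                (row, col),
                2 * r_jit,
                rng.uniform(*spec.dna_band_resting),
                rng.uniform(*spec.chromatin_band_resting),
            )
        )

    speck_r = _speck_radius(spec.speck_max_area_px)
    speck_centers = []
    for _ in range(spec.dna_specks):
        row, col = _place(rng, spec.shape, speck_r + 1.0, placed)
        speck_centers.append((row, col))

    for cell in cells:
        row, col = cell.center
        radius = cell.diameter_px / 2.0
        if cell.cell_class == RESTING:
            _render_resting(dna, chrom, rng, row, col, radius, cell.dna_peak, cell.chromatin_peak)
        elif cell.cell_class == NETOTIC:
            _render_netotic(dna, chrom, row, col, radius, cell.dna_peak, cell.chromatin_peak)
        else:
            _render_net_blob(chrom, rng, row, col, radius, cell.chromatin_peak)
    for row, col in speck_centers:
        _render_speck(dna, row, col, speck_r, spec.speck_intensity)

    dna_img = ImageField(
        pixels=_finish(dna, spec.background_dna, spec, rng),
        bit_depth=spec.bit_depth,
        channel="dna",
        field_id=field_id,
        specimen_id=specimen_id,
        pixel_size_um=spec.pixel_size_um,
    )
    chrom_img = ImageField(
        pixels=_finish(chrom, spec.background_chromatin, spec, rng),
        bit_depth=spec.bit_depth,
        channel="chromatin",
        field_id=field_id,
        specimen_id=specimen_id,
        pixel_size_um=spec.pixel_size_um,
    )
    truth = GroundTruth(
        cells=cells,
        n_resting=spec.n_resting,
        n_netotic=spec.n_netotic,
        n_nets=spec.n_nets,
        speck_centers=speck_centers,
    )
    return dna_img, chrom_img, truth


def _derived_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def generate_specimen(
    spec: SceneSpec, n_fields: int = 5, specimen_id: str = "specimen"
) -> tuple[ChannelStack, ChannelStack, list[GroundTruth]]:
    """Render ``n_fields`` independent fields emulating one coverslip.

    The total cell count per field is fixed, but each field's NETotic count
    is drawn binomially around the specimen's true fraction — the sampling
    variation of photographing random regions of one coverslip.  Per-field
    seeds derive deterministically from (spec.seed, field index).
    """
    if n_fields < 1:
        raise ConfigurationError("n_fields must be >= 1")
    composition_rng = np.random.default_rng(_derived_seed(spec.seed, 90001))
    n_total = spec.n_resting + spec.n_netotic
    p = spec.n_netotic / n_total if n_total else 0.0
    dna_fields, chrom_fields, truths = [], [], []
    for i in range(n_fields):
        n_net_i = int(composition_rng.binomial(n_total, p)) if n_total else 0
        fspec = dataclasses.replace(
            spec,
            seed=_derived_seed(spec.seed, i),
            n_resting=n_total - n_net_i,
            n_netotic=n_net_i,
        )
        d, c, t = generate_field(
            fspec, field_id=f"{specimen_id}_f{i + 1}", specimen_id=specimen_id
        )
        dna_fields.append(d)
        chrom_fields.append(c)
        truths.append(t)
    return ChannelStack(dna_fields), ChannelStack(chrom_fields), truths


def generate_timecourse(
    spec: SceneSpec,
    timepoints_min: list[float],
    specimen_id: str = "timecourse",
) -> tuple[ChannelStack, ChannelStack, list[str], list[GroundTruth]]:
    """Render one field per stimulation timepoint along a decondensation trajectory.

    Class parameters are interpolated against time in minutes: DNA-dye
    intensity starts decreasing after ~10 min, chromatin staining rises to
    a plateau near 120 min, and the stained diameter grows from the resting
    ~10 µm to the NETotic >20 µm after a ~90 min lag.
    """
    if not timepoints_min:
        raise ConfigurationError("timepoints_min must be non-empty")
    n_cells = spec.n_resting + spec.n_netotic
    dna_base = float(np.mean(spec.dna_band_resting))
    chrom_base = float(np.mean(spec.chromatin_band_netotic))
    dna_fields, chrom_fields, labels, truths = [], [], [], []
    for i, t in enumerate(timepoints_min):
        d_um = float(
            np.interp(t, [0, 90, 240], [spec.resting_diameter_um, spec.resting_diameter_um,
                                        spec.netotic_diameter_um])
        )
        dna_factor = float(np.interp(t, [0, 10, 130, 240], [1.0, 1.0, 0.42, 0.38]))
        chrom_factor = float(np.interp(t, [0, 10, 120, 240], [0.30, 0.36, 1.0, 1.0]))
        rng = np.random.default_rng(_derived_seed(spec.seed, 50000 + i))
        radius = 0.5 * d_um / spec.pixel_size_um
        dna = np.zeros(spec.shape)
        chrom = np.zeros(spec.shape)
        placed: list[tuple[float, float, float]] = []
        cells = []
        for _ in range(n_cells):
            r_jit = radius * rng.uniform(0.92, 1.08)
            row, col = _place(rng, spec.shape, 1.05 * r_jit + 1.5, placed)
            dna_peak = dna_base * dna_factor * rng.uniform(0.95, 1.05)
            chrom_peak = chrom_base * chrom_factor * rng.uniform(0.95, 1.05)
            _render_netotic(dna, chrom, row, col, r_jit, dna_peak, chrom_peak)
            cells.append(CellTruth("timecourse", (row, col), 2 * r_jit, dna_peak, chrom_peak))
        label = f"{t:g}"
        dna_fields.append(
            ImageField(
                pixels=_finish(dna, spec.background_dna, spec, rng),
                bit_depth=spec.bit_depth,
                channel="dna",
                field_id=f"{specimen_id}_t{label}",
                specimen_id=specimen_id,
                pixel_size_um=spec.pixel_size_um,
            )
        )
        chrom_fields.append(
            ImageField(
                pixels=_finish(chrom, spec.background_chromatin, spec, rng),
                bit_depth=spec.bit_depth,
                channel="chromatin",
                field_id=f"{specimen_id}_t{label}",
                specimen_id=specimen_id,
                pixel_size_um=spec.pixel_size_um,
            )
        )
        labels.append(label)
        truths.append(GroundTruth(cells=cells, n_resting=0, n_netotic=0, n_nets=0))
    return ChannelStack(dna_fields), ChannelStack(chrom_fields), labels, truths


# ---------------------------------------------------------------------------
# scenario presets (documentation/demo configs; the real experiments they are
# named after depend on donor cells and are not claimed to be reproduced)

def _fraction_spec(n_total: int, fraction: float, **overrides) -> SceneSpec:
    n_net = int(round(n_total * fraction))
    return SceneSpec(n_resting=n_total - n_net, n_netotic=n_net, **overrides)


PRESETS: dict[str, SceneSpec] = {
    "unstimulated": _fraction_spec(200, 0.02),
    "pma_2h": _fraction_spec(200, 0.40),
    "pma_6h": _fraction_spec(200, 0.80),
    "flagellin": _fraction_spec(200, 0.03),
    "pseudomonas_moi100": _fraction_spec(200, 0.40, dna_specks=40),
    # 10-min-activation analog used to calibrate the chromatin threshold:
    # chromatin already brighter than truly resting cells, no expanded footprints
    "calibration_10min": SceneSpec(
        shape=(512, 512),
        n_resting=50,
        n_netotic=0,
        chromatin_band_resting=(58.0, 75.0),
    ),
    # stimulation time-course imaged at 40x (0.16 um/px) with a low camera
    # noise floor, so the Moments auto-threshold always clears the background
    "timecourse_40x": SceneSpec(
        shape=(1024, 1024),
        n_resting=12,
        n_netotic=0,
        pixel_size_um=0.16,
        background_chromatin=2.0,
        read_noise_sigma=1.0,
    ),
}


def get_preset(name: str, seed: int | None = None) -> SceneSpec:
    """Fetch a named scenario preset, optionally reseeded."""
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available presets: {', '.join(sorted(PRESETS))}"
        )
    spec = dataclasses.replace(PRESETS[name])
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    return spec


def calibration_field(
    seed: int = 0, shape: tuple[int, int] = (512, 512)
) -> ImageField:
    """Generate the chromatin channel of a 10-min-activation calibration field."""
    spec = dataclasses.replace(get_preset("calibration_10min", seed=seed), shape=shape)
    _, chrom, _ = generate_field(spec, field_id="calibration", specimen_id="calibration")
    return chrom


def write_specimen(
    out_dir: str | Path,
    dna_stack: ChannelStack,
    chromatin_stack: ChannelStack,
    truths: list[GroundTruth],
) -> None:
    """Write a generated specimen as per-field TIFFs plus a ground-truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell_rows, summary_rows = [], []
    for dna, chrom, truth in zip(dna_stack.fields, chromatin_stack.fields, truths):
        write_field(dna, out_dir / f"{dna.field_id}_dna.tif")
        write_field(chrom, out_dir / f"{chrom.field_id}_chromatin.tif")
        for cell in truth.cells:
            cell_rows.append(
                {
                    "specimen_id": dna.specimen_id,
                    "field_id": dna.field_id,
                    "cell_class": cell.cell_class,
                    "center_row": cell.center[0],
                    "center_col": cell.center[1],
                    "diameter_px": cell.diameter_px,
                    "dna_peak": cell.dna_peak,
                    "chromatin_peak": cell.chromatin_peak,
                }
            )
        summary_rows.append(
            {
                "specimen_id": dna.specimen_id,
                "field_id": dna.field_id,
                "n_resting": truth.n_resting,
                "n_netotic": truth.n_netotic,
                "n_nets": truth.n_nets,
                "n_specks": len(truth.speck_centers),
                "true_fraction": truth.true_fraction,
            }
        )
    pd.DataFrame(cell_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out_dir / "ground_truth_summary.csv", index=False)
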