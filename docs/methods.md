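# Methods

## The quantification procedure

`netquant` implements a semi-automatic, dual-channel fluorescence
quantification of in vitro NET (neutrophil extracellular trap) formation.
The biological contrast it exploits: resting neutrophils have small
(~10 µm), condensed, lobulated nuclei that stain brightly with
DNA-intercalating dyes (Hoechst 33342) but weakly with anti-chromatin
antibodies; during NETosis the nucleus decondenses and expands (>20 µm),
DNA-dye intensity drops, and anti-chromatin staining rises sharply because
the antibody penetrates decondensed chromatin.  Counting objects per
channel therefore counts *all* cells (DNA channel) and *NETotic events*
(chromatin channel), and their ratio is the statistic of interest:

```
NET-rate [%] = 100 × N_chromatin / N_dna
```

Per field (one microscope image position) the pipeline is:

1. **DNA channel** → Bernsen local adaptive threshold (radius 15,
   contrast threshold 35) → connected-component labeling (8-connectivity)
   → keep objects of area ≥ 20 px → `nuclei_count`.
2. **Chromatin channel** → global threshold at a calibrated level →
   labeling → keep objects of area ≥ 75 px → `net_event_count`.
3. `net_rate_pct = 100 × net_event_count / nuclei_count`, undefined (an
   error, never silently 0) when no nuclei are counted, and deliberately
   not clamped at 100% — a rate above 100% flags segmentation failure or
   cell loss that the RGB overlay control images exist to expose.

Per specimen (coverslip), typically five fields are photographed at random
positions; the per-field rates are averaged and their sample standard
deviation (n−1 denominator) reported.  The fields are treated as a random
sample of the coverslip, which is why rates — not pooled counts — are the
unit of aggregation.

All sizes and cutoffs are in pixels; `pixel_size_um` is metadata only.
Both 8- and 16-bit grayscale inputs are supported; RGB input is rejected
rather than converted, because the acquisition camera is monochrome and a
silent luminance conversion would shift every threshold.

## Bernsen local threshold

For each pixel, local minimum and maximum are taken over a disk of the
configured radius, truncated at image borders (no synthetic padding).
With `mid = (local_max + local_min)/2` and
`contrast = local_max − local_min`:

* `contrast < contrast_threshold` (flat neighborhood): the pixel is
  foreground iff `mid ≥ 2^(bit_depth−1)` — whole flat regions are assigned
  by their absolute brightness;
* otherwise foreground iff `pixel ≥ mid`.

The parameter is named **radius** (default 15).  The procedure this
reproduces is usually described as "diameter 15", but the thresholding
plugin it names parameterizes its window by a radius field whose default
is 15; we reproduce the tool as run.  Users wanting a literal 15 px
diameter can pass `radius=7`.

Implementation note: the disk is decomposed into a union of centered
rectangles (one per distinct per-row half-width), each separable into two
1-D min/max passes, giving exact truncated-disk extrema in
O(radius · N) instead of O(radius² · N).  The unit tests compare every
mask against a brute-force per-pixel neighborhood enumeration.

## Moment-preserving (Tsai) threshold

The chromatin channel of the staining-pattern analyses is auto-thresholded
with the moment-preserving criterion: choose the bilevel image that
preserves the first three gray-level moments of the input.  The moment
equations yield the background fraction `p0`; the returned threshold is
the gray level whose cumulative histogram fraction is closest to `p0`
(first level attaining the minimum).  A constant image has no threshold
and raises a degenerate-input error.  The test oracle re-derives the
threshold by a different route (linear solve for the characteristic
polynomial, `numpy.roots`, then the same quantile rule).

## Chromatin-threshold calibration

The original procedure sets the chromatin threshold *interactively*: the
minimum threshold that leaves no objects larger than 75 px on an image of
briefly (10 min) activated cells — cells whose chromatin staining has
already brightened but whose footprints have not yet expanded.
`calibrate_chromatin_threshold` mechanizes this: the smallest integer
level `t` such that global binarization at `t` yields at most
`tolerated_large_object_count` components of area ≥ `net_area_cutoff`.
The tolerance (default 0) is the mechanized form of the human judgment
"except spontaneous NETs": a calibrator who sees k genuine spontaneous
NETs in the calibration field passes `tolerated_large_object_count=k`.

The scan walks the distinct gray levels in ascending order; since the
mask — and hence the component structure — changes only at those levels,
this returns exactly the threshold of an exhaustive per-integer linear
scan (asserted against one in the tests).  Foreground is inclusive
(`pixel ≥ t`), and "larger than 75 px" is implemented as `area ≥ 75`
being a violation, the complement of the counting stage's inclusive
`area ≥ 75` cutoff, so calibration and counting criteria are exactly
complementary.

## Particle analysis conventions

* Connectivity default 8; labels are consecutive 1..N in row-major order
  of each component's first pixel, so outputs are stable across runs.
* Area filters are inclusive at both ends: a 20 px nucleus and a 75 px
  chromatin object both count.
* Edge-touching objects are included; excluding them would bias against
  large NETs at field borders.
* No hole filling, no watershed splitting.  Confluent NETs merge into
  single particles and the event count drops — a known, accepted
  undercounting mode of the method (see the confluence study below).

## Staining-pattern analyses

`line_profile` samples all channels along one shared segment at unit-pixel
steps with nearest-pixel lookup (single-pixel line width, no sub-pixel
interpolation — interpolation would alter values on sharp synthetic
edges).  `timecourse_summarize` segments each timepoint's chromatin image
with the moments threshold, labels all objects (no size filter by default;
an optional `min_area` is exposed), measures per-object maximum intensity
in both channels, and reports per-timepoint means of the maxima plus mean
object area.  A timepoint whose chromatin image is constant is flagged
with an error while the remaining timepoints are still summarized.

## The synthetic-data generator

No image data is deposited for this method, so validation uses a
generator whose defaults encode the study conditions:

| parameter | default | rationale |
|---|---|---|
| pixel scale | 0.64 µm/px | 10× acquisition; makes a 10 µm nucleus ≈ 16 px across (area ≈ 190 px ≥ 20 px filter) and a 22 µm NETotic cell ≈ 34 px (area ≈ 900 px ≥ 75 px cutoff) |
| resting cells | 10 µm, DNA peaks 170–220, chromatin peaks 35–55 | bright condensed nucleus, weak antibody signal |
| resting shape | 3–4 overlapping soft ellipses | lobulated polymorphonuclear morphology |
| NETotic cells | 22 µm soft disks, DNA 60–95, chromatin 150–210 | decondensed: DNA-dim, chromatin-bright; the chromatin cloud is drawn wider (1.05 r) than the residual DNA disk (0.72 r), as antibody staining surrounds the residual DNA signal |
| released NETs | ~30 µm irregular chromatin-only blobs | count as events with no nucleus (off by default) |
| background / noise | DNA 8, chromatin 6; Gaussian read noise σ = 2; Poisson shot noise at gain 0.25 | fluorescence-camera phenomenology, clipped to the dynamic range |
| fields per specimen | 5, per-field NETotic counts drawn binomially around the specimen fraction | sampling variation of photographing random coverslip regions |

The resting chromatin dome is *graded* (quadratic falloff), so the
calibration scan sees a smoothly shrinking footprint rather than an
all-or-nothing jump.

**Calibration preset.** `calibration_10min` renders an all-resting field
whose chromatin peaks (58–75) sit *above* the standard resting band
(35–55): briefly activated cells are already brighter than truly resting
ones, which is precisely why the original procedure calibrates on them.
The threshold that silences this field therefore clears every resting
cell in test fields with margin while remaining far below NETotic signal
(≥ 150).  This yields the generator's separability guarantee (asserted in
the tests): at the calibrated threshold, every resting chromatin footprint
is < 75 px and every NETotic footprint ≥ 75 px, so recovery failures are
attributable to the pipeline, not the scene.

**Confluence confounder.** With `confluent_nets` on, NETotic cells are
placed in overlapping clusters of 2–3 (center spacing 1.15–1.55 r).
Because the chromatin footprint is a superset of the DNA footprint,
chromatin blobs merge at least as often as DNA objects do, so the
recovered rate can only fall — the documented direction of the confluence
bias, asserted pairwise over seeds.

**DNA specks.** Bright dots capped at `speck_max_area_px` (default 12 px,
below the 20 px nucleus filter) emulate extracellular bacterial DNA; they
must never change the nucleus count.

**Time-course preset.** `timecourse_40x` emulates the stimulation
time-course as acquired at 40× (0.16 µm/px, 12 cells per 1024² field)
with a lower camera noise floor (background 2, read noise σ = 1).  The
lower floor keeps the noise ceiling below the moments threshold even at
the dim 0-min timepoint, which is the generator-side contract the
no-size-filter segmentation relies on.  Class parameters are interpolated
along the decondensation trajectory: DNA intensity declines after ~10 min,
chromatin intensity rises to a plateau near ~120 min, diameter grows from
10 µm to 22 µm after a ~90 min lag.

**What the generator does not emulate:** optics (no PSF, no vignetting or
uneven illumination), focus drift, non-neutrophil cells, autofluorescence,
cell detachment, and real biological variation between donors.  Passing
the recovery tests shows the *computational* pipeline is unbiased under
the stated imaging model; it does not validate the staining chemistry or
guarantee accuracy on real micrographs with artifacts the generator omits.

## Numerical choices and degenerate inputs

* Thresholds are integers on the native gray scale; no sub-level
  interpolation anywhere.
* Bernsen `mid` is computed in floating point; ties (`pixel == mid`) are
  foreground.
* The low-contrast rule's brightness criterion scales with bit depth
  (128 for 8-bit, 32768 for 16-bit), so mid-range semantics are preserved
  for 16-bit input.
* Zero-nuclei fields raise a named error in the library; the CLI flags
  such fields in the output table (empty rate) and continues the batch.
* Specimen SD is reported as missing (not 0) for a single field.
* Scene placement uses rejection sampling with a 3 px minimum gap between
  object footprints (plus jittered radii); an overfull scene raises an
  error rather than silently overlapping.

## Validation problem sizes

The test suite validates Bernsen against brute force on 50 random 64×64
images at radii {1, 3, 7, 15}; particle analysis against a flood-fill
oracle on 100 random 32×32 masks (both connectivities); calibration
against exhaustive linear scans on 20 generated calibration fields; and
fraction recovery at true fractions {0, 0.1, 0.3, 0.5, 0.8} with 20
specimens of 5 × 200-cell fields per fraction (|mean recovered − truth| <
5 percentage points; observed errors are well under 2).
`scripts/acceptance.py` reruns the same studies at 5 specimens per
fraction, 10 confluence pairs and 5 speck pairs — sizes chosen so the
whole script completes in a few minutes while keeping Monte-Carlo error
on each reported mean far below the effects being measured.

## Known limitations

* Confluent or touching NETs are counted as single particles; the rate is
  underestimated at high NET density (by construction, ~50% of events in
  the fully clustered synthetic scenario).
* Released NETs without a residual nucleus inflate the numerator but not
  the denominator; rates above 100% are possible and intentionally
  reported as computed.
* The calibration rule assumes the calibration field genuinely contains
  no over-cutoff objects (beyond the tolerated count); calibrating on a
  field with real NETs and tolerance 0 yields an over-high threshold.
* The radius-vs-diameter ambiguity of the Bernsen window (see above) is a
  documented convention, not a resolvable fact.
* Whether edge particles were excluded in the original procedure is not
  stated; they are included here.
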