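# Methods

This note documents the models, parameter choices, and known limits of
`cryptometry`. It is written for users deciding whether the package's
operational definitions match their laboratory's protocol.

## The measurement model

A whole mount is imaged twice: once after methylene-blue staining (ACF
appear as dark foci with crypt lumens) and once after HID-AB restaining
(sulphomucin dark brown, sialomucin blue, depleted epithelium unstained).
Because the tissue is bonded to the slide, the two captures differ only
by a stage translation — no rotation, scale, or deformation — so
registration is a search over integer pixel shifts.

Each focus is a user-circumscribed closed polygon. The drawn border
belongs to the focus: filled masks include interior *and* boundary pixel
centers. All areas are pixel counts × (µm/px)²; all lengths are pixel
estimates × µm/px.

### Morphometric battery

| Quantity | Definition |
|---|---|
| `ACF_AREA` | mask pixel count × (µm/px)² |
| `ACF_PERIM` | Crofton 4-direction perimeter estimate |
| `ACF_ROUND` | `ACF_PERIM² / (4π · ACF_AREA)` |
| `ACF_DIAAVG` | mean Feret (caliper) diameter over 18 directions |
| `ACF_DEN` | mean over mask of 1 − L, L = luminance / white point, clipped to [0, 1] |
| `ACF_IOD` | `ACF_AREA × ACF_DEN` |
| `ACF_EPIAREA` | `ACF_AREA − C_SUMAREA` (epithelium = focus minus lumens) |
| `C_*` | same battery per crypt lumen, then summed (`C_SUMAREA`) or averaged |
| `C_AVGMAXDIA` | mean over crypts of the maximum Feret diameter |
| `C_AVGSIZELEN` | mean over crypts of the best-fit-ellipse major axis |
| `C_ROUNDCAT` | bin of `C_AVGROUND`: 0 [1,1.25), 1 [1.25,1.75), 2 [1.75,2.5), 3 [2.5,4), 4 [4,∞) |

Choices that were genuinely open, and what we picked:

* **Perimeter.** The Crofton (4-direction) estimator is used because
  naive boundary-pixel counting systematically overestimates and breaks
  roundness = 1 for rasterized disks. Crofton is accurate to <0.5% on
  disks of radius ≥ 50 px but *underestimates* long straight edges by
  ~5% (directional anisotropy): a rasterized axis-aligned square measures
  ≈1.14 rather than the analytic 4/π ≈ 1.273. Since ACF and crypt lumens
  are round-ish, the disk regime is the one that matters; roundness may
  dip slightly below 1 on small rasterized disks and is deliberately not
  clamped.
* **Density.** "Density" is defined as mean(1 − normalized luminance)
  with the white point defaulting to the 99th percentile of background
  (outside-focus) luminance, falling back to 255 when no background is
  visible. A mean-optical-density mode (−log10 transmittance, clipped at
  OD 2 and rescaled to [0, 1]) is available via `density_mode="od"`. The
  linear form is the default because it lands naturally on a [0, 1]
  scale. This is an operational definition and a known divergence risk
  against proprietary analyzers.
* **Diameters.** Feret extents are computed as projection span + 1 px
  (the pixel footprint), over 18 equally spaced directions. "Average size
  length" per crypt is the major-axis length of the intensity-free
  best-fit ellipse; these are documented interpretations of measurement
  names whose original definitions are proprietary.
* **Roundness categories.** The 0–4 bin edges above place a typical
  crypt roundness of ~2.2 mid-scale; the edges are configurable.

### Crypt detection

The focus patch luminance is percentile-stretched (defaults 2–98), and
pixels darker than a threshold inside the mask become lumen candidates;
8-connected components smaller than `min_area_um2` (default 50 µm²) are
discarded. The default threshold is Otsu on the stretched in-mask values
with a guard: lumens can plausibly occupy at most `max_dark_fraction`
(default 0.35) of a focus, and when a threshold exceeds that — which
happens when lumens are a tiny minority (e.g. two thin slits in a large
focus) and Otsu splits the epithelium mode instead — thresholding is
repeated on the dark subpopulation (up to 4 iterations). All detected
maps support replayable toggle / join / split edits with an edit log, in
place of interactive curation.

### Registration

`estimate_shift` exhaustively evaluates normalized cross-correlation
over all integer shifts in ±`max_shift_px` (default 50), with ties broken
toward the smallest |dx|+|dy|, then dy, then dx. Two channels are
offered: raw luminance (the direct analogue of eyeballing a half-opacity
overlay; the default and the contractual reference) and Sobel gradient
magnitude. Luminance NCC is the right tool *within* a stain but can fail
*across* stains: a mucin-depleted focus is dark in methylene blue and
near-white in HID-AB, so luminance anti-correlates exactly where the
lesions are. Tissue edges coincide regardless of stain polarity, so the
pipeline's register stage uses the gradient channel by default
(config-exposed, `register.channel`). On phantoms the gradient channel
recovers all applied shifts exactly, with or without the default noise.

### Mucin classes and MDF

Pixels inside the focus are classified in HSV with precedence
HID → AB → UNSTAINED:

* HID: hue 10–50° with value ≤ 0.55, or very dark saturated pixels
  (saturation ≥ 0.60 and value ≤ 0.35 — heavy HID deposits approach
  black);
* AB: hue 180–260° with saturation ≥ 0.25;
* otherwise UNSTAINED.

**These numeric gates are calibrated to the phantom palette** and are
fully configurable; real-slide use requires recalibration against the
user's scanner and stain batch. Percent areas are class pixel counts
over in-mask pixels (summing to 100 by construction). A focus is MDF
when the unstained percent is ≥ 85 (inclusive) *and* it does not overlap
GALT. The four stain-deposition categories are: fully depleted
(unstained ≥ 85%), sulpho-abundant (HID ≥ 70%), mixed (both stains
≥ 15%), sulpho-depleted (otherwise, with AB > HID). The 70/15 numbers
operationalize qualitative class descriptions and are configurable.

### GALT handling

GALT regions are circumscribed like foci. A focus with ≥ 50% of its area
inside GALT is flagged `galt_overlap` and excluded from MDF calling; any
lesser contact (including mere 8-adjacency) flags `galt_peripheral`, and
the focus is retained. The 50% rule is a configurable operationalization
of a qualitative exclusion.

### Statistics

Per-segment summaries count incidence (% of rats with ≥ 1 focus of the
class), totals, and per-rat mean ± sample SD **over all n_rats rats**,
i.e. rats bearing zero foci contribute zeros — the rule under which
published per-rat means reproduce from published totals. The MDF/ACF
index is 100 × MDF total / non-MDF total per segment; a zero denominator
yields NaN, not an exception. Group comparison filters to foci with
≥ 5 crypts and applies Welch's unequal-variance two-sided t test per
measure, reporting group means ± SEM; two zero-variance groups with
equal means are defined to give p = 1. No multiple-testing correction is
applied (raw p is reported).

## The phantom generator

The generator is the package's test substrate, not a histology
simulator. It renders, at 2 µm/px by default:

* a light-blue mucosa with a faint periodic "normal crypt" lattice
  (period 50 µm, amplitude 10/255) shared between both stain layers —
  the same tissue is imaged twice — plus independent per-layer Gaussian
  noise (SD 3/255 by default);
* foci as disks darker than background (darkness parameter scales the
  blend toward a dark navy), containing disjoint crypt lumens laid out
  on a ring (round disks, 2.2:0.45 aspect ellipses for slits, or
  disk-stamped Archimedean arcs for spirals);
* HID-AB foci as angular-sector partitions into the three class colors,
  with sector cuts placed by exact pixel counts so realized class
  fractions match requested fractions to within one pixel — exactness
  the threshold tests rely on;
* GALT polygons rendered pale in both layers;
* the HID-AB raster translated by a known integer (dx, dy) with the
  background color filling vacated margins.

Identical spec + seed produces bit-identical rasters. Default study
conditions (the `default_spec` phantom) use three foci spanning the
three crypt morphologies and mucin profiles from strongly stained to
depleted, one GALT region, and a (7, −3) stage shift; randomized suites
(`random_spec`) sample 192×192 px phantoms with 1–2 feasible foci, lumen
radii ≥ 3 px, and shifts within ±6 px.

What the phantom does **not** model: staining variability and gradients,
mixed stains within a pixel, tissue folds and debris, illumination
falloff, defocus that varies continuously with topography, or ACF whose
outline differs between stains. Passing the phantom suites therefore
demonstrates the *algorithms implement their definitions correctly* —
it does not validate the default HSV gates or crypt threshold against
real slides, which require per-laboratory calibration.

## Numerical conventions

* Rasters are row-major, origin top-left, 0-based, pixel-center
  addressing; polygons are (x, y) = (col, row); bounding boxes are
  half-open. Blending rounds half-up; integer outputs are uint8.
* Shift convention: `estimate_shift(ref, mov)` returns the displacement
  of `mov` relative to `ref`; `apply_shift(mov, -dx, -dy)` aligns it.
* Polygon fill uses topological coverage of pixel centers (shapely
  `covers`), equivalent to even-odd fill for the simple polygons the
  validator requires. Polygonizing a mask traces the 0.5-level contour
  so fill ∘ polygonize is the identity on hole-free masks.
* Ties in focus fusion resolve to the lowest plane index; stitching with
  `blend="none"` is last-writer-wins in row-major tile order.
* The roundness scale-invariance check redraws analytic shapes at double
  resolution rather than block-upsampling masks: nearest-neighbor
  upsampling manufactures 2-px staircases that inflate any
  discretization-consistent perimeter estimator by ~10% and says nothing
  about measurement convergence.
* Problem sizes in the test suite (320×320 default phantom, 100-seed
  randomized batches at 192×192, 1000-replicate null calibration of the
  Welch comparison) were chosen as the smallest sizes at which the
  discretization bounds above hold with margin.

## Known limitations

* The best-contrast fusion and the commercial acquisition software it
  stands in for are not claimed equivalent; only the stated contract
  (windowed-variance argmax, default window 15 px) is implemented.
* Focus-measure fusion shows the classic halo artifact: within roughly a
  blur radius of a strong edge, the defocused plane can out-score the
  sharp one. Choose the fusion window larger than the expected blur
  kernel.
* Automatic ACF *discovery* is out of scope: no published algorithm
  reliably finds ACF in methylene-blue whole mounts, so circumscription
  remains user- (or ground-truth-) driven.
* Registration is integer-translation only by design; sub-pixel or
  rotational misalignment is not corrected.
* The HSV gates, the 50% GALT rule, the 70/15 category numbers, and the
  crypt-detection defaults are operational choices exposed in config;
  only the ≥85% MDF rule and the measurement formulas are fixed
  definitions.
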