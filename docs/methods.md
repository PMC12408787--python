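# Methods

This note documents the models behind `hcbfquant`: what each component
assumes, which parameters matter, what the synthetic data does and
does not emulate, and the numerical choices that were genuinely open.

## Imaging model

High-contrast brightfield (HCBF) imaging exploits defocusing: a
transparent cell refracts light like a lens, so a plane below focus
shows it as a bright spot over the background. A stronger defocus
suppresses single-cell contrast and highlights the large fused
myotubes as bright ridges. The package does not model this optics; it
models its *appearance*. The renderer draws

- cells as isotropic Gaussian spots, FWHM equal to the nominal spot
  diameter (default uniform in 20–32 µm), amplitude 12 000 counts;
- myotubes as ridges with a Gaussian cross-section (FWHM = width,
  uniform 15–40 µm; polyline length 150–1500 µm), amplitude 3000;
- nuclei (fluorescence channel) as 12 µm FWHM spots of amplitude
  20 000 over a near-zero (200-count) background;

on a background of 8000 counts with a quadratic radial vignette
(strength 0.05), a bright Gaussian meniscus ring near the well rim
(peak 12 000 at 0.88 of the well radius, σ = 60 µm), Poisson shot
noise and Gaussian read noise (σ = 100), clipped and quantized to
16-bit. Cross-channel bleed mirrors the two-defocus design: myotubes
render at 30 % of their amplitude on the cell channel, single cells at
25 % of theirs on the myotube channel, which is why isolated cells are
visible but sub-threshold-or-sub-size on each other's channel.

The amplitudes are set so that the standard recipe thresholds
(3000 / 1000 / 4000 counts) sit well above residual noise and well
below the post-preprocessing object peaks. The box smoothing of the
recipes costs small spots roughly half their peak height; an amplitude
much below ~10 000 would push the smallest cells under the 3000-count
threshold, so the spot amplitude is deliberately generous relative to
the ridge amplitude.

**Ground-truth footprints.** Each object's "true" area is the area
inside a stated iso-intensity contour of its own noiseless rendering:
3000 counts for cell spots, 1000 counts for myotube ridges — the same
levels the default recipes threshold at. This makes truth areas and
measured areas refer to the same contour, so area comparisons test the
pipeline rather than an arbitrary footprint convention. Myotube truth
is rasterized at render resolution and stored on the scene; an
analytic rounded-rectangle approximation is also available and agrees
with the rasterization to a few percent.

## Quantification pipeline

One parametrised recipe covers all three analyses:

1. **Rolling-ball background subtraction** (radius 20 µm): the
   background is the envelope traced by a ball rolled under the image;
   structures narrower than the ball footprint (spots, ridges) survive
   subtraction, slow gradients and plateaus are removed exactly. A
   radius below one pixel raises, pointing at the resolution.
2. **Mean-filter smoothing**: the integer smoothing setting is a box
   radius in pixels *at the 1.6 µm/px reference scale* (setting 10 =
   21×21 px at 1.6 µm/px); at other resolutions the radius is rescaled
   so smoothing has a fixed physical width. `smooth()` itself is
   defined purely in pixels (setting 0 = identity; an impulse of
   height h becomes h/(2s+1)²).
3. **Background floor**: where a recipe evaluates the lowest p % of
   ROI pixels, the floor is their mean; otherwise the floor is zero,
   because rolling-ball subtraction has already flattened the
   baseline. The signal threshold is counts above that floor — this is
   what makes the numeric thresholds transferable across plates with
   different background levels.
4. **Labeling**: 8-connected components; with split-touching enabled,
   a marker-based watershed on the Euclidean distance transform (EDT).
5. **Size filter**: objects kept when the equivalent circular diameter
   2·√(area/π) lies inside the recipe band. Equivalent diameter — not
   major-axis length — is the package's single largest interpretive
   choice; it is what keeps a 110 µm floor meaningful for thick
   elongated ridges.

A frame whose foreground covers ≥99 % of the ROI is flagged
`confluent/unreliable` instead of raising; label-free counting is
documented to degrade only at full confluence.

**Split-touching markers.** Markers are h-maxima of the preprocessed
intensity image inside the foreground (suppression depth 100 counts),
complemented by h-maxima of the EDT (depth 1 px) for lobes whose
intensity peaks have fused; intensity markers take precedence. Both
surfaces get a light Gaussian first (σ = 1.5 px, or 2.5 px for recipes
without their own smoothing step) because ragged outlines and pixel
noise otherwise shed spurious maxima. Markers closer than half the
minimum object size — never less than 3 px, since one object's
intensity and EDT maxima can sit a couple of pixels apart — are
merged, the stronger winning, ties broken by scan order. Intensity
markers matter: EDT maxima alone recover touching *pairs* but miss
cells inside chains and clumps, where each cell still keeps its own
brightness peak; on dense wells the intensity+EDT scheme roughly
halves the undercount of the EDT-only scheme. Foreground that ends up
with no marker at all is kept as plain connected components, so
splitting can never lose objects.

## Plate geometry

Plate formats carry the circular growth-area diameter (5934 µm for
96-well, 3369 µm for 384-well; chosen so the published analytical
areas follow exactly), default edge exclusions (1 ring for 96-well,
2 for 384-well → 60 and 240 analyzable wells), and an empirically
calibrated meniscus lookup: (volume, usable-fraction) anchors with
piecewise-linear interpolation, clamped outside the anchor range and
monotone in volume. The meniscus is measured, not modeled — the
anchors ship as defaults (96-well: 47 % at 150 µL; 384-well: 60 % at
50 µL, 80 % at 70 µL) and are user-replaceable.

The stated 96-well plugin ROI (circle, 4700 µm ⇒ 1.73·10⁷ µm²) is
*larger* than the stated 47 % analytical area (1.3·10⁷ µm²). Both
numbers are exposed as given; neither is silently corrected. For
384-well work the package defaults to a 2500 µm ROI, which sits inside
the 70 µL analytical area with margin to the rendered meniscus ring;
there is no published 384-well plugin size. ROI offsets (plate
displacement) are user-supplied configuration; no estimator is
provided.

**Montage arithmetic.** A tile grid covers a target extent when
`fov·(1+(n−1)·(1−overlap)) ≥ extent` per axis, with the smallest such
n. With a 904×1024 px camera crop, 10 % overlap, and 1.6 / 0.65 µm/px
for the 4× / 10× objectives, full-well coverage of a 96-well takes
5×4 = 20 and 12×10 = 120 tiles — a 6× imaging-time and file-size cost
for the 10× objective. The pixel pitches and the crop are reverse-fit
to those grids (no sensor spec is published) and are ordinary config
values; note that a landscape 1224×904 crop cannot yield both grids
for a square target at any single overlap, which is why the crop here
is portrait.

## Live-assay growth model

The simulator is phenomenological, with surface occupancy as the
shared currency. `K` is the carrying capacity in *cell-equivalents*;
myotube area divided by the mean per-cell footprint (≈1080 µm² for the
default spot range) converts area into the same units.

- **Growth**: exact logistic steps (not Euler) after a lag, with
  effective capacity `K − area/footprint − lost`, so cells can only
  grow into surface not already covered by myotubes.
- **Differentiation**: fusion switches on when occupancy reaches
  `diff_onset_density_fraction · K` and off only if occupancy falls
  below 70 % of that trigger (hysteresis). While active, cells convert
  to myotube area at `fusion_rate` — the count falls as the area
  rises, which is exactly the onset signature the kinetics module
  detects. Fused footprint accumulates and is materialized as myotube
  polylines whose analytic footprint matches the consumed
  cell-equivalents (conservation holds to within a few percent;
  tested at 10 %).
- **Detachment**: once the area has plateaued (relative growth <1 %
  per interval *and* area ≥80 % of its historical peak — a reformation
  wave must rebuild before it can detach again), events fire with
  per-interval probability 1−exp(−hazard·Δt). An event removes whole
  tubes until `detachment_drop_fraction` of the area is gone. With
  `reformation`, the freed surface re-enters the growth/fusion loop
  and produces a second area wave of similar height; without it, the
  lost capacity stays unavailable and the area trace is one-peaked.

Defaults (96-well-like): n₀ = 1000, r = 0.06 h⁻¹, K = 12 000,
lag 12 h, onset at 0.85 K, fusion 0.05 h⁻¹, hazard 0.02 h⁻¹, drop 0.5,
4 h read interval, 216 h duration. These produce onset near day 3–4,
plateau area ≈ 2.4·10⁷ µm², and detachment timing that varies strongly
between replicate seeds — the replicate-to-replicate variance that
makes detachment statistics hard in real assays. `two_wave_params()`
is the canonical forced-early-detachment scenario: one detachment
event, two area peaks of similar height, assay ending at the rebuilt
maximum.

The clonal screen (`simulate_clonal_screen`) seeds Poisson(λ) founders
per analyzable well and runs the same state equations per well
(default λ = 0.85, K = 8000, r = 0.065 h⁻¹ with optional log-normal
clone-to-clone rate variation, lag 24 h, no detachment on the 8-day
timescale). Fast homogeneous clones make every occupied well
cell-positive, so the cell-positive fraction estimates 1−e^(−λ);
heterogeneous rates reproduce the day-7→day-8 jump in myo-positive
wells as slower clones cross the density trigger between reads.

## Kinetic feature extraction

All features operate on median-filtered (window 3) series — robust to
single-frame segmentation glitches without shifting event timing by
more than one interval. Replicate aggregation reports mean, SD and
SEM = SD/√n per timepoint (live-assay ribbons conventionally use SEM);
n = 1 timepoints carry NaN spread and a flag. Missing values are
linearly interpolated for feature extraction and flagged in output.

Event thresholds are operational defaults for features that are
conventionally identified by eye, and are all keyword-exposed:
plateau = pre-maximum slope below 2 % of the maximum per interval over
three intervals; onset = count ≥10 % below its running maximum
sustained two intervals *and* area above 5 % of its eventual maximum;
detachment = area ≥25 % below the running peak sustained two
intervals, with the peak resetting after each event; peaks = local
maxima (boundary maxima included; a constant series has none) with
prominence ≥20 % of the global maximum.

The logistic fit is four-parameter (n₀, r, K, lag) least squares with
multiple starts — n₀ and lag trade off in noisy data and a single
start can settle in a degenerate minimum — keeping the best residual.
With `relative_sigma` set it is weighted least squares with per-point
σ proportional to the value (floored at one count), the correct
weighting when the measurement error scales with the count. Under
per-measurement noise at SNR 20 the fit recovers r and K within 5 %.

## Clonal screen statistics

`poisson_occupancy` evaluates the exact pmf with the tail by
complement, so the classes and tail sum to 1 to machine precision. At
λ = 0.85: 42.74 % empty, 36.33 % one cell, 15.44 % two, 4.37 % three,
1.12 % four or more (the exact tail; note it rounds to ~1 %, not
below). Empirical plates from `seed_clonal_plate` pass a chi-square
goodness-of-fit against this model (pooled tail bins, α = 0.01,
10 000 wells).

Calls: myo-positive ⇔ area ≥ 60 000 µm²; cell-positive ⇔ count ≥ 120
*or* myo-positive — a fully fused well has few countable cells left
but must stay in the cell-positive denominator, because the
myo-positive percentage is reported out of cell-positive wells. (The
area threshold is sixty thousand µm², written 60.000 µm² in European
decimal notation; misreading it as 60 would break every call.) In
screening mode both analyses run on the same extra-defocused frame;
counts made on that channel carry a `reduced_precision` flag.

## Validation analytics

`compare_methods` pools paired measurements across a density ladder:
Pearson r, least-squares slope/intercept, R² of the fit, per-density
signed relative bias with a flag beyond 10 %, and exclusion of
densities whose replicates carry the confluent flag. On the synthetic
ladder (six densities, 50–1600 cells/well, four replicates, hard-core
placement) the standard counting recipe achieves r ≈ 0.998–0.999
against ground truth with near-zero bias at low density and a
10–15 % undercount at the top density — the expected "slight
underestimate" regime of label-free counting.

## What the synthetic data does not capture

Real defocus spots are not Gaussian (they have diffraction rings and
asymmetries); real myotubes branch, taper and overlap; cells migrate
between reads; plates carry manufacturer-specific plastic artefacts;
illumination drifts over days; the meniscus distorts geometry
(defocus) rather than adding a clean bright ring. Passing tests
therefore demonstrate that the *pipeline* implements its contracts
and tracks a known truth under realistic noise — not that the specific
thresholds are optimal for any particular real instrument, plate or
cell line, which is why every recipe parameter is configuration.

## Problem sizes and determinism

Default synthetic resolution is 3.2 µm/px (384-well frames 1056²,
96-well 1856²); the test suite uses 64²–1056² frames and truth-level
kinetic series, and the linearity study uses the full six-density ×
four-replicate ladder at default resolution. All randomness flows from
explicit integer seeds through spawned numpy generators; identical
seed and configuration reproduce bit-identical frames and
byte-identical result CSVs.
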