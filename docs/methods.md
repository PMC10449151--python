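# Methods

`retimorph` implements an automated retinal vasculometry pipeline — image
quality gating, unsupervised vessel segmentation, vessel width measurement,
arteriole/venule (A/V) classification and optic disc localisation — together
with the evaluation statistics used to validate such pipelines against human
annotations.  Because no annotated image set ships with the package, every
stage is exercised against a synthetic fundus generator that knows its own
ground truth exactly.  This note records the models, the defaults and why,
and what the synthetic evaluation does and does not establish.

## Synthetic fundus images

`synthetic.generate_retina` renders a macular-centred, fundus-like scene:
a vignetted background (base intensity 0.62 on a [0, 1] scale), a bright
flat-topped optic disc (the brightest structure), a dark Gaussian fovea, and
a vascular tree grown from the disc edge by recursive bifurcation (four
arcades, two arteriolar and two venular; child width = parent × 0.8, floored
at 2 px; default root width 18 px at 512×512, scaling linearly with image
size).  Arteriolar and venular trees share identical geometry statistics so
the two classes differ in rendered intensity only, not calibre.

The vessel cross-section at distance `d` from the centreline is a
baseline-subtracted Gaussian trough with scale `s = width/2`:

    offset(d) = -A · (exp(-d²/2s²) - e⁻²) / (1 - e⁻²)   for |d| ≤ 2s, else 0

The subtraction leaves the second derivative unchanged inside the support, so
the zero-crossings of the profile's second derivative sit exactly at `d = ±s`
and the edge-to-edge width equals the nominal width — a closed-form oracle
for the width module.  Trough depth `A` is 0.36 for venules and 0.25 for
arterioles (venules appear darker); pixel noise is Gaussian with SD 0.01.

Three profile regimes mirror the strata used in width-validation studies:
*normal*; *central reflex*, which adds a bright axial ridge (amplitude
0.35·A, scale s/4 for arterioles and s/6 for venules — the reflex is wider
in arterioles); and *low contrast*, which scales `A` by 0.45 and adds an
illumination ramp.  Quality degradations are applied last: extreme blur
(σ = height/32) and ≥60%-area occlusions define the *inadequate* class;
uneven illumination leaves an image adequate.  The inadequate prevalence in
generated cohorts defaults to 17.4%, matching the class balance of the
manually labelled 1,000-image set that real quality gates were trained on.

Rendering rasterises centreline samples on a 2× supersampled grid and
assigns each pixel the profile of its nearest sample via a Euclidean
distance transform (quantisation ≤ 0.25 px).  The ground-truth mask is
`d ≤ width/2`; ground-truth widths are the rasterisation parameters
themselves, never re-measured.

**What the generator does not emulate:** pathology (drusen, haemorrhages),
texture of the nerve fibre layer, true optics (PSF, chromatic effects),
vessel tapering within a segment, and the intensity statistics of any real
camera.  Passing tests therefore demonstrate internal consistency of the
algorithms under controlled conditions, not clinical performance.

## Vessel segmentation

A multi-scale line detector scores each pixel as
`mean(window) − mean(best oriented line)`, maximised over 12 orientations
and line lengths {5, 9, 15} px within a 15×15 surround, clipped at zero.
Being a difference of local means, the response — and the segmentation — is
invariant to adding a constant to the image.  Pre-processing replaces pixels
above the 95th intensity percentile with a masked-blur background estimate so
the disc and specular highlights cannot masquerade as lines.

Hysteresis thresholds are the 90th/96th percentiles of the response, floored
at absolute contrasts 0.012/0.020.  The floors matter: pure percentile
thresholds always keep a fixed share of pixels, so a blurred image would
still yield a full-sized (garbage) vessel map and quality features would
carry no signal.  With floors, degraded images collapse toward empty maps,
as a practitioner would expect.  The binary map is the morphological
reconstruction of the low mask from high-mask seeds (8-connectivity).
Post-processing removes objects under 64 px² and a fovea exclusion disc
(radius 0.10 × image height; the fovea is located as the darkest large-scale
minimum of the central third when not supplied).

At the defaults, pooled over 20 default synthetic retinas, pixel sensitivity
is ≈0.77 with specificity ≈0.975 (post-processing on); switching
post-processing on never adds false positives and trades sensitivity for
specificity, the direction reported for real pipelines.

## Image quality

Three global shape features of the unpost-processed vessel map: **area**
(vessel fraction), **fragmentation** (8-connected components per vessel
pixel) and **complexity** (skeleton pixels per vessel pixel); an empty map is
(0, 0, 0) by convention.  Fragmentation and complexity are per-pixel ratios
and hence resolution-dependent, so quality scoring always runs at a fixed
working resolution (long side 256 px) — a trained gate then transfers across
capture sizes.

The classifier is an RBF-kernel SVM on standardised features, with C and γ
selected over a logarithmic grid by seeded stratified 5-fold CV.  Its
decision value is min-max rescaled over the training set and squashed through
a logistic to give `p(inadequate) ∈ [0, 1]`; the quality score is
`1 − p(inadequate)` (1 = highest quality) and an image is *inadequate* when
score ≤ 0.48 (boundary inclusive).  The model serialises to JSON (support
vectors, dual coefficients, intercept, γ, scaler and normalisation constants)
and predictions always go through the stored arrays, so save/load round-trips
are bit-exact.  On a 500-train/500-test synthetic split the gate separates
the classes essentially perfectly — the synthetic degradations are cruder
than real-world quality loss, so this is an upper bound, not a claim about
real images.

## Vessel widths

Centrelines are the skeleton of the mask (small holes ≤16 px filled first;
residual 2×2 skeleton blocks removed by a connectivity-preserving pass),
partitioned into segments at junction pixels (≥3 skeleton neighbours).
Orientation at a point is the principal direction of the chain within ±5
points.  The intensity profile is sampled along the perpendicular (bilinear
interpolation, 0.25 px steps), smoothed with a Gaussian, and each edge is the
second-derivative zero-crossing nearest the vessel interior, localised by
linear interpolation; the width is the distance between the two edges.

Two numerical choices matter:

* **Smoothing correction.** Gaussian smoothing at scale σₛ moves the
  zero-crossing of a Gaussian-trough edge from h to √(h² + σₛ²); each
  half-width is corrected back as √(h² − σₛ²).  This keeps the closed-form
  oracle exact (2σ ± 0.25 px for σ = 2…10 at 8 orientations).
* **Calibre-adaptive scales.** Wide vessels have weak edge curvature relative
  to noise, so σₛ = 0.3 × (local half-width from the mask distance
  transform), clipped to [1, 3.5] px — the correction makes larger smoothing
  harmless.  The edge search range per site is likewise bounded at
  2.2 × local half-width + 2 px so a profile cannot latch onto a parallel or
  crossing vessel.

On central-reflex profiles the search on each side starts at the side's
darkest sample (the trough bottom), which lies beyond the reflex whenever one
is present, so the reflex's internal zero-crossings are never returned.
Plausibility filters reject widths over 30 px, half-width asymmetry over
1.8:1, and sites inside 1.2 × the optic-disc radius; rejected measurements
are kept with a reason code.  Measurements are taken every 2nd centreline
point, skipping 5 points at each segment end.

Across six synthetic retinas spanning the three regimes (~1,600–1,900 paired
profiles), ground truth minus measured width has |mean| well under 1 px with
SD ≈ 1.7–2.0 px — the same scale as published human-vs-automated agreement —
with the central-reflex stratum biased toward over-measurement and the
low-contrast stratum noisiest, echoing the published stratum pattern.
Agreement is summarised by Bland–Altman statistics (sample SD with n−1;
limits at mean ± 1.96 SD; undefined metrics reported as NaN, never 0 or 1).

## Arteriole/venule classification

Human graders separate A from V by colour (venules darker), central reflex
(stronger in arterioles) and calibre, judged *relative to adjacent vessels*.
The feature backend encodes exactly that per centreline pixel: trough depth
below a vessel-free background field (a masked Gaussian blur excluding
dilated vessel pixels, so neighbours cannot corrupt the reference), reflex
strength relative to depth, and local calibre from the mask distance
transform — with depth and calibre normalised by their per-image medians,
making the features invariant to per-image contrast and brightness.  A
logistic model on standardised features yields p(arteriole); pixels with no
vessel-like trough get exactly 0.5 (uninformative).  Segment probability is
the mean over its pixels; labels are strict (`A` iff p > t, `V` iff
1 − p > t, ties unclassified), so the retention fraction is 1 at t = 0.5 and
non-increasing in t.  On held-out synthetic retinas the backend reaches
≈0.90–0.92 segment accuracy at t = 0.5 (≈0.99 per pixel), with accuracy
rising and retention falling along the 0.5…0.9 threshold sweep.  Swapping
the A/V rendering intensities inverts predictions almost exactly, confirming
the features respond to the intended cues rather than geometry.  A 6-layer
CNN backend is a recognised alternative at this task; it is not shipped, and
`backend="cnn"` raises.

## Optic disc

Shade correction subtracts a Gaussian background at 0.25 × min(image dims);
the disc is the argmax of the corrected image smoothed at (disc radius)/4,
searched over the image minus a 5% border margin and a fovea-zone exclusion
disc (radius 0.15 × height around the image centre for macular-centred
images; no left/right prior, since the disc side depends on the eye).  The
radius estimate is 0.08 × image height.  Detection (predicted centre inside
the true disc) succeeds on 100/100 seeded synthetic images, including ones
with illumination ramps.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use desk-scale cohorts chosen to
exercise each protocol at the designs known from validation practice: a
500/500 quality split at 256×256, 20 retinas for segmentation, six retinas
(two per regime) for width agreement, six training and six test images for
A/V, and 100 images for disc detection.  All randomness flows from explicit
seeds; for a fixed seed the generator is bit-reproducible and a full
pipeline run produces byte-identical CSV outputs across invocations.

## Known limitations

* All quantitative guarantees are under the generator's conditions; real
  fundus images have harder illumination, pathology and optics.
* The segmentation thresholds (percentiles + floors) assume vessel-like
  contrast on a [0, 1] scale; other modalities need reconfiguration.
* Width measurement assumes trough-like cross-sections; strongly saturated
  or occluded vessels fall back on the plausibility filters.
* The A/V backend relies on within-image contrast between classes; images
  containing a single vessel class would be classified at chance.
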