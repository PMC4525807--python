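# Methods

## Problem and scope

Macroscopic algal aggregates (centimetres to tens of centimetres; rounded
pennate-diatom flocs and filamentous *Melosira arctica* strings) float up
against the underside of Arctic sea ice.  Their abundance, spatial pattern
and biomass can be surveyed with an upward-looking camera on an ROV flying a
metre or so below the ice.  This package implements the full processing
chain from raw frames to station-level statistics — threshold detection,
metric registration, floe-scale gridding, six areal-biovolume estimators,
Lloyd's patchiness and power-law size spectra — together with a synthetic
survey generator that supplies frames with exact ground truth, since no raw
under-ice survey video is publicly archived.

## Detection model

Aggregates are dark against the bright backlit ice, so a pixel is classified
as aggregate when its green-channel value lies in [0, 100] of 255 (both
bounds inclusive; configurable).  Frames are first cropped to a centred
250 x 200 px window of the native 384 x 288 px raster to discard vignetted
edges and the camera overlay; the crop position is configurable because only
the output size is fixed by the workflow.  Connected components
(8-connectivity by default) become regions; per-region pixel area,
boundary-step perimeter, and second-moment ellipse axes/orientation are
measured with scikit-image.

Frame QC discards frames deeper than 5 m or tilted beyond 10 degrees
(strict inequalities: boundary values are kept), plus an optional manual
blocklist.  Regions of more than 10 px get full shape parameters
("measurable"); smaller regions still count toward abundance and coverage.

### Clump flagging

Close-lying aggregates occasionally merge into one region.  Manual frame
review is not reproducible, so an automated surrogate flags a measurable
region when

* its solidity (area / convex-hull area) is below 0.85 **and** the region
  has at least 50 px — single aggregates are near-convex ellipses while a
  merged pair is visibly waisted; below ~50 px discretisation alone makes
  thin ellipses ragged, and a merged pair of measurable aggregates is
  necessarily larger; or
* its log10 area exceeds the per-frame median by more than 10 scaled MADs —
  a deliberately loose cut, because genuine aggregate sizes are heavy-tailed
  (power-law spectrum) and a linear-scale outlier rule would flag the
  physically real tail that carries most of the biovolume.

Flagged regions are excluded from shape/size statistics but retained for
abundance and coverage.  On the reference scenario this flags under 1 % of
measurable regions.

## Metric registration

The camera is a pinhole with one laboratory constant k = 4.5 mm px^-1 m^-1:
at altimeter distance D the scale is k·D (4.5 mm/px at 1 m, matching a
4-5 mm ground-sample distance).  Areas scale with the square, lengths
linearly.  Tilt below the QC cut is not corrected; it contributes to the
<15 % size-uncertainty budget, which the tests verify across standoffs of
0.5-2 m.  Ice draft is vehicle depth minus altimeter distance, clipped at
zero (with a counter) because sensor noise can invert the difference.

Shape descriptors: ECD d = 2 sqrt(A/pi); eccentricity
sqrt(1 - (minor/major)^2); circularity 4 pi A / P^2 (may exceed 1 by a few
percent for small regions — a perimeter-discretisation artefact, left
unclipped).  Frame footprint uses the cropped extent (only cropped pixels
are analysed); abundance = regions per footprint, coverage = aggregate
pixel fraction.

## Gridding

Survey tracks overlap, so frame summaries are averaged onto a floe-fixed
3 x 3 m raster (the positioning uncertainty).  Cell indices are
floor((pos - origin)/3) with half-open cells; the origin defaults to the
minimum observed position and is stored with the output.  Cell values are
arithmetic means over frames — duplicating all frames of a cell changes
nothing, which is the point — except diameter statistics, which pool the
individual measurable aggregates of the cell.  Cells without frames are
absent, not zero.  Roughness is reported as the windowed (3 x 3 cells)
standard deviation of cell mean drafts; this is a surrogate definition and
is labelled as such.

## Biovolume estimators

Each aggregate is treated as a compact sphere of its ECD,
V = a · (4/3) pi (d/2)^3 in ml m^-2 (d in cm, a in m^-2).  Because V is
cubic in d, the choice of summary statistics dominates the answer; six
conventions are implemented (aggregate_list, global_mean, global_median,
gridded_mean, gridded_median, raster_cells — see the `biomass` module
docstring for definitions).  Choices that the definitions leave open, fixed
here: "global" diameter statistics are taken over the pooled detection
list; gridded statistics average per-cell values (the per-cell median for
gridded_median, the per-cell mean within raster_cells); the aggregate_list
survey area is the plain sum of valid-frame footprints without overlap
deduplication — overlap inflates it by construction, which is that
estimator's documented caveat.  Diameters entering any estimator are ECDs
of measurable, non-clump-flagged regions; abundance counts every detection
(detect-only regions have no shape, so this split is forced).

Under a heavy-tailed size law the estimators *should* disagree:
median(d)^3 can sit an order of magnitude below mean(d^3).  The tests
verify both directions — agreement within 10 % on a homogeneous
narrow-size field, and the expected spread on power-law fields.

Carbon = V x 0.39 mg C ml^-1 (390 mg C per litre of aggregate, a field
calibration from samples of known volume).  Report tables round one decimal,
half away from zero.

## Spatial statistics

**Lloyd's patchiness.**  From per-cell counts (cell mean abundance x cell
area, rounded to integers, occupied cells only): mean crowding
m* = m + (s^2/m - 1) and P = m*/m.  The default uses the sample variance
(ddof = 1, Lloyd's variance-estimate form); with ddof = 0 the expression is
algebraically identical to the literal per-individual "mean number of
neighbours in my cell", which the tests exploit as a brute-force oracle.
P ~ 1 for Poisson scatter, > 1 for clustering.

**Size spectra.**  f(d) = c d^b fitted by least squares on
log10(number density) vs log10(d) over non-empty logarithmically spaced
bins (16 by default), number density being counts normalised by bin width
and sample size.  With log-spaced bins the exact bin-averaged densities of
a power law lie exactly on a line of slope b, so the fit is unbiased up to
sampling noise; recovery at n = 5000 is within +-0.2 in practice.  Fits
with R^2 < 0.8 are flagged.  Two fits are reported: from the smallest
reliable ECD (3x pixel pitch at the median standoff) and restricted to
d >= 2 cm.  Caveat: if the fit window starts below the true lower support
of the distribution, the partially filled bottom bins bias the slope
shallow — on the reference scenario (support starting at 2 cm) the
restricted fit is the faithful one.  A truncated-Pareto MLE mode exists for
sensitivity analysis.

**Type fractions.**  Station mean eccentricity is mapped linearly between
the survey-wide extremes, which coincide with purely rounded and purely
filamentous stations.  The default "anchored" convention puts
f_elong = (eps - eps_min)/(eps_max - eps_min) so that high eccentricity
means elongated; the mirror-image "literal" convention (labels swapped, as
some reports print the formula) is provided because the printed assignment
contradicts its own anchoring — both are exposed, no intent is guessed.

**Correlations.**  Pearson r with two-sided p per requested station-level
variable pair, pairwise-complete, no multiplicity correction.

## Synthetic data generator

The generator defines the study conditions; its defaults are the shipped
reference scenario (`configs/reference_scenario.yaml`):

* **Scene**: 80 x 80 m floe on a 0.5 m raster; draft = 1.0 m mean + a
  Gaussian random field (sd 0.3 m, correlation length 10 m) + 2 straight
  ridge keels (Gaussian cross-section, 3 m amplitude, 4 m width), clipped
  at zero; roughness = 5-cell windowed std; transmittance = exp(-1.5 z).
* **Aggregates**: expected density 3 m^-2 (survey-typical); ECDs from a
  truncated power law b = -3 on [2, 30] cm (the canonical marine-particle
  slope; 2 cm keeps everything measurable at 1 m standoff); positions from
  a Thomas process (parents 0.05 m^-2, offspring displacement sd 2 m,
  offspring mean fixed by the total density), offspring wrapped onto the
  scene torus so counts are exact; 20 % filamentous (eccentricity drawn
  from [0.93, 0.995] — filaments are rendered as thin ellipses, true
  curvilinear strings are out of scope), 80 % rounded (eccentricity
  [0.55, 0.85]).  Optional draft affinity accepts a proposed position at
  draft z with probability exp(-affinity (z - z_min)), redrawing on
  rejection (count-preserving); it emulates trapping in draft minima
  qualitatively and is off by default because it is a stand-in, not an
  inference target.
* **Survey**: lawnmower track, 10 m line spacing, 0.5 m s^-1, one frame
  per 5 s, 1 m standoff.  The altimeter reads the true standoff; the depth
  sensor reads draft + standoff + N(0, 0.05 m); recorded positions get
  N(0, 1 m) per axis; tilt records are |N(0, 3 deg)|.
* **Rendering**: background green 190 +- a lateral ramp of 25 plus
  N(0, 6) pixel noise; aggregate pixels at green 40.  Clean by
  construction: every background pixel stays far above 100 and every
  aggregate pixel far below.  Red and blue are affine in green (the
  detector reads only green).

What the generator does **not** emulate — and hence what green tests do not
show about real data: texture inside aggregates and ice, air bubbles and
small-scale ice structures (the real false-positive sources), brightness
transitions between ice types (the real cause of the field campaign's ~54 %
manual frame rejection), motion blur, lens distortion, curvilinear
filaments, and attached (as opposed to free-floating) aggregates.  The
adversarial rendering mode (gradient pushing a corner of the background
below the threshold) probes the first failure class only.

## Determinism and numerics

Every run funnels randomness through `numpy.random.default_rng` seeded from
one integer; sub-seeds are drawn once at the top.  Fixed seed implies
byte-identical artifacts (tested).  Degenerate inputs reject loudly:
inverted threshold bounds, non-positive extents/distances, d_min >= d_max,
fewer than 20 diameters or fewer than 3 non-empty bins for a slope fit,
zero mean count for patchiness, zero initial biovolume for a change
estimate.

## Problem sizes

The shipped reference scenario (80 x 80 m, ~250 frames, ~900 detections)
is sized so that a full pipeline run takes a few seconds and the complete
test suite with its Monte-Carlo checks stays around half a minute; the
statistical tolerances used in the tests were chosen for those sizes
(e.g. slope +-0.3 at n = 5000, Lloyd's P within 5 % of 1 at 10^4 Poisson
cells).

## Known limitations

* The green-channel threshold is a global constant; no adaptive
  backlighting correction is attempted (mirroring the transparent original
  workflow, and its failure modes).
* Abundance counts regions intersecting the crop, which overcounts point
  density by the edge-intersection (Minkowski) term, ~+15 % at reference
  sizes; the validation compares against the instance density actually in
  view.  Coverage is unaffected.
* Median-based biovolume estimators are not consistent estimators of true
  mean volume under heavy-tailed sizes — by design; they trade bias for
  robustness to the (real) misdetection of large clumps.
* Station-level type fractions need cross-station eccentricity extremes and
  are therefore not part of a single-station report.
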