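# underice

Quantification of algal aggregates under Arctic sea ice from upward-looking
ROV imagery — and a synthetic survey generator with exact ground truth for
validating every stage of the chain.

## Who this is for

Sea-ice ecologists and image-analysis practitioners who need to turn
upward-looking under-ice camera surveys into station-level numbers:
aggregate abundance (m⁻²), percent cover, areal biovolume and carbon,
spatial patchiness, and size spectra.  Macroscopic aggregates (rounded
pennate-diatom flocs, filamentous *Melosira arctica* strings, > 1 cm) float
up against the ice underside; because they are dark against the bright
backlit ice they can be segmented with a simple green-channel threshold —
but turning 2-D detections into biomass involves consequential choices that
this package makes explicit and comparable.

## The method in brief

1. **Detection** — crop each 384 × 288 frame to an undisturbed 250 × 200
   window, classify pixels with green value in [0, 100] (of 255) as
   aggregate, label connected regions, and measure pixel area, perimeter
   and fitted-ellipse axes.  Frames deeper than 5 m or tilted beyond 10°
   are discarded; regions over 10 px get full shape parameters; probable
   merge artefacts ("clumps") are flagged out of the shape statistics.
2. **Metric registration** — a pinhole camera with one constant
   *k* = 4.5 mm px⁻¹ m⁻¹ converts pixels to metres at the altimeter
   standoff; ECD d = 2√(A/π), eccentricity √(1 − (minor/major)²),
   circularity 4πA/P².  Ice draft = depth − altimeter distance.
3. **Gridding** — frame summaries are averaged onto a floe-fixed 3 × 3 m
   raster so overlapping track segments are not double-counted.
4. **Biovolume** — every aggregate is a sphere of its ECD:

   V = a · (4/3)π(d/2)³  [ml m⁻²],  carbon = 0.39 mg C ml⁻¹ · V.

   Six estimator variants (aggregate_list, global_mean, global_median,
   gridded_mean, gridded_median, raster_cells) differ only in how the
   abundance *a* and diameter *d* are summarised — and can disagree by an
   order of magnitude on patchy, heavy-tailed fields, which is the point of
   computing all of them.
5. **Spatial statistics** — Lloyd's mean crowding m* = m + (s²/m − 1) and
   index of patchiness P = m*/m on gridded counts (P ≈ 1 random, > 1
   clustered); power-law size spectra f(d) = c·dᵇ fitted on log-spaced
   bins (slope b ≈ −3 is typical of marine particle fields); aggregate-type
   fractions from a linear map of mean eccentricity.

Because no raw under-ice survey video is publicly archived, the
`synthetic` module generates the whole observable world — ice draft field
with ridge keels, Thomas-clustered aggregates with truncated power-law
sizes, a noisy ROV survey, and rendered frames — with every rendered
aggregate linked to its ground-truth record, so recall, precision and size
bias are measurable exactly.  See `docs/methods.md` for the full model
description and `docs/data_dictionary.md` for output columns and units.

## Worked example

Run the shipped reference scenario (80 × 80 m floe, ~3 aggregates m⁻²,
power-law sizes with b = −3 on 2–30 cm, lawnmower survey at 1 m standoff):

```sh
underice run-all --config configs/reference_scenario.yaml --out out --seed 1
```

prints (abridged):

```json
{
  "n_frames_valid": 252,
  "n_detections": 883,
  "abundance": 3.4607093866353127,
  "coverage_pct": 0.5302222222222222,
  "V_gridded_median": 59.51709551380457,
  "C_gridded_median": 23.211667250383783,
  "V_raster_cells": 140.9060377696414,
  "lloyd_P": 1.6337494797736303,
  "slope_gt2cm": -2.9012580675422845,
  "recall": 0.9933333333333333,
  "precision": 1.0,
  "size_bias": 0.006071216728829313
}
```

Reading it: 252 frames survive QC and yield 883 detections, i.e. 3.46
aggregates m⁻² covering 0.53 % of the ice — the detector finds 99.3 % of
the resolvable ground-truth aggregates with no false positives and a 0.6 %
mean size bias.  The restricted spectrum slope (Ø > 2 cm) recovers the
generating −3 within 0.1.  Note the estimator spread: the gridded-median
biovolume (59.5 ml m⁻²) is less than half the raster-cells value (140.9)
on the same detections, because the size distribution is heavy-tailed —
exactly the behaviour that motivates comparing all six.  `out/` holds the
per-frame, per-detection and per-cell CSVs, the QC report and the resolved
config.

Other entry points: `underice simulate` (frames + nav + ground truth to
disk), `underice detect` (process an existing frame directory),
`underice compare` (two surveys of one floe → per-method biovolume-loss
table).  Everything is also callable as a library; `RunConfig` +
`run_pipeline` reproduce any run from one seed.

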