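# Data dictionary

Units convention: frame footprints and region areas m²; aggregate lengths
(ECD, axes) cm; biovolume ml m⁻² (1 ml = 1 cm³); carbon mg C m⁻²; draft and
roughness m; coverage a fraction (percent only where a column says `pct`).

## nav.csv (written by `simulate`, read by `detect`)

| column | unit | meaning |
|---|---|---|
| frame_id | – | integer key, matches `frame_<id>.png` |
| t_s | s | capture time from survey start |
| depth_m | m | vehicle depth (sensor reading, noisy) |
| tilt_deg | ° | vehicle tilt magnitude |
| altimeter_m | m | acoustic distance to the ice underside (standoff) |
| x_m, y_m | m | recorded floe-fixed position (noisy) |

## detections.csv

| column | unit | meaning |
|---|---|---|
| frame_id, region_id | – | keys |
| pixel_area | px | connected-region area in the crop |
| centroid_row, centroid_col | px | region centroid in cropped raster |
| area_m2 | m² | metric area at the frame's pixel scale |
| ecd | cm | equivalent circular diameter 2√(area/π) |
| perimeter_m | m | boundary-step perimeter |
| major_cm, minor_cm | cm | fitted-ellipse full axes |
| eccentricity | – | √(1 − (minor/major)²); empty if no ellipse fit |
| circularity | – | 4π·area/perimeter² (can slightly exceed 1) |
| measurable | bool | area > 10 px and ellipse fit available |
| clump_flag | bool | excluded from shape/size statistics |

## frames.csv (one row per valid frame)

| column | unit | meaning |
|---|---|---|
| frame_id | – | key |
| x, y | m | recorded position |
| n_aggregates | – | detections in the frame (all sizes) |
| footprint | m² | metric extent of the analysis crop |
| abundance | m⁻² | n_aggregates / footprint |
| coverage | fraction | aggregate pixel area / footprint |
| mean_ecd, median_ecd | cm | measurable, non-flagged regions |
| mean_eccentricity | – | ditto |
| draft | m | depth − altimeter, clipped at 0 |
| i, j | – | 3 m grid-cell indices (j along x, i along y) |

## grid.csv (one row per occupied 3 × 3 m cell)

| column | unit | meaning |
|---|---|---|
| i, j | – | cell indices; `x_center`, `y_center` in m |
| n_frames | – | frames averaged into the cell |
| abundance, coverage | m⁻², fraction | means over frames |
| mean_ecd, median_ecd | cm | pooled over the cell's aggregates |
| mean_eccentricity | – | mean over frames |
| draft | m | mean over frames |
| roughness | m | windowed std of neighbouring cell drafts (surrogate) |
| transmittance | – | scene transmittance at the cell centre (synthetic runs) |

## ground_truth.csv (synthetic runs)

One row per rendered aggregate instance: `frame_id`, `agg_id`, pixel centre
(`row_px`, `col_px` in native raster), projected `radius_px`, rendered
`n_pixels`, true `diameter_cm`, `eccentricity`, `type_label`, and the
crop-visibility flags `in_crop` / `fully_in_crop`.

## report.json

`full_precision` and `rounded` (one decimal, half away from zero) blocks of
the station summary: frame/detection counts, abundance, coverage_pct,
`V_<method>` / `C_<method>` for the six estimators, `lloyd_P`, `slope`
(fit from 3× pixel pitch) and `slope_gt2cm` (fit restricted to Ø > 2 cm),
plus `recall` / `precision` / `size_bias` when ground truth is available.
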