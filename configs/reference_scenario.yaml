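# Reference synthetic survey scenario: one 80 x 80 m floe, clustered
# aggregate field at the survey-typical density of ~3 aggregates per m^2,
# power-law sizes with slope -3 between 2 and 30 cm, lawnmower track at
# 0.5 m/s with one frame every 5 s from 1 m standoff, clean rendering
# (aggregates well inside the 0-100 green band, background well above it).
# Used by the validation harness and the acceptance script.
seed: 0
calib:
  k: 4.5            # mm per pixel per metre of standoff
cell_size: 3.0      # m, floe-fixed grid
carbon_density: 0.39   # mg C per ml of aggregate volume
restricted_fit_d_min: 2.0   # cm, "large aggregate" slope fit bound
detection:
  green_lo: 0
  green_hi: 100
  crop_width: 250
  crop_height: 200
  connectivity: 8
  max_depth: 5.0    # m, strict >
  max_tilt: 10.0    # deg, strict >
  min_shape_pixels: 10
  solidity_min: 0.85
  size_outlier_k: 10.0
  min_solidity_area: 50
simulation:
  extent: [80.0, 80.0]
  intensity: 3.0    # aggregates m^-2, expected
  filamentous_fraction: 0.2
  draft_affinity: 0.0
  scene:
    cell_size: 0.5
    mean_draft: 1.0
    draft_std: 0.3
    correlation_length: 10.0
    n_ridges: 2
    ridge_amplitude: 3.0
    ridge_width: 4.0
  size_law:
    b: -3.0
    d_min: 2.0      # cm
    d_max: 30.0
  clustering:
    parent_intensity: 0.05   # clusters m^-2
    cluster_sd: 2.0          # m
  survey:
    track_type: lawnmower
    speed: 0.5               # m s^-1
    frame_interval: 5.0      # s
    nominal_standoff: 1.0    # m
    depth_noise: 0.05        # m
    tilt_noise: 3.0          # deg
    position_noise_sd: 1.0   # m
    line_spacing: 10.0       # m
  rendering:
    background_green_mean: 190.0
    gradient_amp: 25.0
    noise_sd: 6.0
    aggregate_green: 40.0
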