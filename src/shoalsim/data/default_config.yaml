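# Default shoalsim configuration.
# Units: cm, seconds, degrees (angles in files); radians are internal only.
ages:
  7:  {arena_diameter_cm: 6.5,  fish_length_cm: 0.4, fish_height_cm: 0.2,  bout_rate_hz: 1.65, bout_size_cm: 0.1}
  14: {arena_diameter_cm: 9.2,  fish_length_cm: 0.5, fish_height_cm: 0.25, bout_rate_hz: 1.4,  bout_size_cm: 0.12}
  21: {arena_diameter_cm: 12.6, fish_length_cm: 0.8, fish_height_cm: 0.4,  bout_rate_hz: 1.4,  bout_size_cm: 0.16}
simulation:
  dt_s: 0.02
  duration_s: 600.0
  n_agents: 5
  n_repetitions: 50
  bout_duration_s: 0.32
  start_fraction: 0.9
  turn_sigma_deg: 30.0
  speed_profile: triangular
retina:
  eye_separation_cm: 0.12
  eye_radius_cm: 0.045
  eye_height_cm: 0.5
  effective_field_deg: 163.0
  vergence_deg: 36.0
  ray_span_deg: 165.0
  n_rays: 1000
responses:
  vr_curves:
    7:  [[0, 0.5], [6, 0.5], [60, 0.75]]
    14: [[0, 0.5], [6, 0.4], [11, 0.5], [60, 0.75]]
    21: [[0, 0.5], [25, 0.35], [52, 0.5], [90, 0.7]]
  wall:
    p_max: 0.8
    chance_distance_bl: 3.0
    engage_distance_bl: 2.0
  group_delta_curves:
    7:  {style: monotone, peak_delta_deg: 30.0, peak_p: 0.65, return_to_chance_deg: 90.0}
    14: {style: peaked,   peak_delta_deg: 30.0, peak_p: 0.65, return_to_chance_deg: 90.0}
    21: {style: peaked,   peak_delta_deg: 30.0, peak_p: 0.65, return_to_chance_deg: 90.0}
analysis:
  bin_width_deg: 5.0
  wall_bin_width_bl: 1.0
  wall_exclusion_bl: 3.0
  ci_method: clopper-pearson
  log_base: e
  n_shuffles: 1000
  nn_stride: 5
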