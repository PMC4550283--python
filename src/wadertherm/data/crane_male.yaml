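# Adult male whooping crane.  Torso feather depths follow the female's
# measurements (the male's own reading was unusable).
name: crane_male
mass_kg: 6.15
fat_fraction: 0.10
density_target_kg_m3: 633.3
physiology:
  bmr_w: 13.7
  core_temp_c: 40.7
  core_temp_max_c: 44.0
  core_temp_min_c: 37.7
  flesh_conductivity_w_mk: 0.5
  flesh_conductivity_min_w_mk: 0.4
  flesh_conductivity_max_w_mk: 2.5
  activity_heat_fraction: 0.8
  o2_extraction_max_pct: 31.0
  o2_extraction_min_pct: 2.10
  skin_wetness_fraction: 0.002
  config_factor_sky: 0.5
  config_factor_ground: 0.3
counter_current:
  dt_min_c: 1.0
  floor_c: 3.0
parts:
  torso:
    shape: ellipsoid
    semi_axes_m: [0.293, 0.108, 0.098]
    feather:
      diameter_um: 18.75
      density_per_cm2: 14400
      length_mm: {dorsal: 61.0, ventral: 55.0}
      depth_mm: {dorsal: 10.0, ventral: 15.0}
      reflectivity: 0.62
  neck:
    shape: elliptical_cylinder
    semi_axes_m: [0.0415, 0.0415]
    length_m: 0.297
    feather:
      diameter_um: 18.75
      density_per_cm2: 14400
      length_mm: {dorsal: 22.0, ventral: 26.0}
      depth_mm: {dorsal: 10.0, ventral: 9.0}
      reflectivity: 0.62
  head:
    shape: truncated_cone
    proximal_semi_axes_m: [0.034, 0.034]
    distal_semi_axes_m: [0.0175, 0.0175]
    length_m: 0.106
    feather:
      diameter_um: 18.75
      density_per_cm2: 14400
      length_mm: {dorsal: 22.0, ventral: 26.0}
      depth_mm: {dorsal: 18.0, ventral: 4.0}
      reflectivity: 0.62
  beak:
    shape: truncated_cone
    proximal_semi_axes_m: [0.0175, 0.0175]
    distal_semi_axes_m: [0.0025, 0.0025]
    length_m: 0.134
    reflectivity: 0.33
    counter_current: true
  left_leg:
    shape: elliptical_cylinder
    semi_axes_m: [0.0085, 0.0065]
    length_m: 0.359
    reflectivity: 0.33
    counter_current: true
  right_leg:
    shape: elliptical_cylinder
    semi_axes_m: [0.0085, 0.0065]
    length_m: 0.359
    reflectivity: 0.33
    counter_current: true
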