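# Adult female whooping crane: morphometry, plumage and physiology.
# Flesh dimensions are as measured (photogrammetry / tape); the loader
# rescales them to the whole-body flesh density target.
name: crane_female
mass_kg: 5.05
fat_fraction: 0.10
density_target_kg_m3: 633.3
physiology:
  bmr_w: 11.9
  core_temp_c: 40.7
  core_temp_max_c: 44.0
  core_temp_min_c: 37.7
  flesh_conductivity_w_mk: 0.5
  flesh_conductivity_min_w_mk: 0.4
  flesh_conductivity_max_w_mk: 2.5
  activity_heat_fraction: 0.8
  o2_extraction_max_pct: 31.0
  o2_extraction_min_pct: 2.12
  skin_wetness_fraction: 0.002
  config_factor_sky: 0.5
  config_factor_ground: 0.3
counter_current:
  dt_min_c: 1.0
  floor_c: 3.0
parts:
  torso:
    shape: ellipsoid
    semi_axes_m: [0.2725, 0.120, 0.100]
    feather:
      diameter_um: 18.75
      density_per_cm2: 14400
      length_mm: {dorsal: 60.0, ventral: 60.0}
      depth_mm: {dorsal: 10.0, ventral: 15.0}
      reflectivity: 0.62
  neck:
    shape: elliptical_cylinder
    semi_axes_m: [0.0415, 0.0415]
    length_m: 0.315
    feather:
      diameter_um: 18.75
      density_per_cm2: 14400
      length_mm: {dorsal: 25.0, ventral: 24.0}
      depth_mm: {dorsal: 10.0, ventral: 10.0}
      reflectivity: 0.62
  head:
    shape: truncated_cone
    proximal_semi_axes_m: [0.035, 0.035]
    distal_semi_axes_m: [0.017, 0.017]
    length_m: 0.103
    feather:
      diameter_um: 18.75
      density_per_cm2: 14400
      length_mm: {dorsal: 25.0, ventral: 24.0}
      depth_mm: {dorsal: 10.0, ventral: 2.0}
      reflectivity: 0.62
  beak:
    shape: truncated_cone
    proximal_semi_axes_m: [0.017, 0.017]
    distal_semi_axes_m: [0.0025, 0.0025]
    length_m: 0.114
    reflectivity: 0.33
    counter_current: true
  left_leg:
    shape: elliptical_cylinder
    semi_axes_m: [0.0085, 0.0065]
    length_m: 0.375
    reflectivity: 0.33
    counter_current: true
  right_leg:
    shape: elliptical_cylinder
    semi_axes_m: [0.0085, 0.0065]
    length_m: 0.375
    reflectivity: 0.33
    counter_current: true
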