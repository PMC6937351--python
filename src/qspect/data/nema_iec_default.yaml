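body:
  semi_axes_mm:
  - 150.0
  - 110.0
  length_mm: 186.0
background_kbq_cm3: 11.0
total_fill_volume_cm3: 9650.0
spheres:
- inner_diameter_mm: 10.0
  center_mm:
  - 28.60000000000001
  - -49.53665309646989
  - 0.0
  fill_volume_cm3: 0.5
  concentration_kbq_cm3: 35.4
- inner_diameter_mm: 13.0
  center_mm:
  - -28.600000000000026
  - -49.53665309646988
  - 0.0
  fill_volume_cm3: 1.0
  concentration_kbq_cm3: 35.4
- inner_diameter_mm: 17.0
  center_mm:
  - -57.2
  - 7.0049796911228604e-15
  - 0.0
  fill_volume_cm3: 2.8
  concentration_kbq_cm3: 35.4
- inner_diameter_mm: 22.0
  center_mm:
  - -28.599999999999987
  - 49.5366530964699
  - 0.0
  fill_volume_cm3: 5.8
  concentration_kbq_cm3: 35.4
- inner_diameter_mm: 28.0
  center_mm:
  - 28.60000000000001
  - 49.53665309646989
  - 0.0
  fill_volume_cm3: 11.7
  concentration_kbq_cm3: 35.4
- inner_diameter_mm: 37.0
  center_mm:
  - 57.2
  - 0.0
  - 0.0
  fill_volume_cm3: 29.0
  concentration_kbq_cm3: 35.4
lung_insert:
  outer_diameter_mm: 50.0
  length_mm: 186.0
  concentration_kbq_cm3: 0.0
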