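# GraSE protocol presets for breath-hold myocardial T2 mapping at 1.5 T.
# One document key per sequence variant. Times in ms, distances in mm.
9Ec:
  first_te: 23.6
  delta_te: 11.8
  n_echoes: 9
  n_startup: 1
  epi_factor: 7
  sense_factor: 2
  matrix_read: 176
  matrix_phase: 168
  voxel_size: 2.0
  slice_thickness: 10.0
  n_dummy: 1
  refocusing_profile: slr_optimized
6Ec:
  first_te: 23.6
  delta_te: 11.8
  n_echoes: 6
  n_startup: 1
  epi_factor: 7
  sense_factor: 2
  matrix_read: 176
  matrix_phase: 168
  voxel_size: 2.0
  slice_thickness: 10.0
  n_dummy: 1
  refocusing_profile: slr_optimized
6EcLR:
  first_te: 23.6
  delta_te: 11.8
  n_echoes: 6
  n_startup: 1
  epi_factor: 7
  sense_factor: 2
  matrix_read: 152
  matrix_phase: 138
  voxel_size: 2.3
  slice_thickness: 10.0
  n_dummy: 1
  refocusing_profile: slr_optimized
7Ec_no_se:
  first_te: 11.8
  delta_te: 11.8
  n_echoes: 7
  n_startup: 0
  epi_factor: 7
  sense_factor: 2
  matrix_read: 176
  matrix_phase: 168
  voxel_size: 2.0
  slice_thickness: 10.0
  n_dummy: 1
  refocusing_profile: slr_optimized
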