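# KO-male-like cortex window: few enlarged canals carry most of the pore
# volume; osteoid halos around pores emulate unmineralised matrix.
kind: cortex_phantom
outer_radius_um: 120.0
inner_radius_um: 71.0
length_slices: 300
voxel_size_um: 0.65
lacunae:
  count: 150
  log10_volume_mean: 2.40
  log10_volume_sd: 0.18
  min_volume_um3: 50.0
  max_volume_um3: 1500.0
  max_elongation: 2.5
canals:
  radius_um: [5.0, 8.0]
  length_um: [100.0, 180.0]
  max_tilt_deg: 12.0
  min_trim_length_um: 60.0
specks:
  size_voxels: 4
osteoid_halo:
  enabled: true
  thickness_um: 2.0
  intensity_fraction: 0.6
intensity:
  bone_mean: 180
  background_mean: 30
  noise_sigma: 5
  bit_depth: 8
target_composition: {lacuna_pct: 22.3, canal_pct: 76.1, noise_pct: 1.6}
seed: 13
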