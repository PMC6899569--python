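# WT-female-like cortex window: lacunae dominate the pore volume, canals minor.
kind: cortex_phantom
outer_radius_um: 120.0
inner_radius_um: 71.0
length_slices: 300
voxel_size_um: 0.65
lacunae:
  count: 280
  log10_volume_mean: 2.40
  log10_volume_sd: 0.18
  min_volume_um3: 50.0
  max_volume_um3: 1500.0
  max_elongation: 2.5
canals:
  radius_um: [3.5, 5.0]
  length_um: [90.0, 180.0]
  max_tilt_deg: 12.0
  min_trim_length_um: 60.0
specks:
  size_voxels: 4
osteoid_halo:
  enabled: false
intensity:
  bone_mean: 180
  background_mean: 30
  noise_sigma: 5
  bit_depth: 8
target_composition: {lacuna_pct: 75.8, canal_pct: 22.0, noise_pct: 2.2}
seed: 11
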