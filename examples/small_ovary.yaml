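volume_shape:
- 64
- 256
- 256
background_level: 40.0
seed: 11
blur: true
noise: true
overlap_tolerance_voxels: 0
imaging:
  voxel_spacing:
  - 16.0
  - 4.0
  - 4.0
  lateral_psf_fwhm: 6.0
  sheet_waist_thickness: 11.0
  sheet_edge_thickness: 60.0
  sheet_edge_distance: 3000.0
  photon_scale: 2.0
  read_noise_sd: 1.0
follicles:
- center:
  - 512
  - 512
  - 512
  semi_axes:
  - 250
  - 230
  - 220
  euler_z_deg: 29.999999999999996
  theca_thickness_base: 60
  theca_thickness_modulation: 0.1
  modulation_phase_deg: 40
  gap_width: 10
  granulosa_width: 18
  coc_diameter: 80
  coc_anchor_deg: 45
- center:
  - 300
  - 200
  - 200
  semi_axes:
  - 60
  - 58
  - 56
  euler_z_deg: 0.0
  theca_thickness_base: 25
  theca_thickness_modulation: 0.0
  modulation_phase_deg: 0.0
  gap_width: 8
  granulosa_width: 10
  coc_diameter: null
  coc_anchor_deg: 0.0
- center:
  - 750
  - 800
  - 300
  semi_axes:
  - 42
  - 41
  - 40
  euler_z_deg: 0.0
  theca_thickness_base: 45
  theca_thickness_modulation: 0.0
  modulation_phase_deg: 0.0
  gap_width: 0
  granulosa_width: 0
  coc_diameter: null
  coc_anchor_deg: 0.0
vessels:
- polyline:
  - - 30
    - 950
    - 100
  - - 500
    - 980
    - 130
  - - 990
    - 960
    - 90
  radius: 16
egg_nests:
- center:
  - 300
  - 850
  - 850
  count: 4
  member_diameter: 75
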