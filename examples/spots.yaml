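seed: 7
psf: {lateral_fwhm_nm: 274.0, axial_fwhm_nm: 680.0}
sample: {kind: flat_layer, n_emitters: 15, field_um: 8.0, brightness: 1000.0}
plan:
  n_frames: 300
  frame_shape: [176, 176]
  pixel_size_nm: 46.0
  z_positions_um: [0.0]
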