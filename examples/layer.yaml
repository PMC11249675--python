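seed: 42
psf: {lateral_fwhm_nm: 274.0, axial_fwhm_nm: 680.0}
sectioning: {a_per_um2: 0.666}
excitation: {mode: tf}
sample: {kind: flat_layer, n_emitters: 120, field_um: 2.9, brightness: 1000.0}
plan:
  n_frames: 300
  frame_shape: [64, 64]
  pixel_size_nm: 46.0
  z_positions_um: {start: -1.5, stop: 1.5, step: 0.05}
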