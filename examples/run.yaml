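# Desk-scale end-to-end run: 20 AD / 27 NC, 30-s recordings at 250 Hz,
# 64 magnetometers, 500 cortical vertices, 68 Desikan-Killiany regions.
seed: 1
output_dir: megspect_out
geometry:
  n_channels: 64
  n_vertices: 500
  n_regions: 68
cohort:
  n_ad: 20
  n_nc: 27
  sampling_rate_hz: 250.0
  duration_s: 30.0
preproc:
  artifact_threshold_t: 1.0e-11
  epoch_length_s: 2.0
inverse:
  snr: 3.0
  depth_exponent: 0.5
stats:
  alpha: 0.05
  test: welch
classifier:
  degree: 2
  n_folds: 6
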