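# Demo end-to-end run: all stages at small problem sizes.
seed: 1
output_dir: runs/demo
stages:
  cohort: true
  dnc: true
  photometry: true
  hplc: true
  histology: true
cohort:
  stages: [early, ultra_early]
dnc:
  state: challenged
photometry:
  frame_rate: 5.0
  duration: 900.0
  bleach_slope: 0.01
  transient_onset: 700.0
  transient_amplitude: 0.5
  transient_decay: 60.0
  noise_sd: 0.02
  fit_window_s: 600.0
  smoothing_s: 5.0
hplc:
  curve_slope: 120.0
  curve_noise_fraction: 0.02
  peak_width_s: 3.0
  noise_sd: 0.5
histology_image:
  shape: [256, 256]
  n_cells_control: 14
  n_cells_pd: 10
counting:
  background_radius: 60
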