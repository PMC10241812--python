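# Three interleaved hairs, planar geometry: the array is scanned linearly.
# Scan step is coarsened from the hardware's 20 um to keep runs desk-scale.
seed: 2
phantom:
  name: hairs
  params:
    seed: 2
geometry:
  n_sensors: 15
  mode: linear_scan
  scan_range_m: 8.0e-3
  scan_step_m: 400.0e-6
medium:
  sound_speed_m_per_s: 1500.0
simulation:
  fs_hz: 400.0e6
  duration_s: 10.0e-6
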