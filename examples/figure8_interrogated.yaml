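# Hot spot on a figure-of-eight trajectory, read out through the full
# comb interrogation chain (synthesis -> array -> demodulation -> dip fit).
seed: 3
phantom:
  name: figure8
geometry:
  n_sensors: 15
medium:
  sound_speed_m_per_s: 1500.0
simulation:
  fs_hz: 400.0e6
  duration_s: 7.0e-6
interrogation:
  enabled: true
array:
  n_rings: 15
  spacing_hz: 1.66e9
  q_factor: 6.0e5
comb:
  n_subcarriers: 1536
  dac_rate_hz: 60.0e9
  bandwidth_hz: 40.0e9
noise:
  receiver_noise_density: 4.9e-9
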