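# Moving polystyrene microsphere imaged by the static 15-element array.
seed: 1
phantom:
  name: microsphere
  params:
    speed_m_per_s: 4.8e-3
    start_m: [-0.5e-3, 1.2e-3]
    direction: [0.6, -1.0]
geometry:
  n_sensors: 15
  pitch_m: 400.0e-6
  standoff_m: 5.0e-3
medium:
  sound_speed_m_per_s: 1500.0
simulation:
  fs_hz: 400.0e6
  duration_s: 7.0e-6
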