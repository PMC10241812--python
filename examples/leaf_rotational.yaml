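# Leaf-vein skeleton on a rotation stage (full-view circular scan).
# Rotation step coarsened from 1 degree to 6 for desk-scale runs.
seed: 4
phantom:
  name: leaf
  params:
    seed: 4
    levels: 2
geometry:
  n_sensors: 15
  mode: rotational
  rotation_step_deg: 6.0
medium:
  sound_speed_m_per_s: 1500.0
simulation:
  fs_hz: 400.0e6
  duration_s: 9.0e-6
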