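"""Physical constants shared across the package."""

SPEED_OF_LIGHT_M_PER_S = 299_792_458.0
"""Vacuum speed of light, m/s. Used for all optical frequency <-> wavelength conversions."""

DEFAULT_WAVELENGTH_M = 1550e-9
"""Telecom C-band probe wavelength of the interrogation laser, m."""

DEFAULT_OPTICAL_CARRIER_HZ = SPEED_OF_LIGHT_M_PER_S / DEFAULT_WAVELENGTH_M
"""Absolute optical frequency of the comb centre at 1550 nm (~193.4 THz)."""
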