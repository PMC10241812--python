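"""Digital frequency comb synthesis (OFDM) and spectral unit conversions.

The interrogation comb is generated digitally: one OFDM frame of N samples at
the DAC rate carries N orthogonal subcarriers spaced by Δf = dac_rate / N.
Played periodically and imposed on the optical carrier by a carrier-suppressed
double-sideband modulator, it becomes a comb of optical tones at multiples of
Δf around the laser frequency.  At the defaults (60 GS/s, 1536 samples) the
tooth spacing is 39.0625 MHz and one frame lasts 25.6 ns.

Everything here works at complex baseband: bin k of the frame's DFT is the
tooth at optical offset k·Δf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import SPEED_OF_LIGHT_M_PER_S

__all__ = [
    "CombSpec",
    "CombWaveform",
    "synthesize_comb",
    "tooth_spacing",
    "hz_to_wavelength_span",
]

#: fixed seed for the default pseudo-random subcarrier phase schedule; phases
#: affect only the crest factor of the time-domain frame, never tooth powers.
DEFAULT_PHASE_SEED = 20230605


@dataclass
class CombSpec:
    """Definition of the digital comb.

    Parameters
    ----------
    n_subcarriers:
        OFDM sequence length N; also the number of DFT bins per frame.
    dac_rate_hz:
        DAC sampling rate.  Tooth spacing is ``dac_rate_hz / n_subcarriers``.
    bandwidth_hz:
        Occupied double-sideband analysis band, centred on the carrier; teeth
        are placed at every bin with |offset| <= bandwidth/2.
    phase_schedule:
        "newman" (deterministic quadratic phases, crest factor ~2, default),
        "random" (seeded pseudo-random) or "zero".
    carrier_suppressed:
        Zero the DC bin, modelling the modulator biased at its null point.
    """

    n_subcarriers: int = 1536
    dac_rate_hz: float = 60e9
    bandwidth_hz: float = 40e9
    phase_schedule: str = "newman"
    phase_seed: int = DEFAULT_PHASE_SEED
    carrier_suppressed: bool = True

    def __post_init__(self) -> None:
        if self.n_subcarriers < 1:
            raise ValueError("n_subcarriers must be >= 1")
        if self.dac_rate_hz <= 0:
            raise ValueError("dac_rate_hz must be positive")
        if not 0 < self.bandwidth_hz <= self.dac_rate_hz:
            raise ValueError(
                "bandwidth_hz must be positive and no larger than dac_rate_hz "
                "(double sideband occupies the DAC band)"
            )
        if self.phase_schedule not in ("random", "newman", "zero"):
            raise ValueError(f"unknown phase_schedule {self.phase_schedule!r}")

    @property
    def tooth_spacing_hz(self) -> float:
        return self.dac_rate_hz / self.n_subcarriers

    @property
    def frame_duration_s(self) -> float:
        """Duration of one OFDM frame = 1 / tooth spacing (25.6 ns at defaults)."""
        return self.n_subcarriers / self.dac_rate_hz

    def bin_indices(self) -> np.ndarray:
        """Signed DFT bin indices of the frame, -N/2 .. N/2-1 in FFT order."""
        n = self.n_subcarriers
        k = np.fft.fftfreq(n, d=1.0 / n)
        return np.round(k).astype(int)

    def occupied_bins(self) -> np.ndarray:
        """Boolean mask (FFT order) of bins carrying a comb tooth."""
        k = self.bin_indices()
        half = self.bandwidth_hz / 2
        mask = np.abs(k) * self.tooth_spacing_hz <= half * (1 + 1e-12)
        if self.carrier_suppressed:
            mask &= k != 0
        return mask

    def tooth_offsets_hz(self) -> np.ndarray:
        """Optical frequency offsets of the occupied teeth, ascending, Hz."""
        k = self.bin_indices()[self.occupied_bins()]
        return np.sort(k) * self.tooth_spacing_hz

    def phases(self) -> np.ndarray:
        """Per-bin subcarrier phases (radians, FFT order)."""
        n = self.n_subcarriers
        if self.phase_schedule == "zero":
            return np.zeros(n)
        if self.phase_schedule == "newman":
            j = np.arange(n, dtype=float)
            return np.pi * (j - 1) ** 2 / n
        rng = np.random.default_rng(self.phase_seed)
        return rng.uniform(0, 2 * np.pi, size=n)


@dataclass
class CombWaveform:
    """One synthesized OFDM frame of complex baseband samples."""

    samples: np.ndarray
    spec: CombSpec

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.shape != (self.spec.n_subcarriers,):
            raise ValueError("frame length must equal n_subcarriers")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("samples must be finite")

    def tooth_values(self) -> np.ndarray:
        """Complex DFT bin values of the frame (FFT order)."""
        return np.fft.fft(self.samples)

    def tooth_power_fractions(self) -> np.ndarray:
        """Per-bin power as a fraction of the total frame power (FFT order)."""
        p = np.abs(self.tooth_values()) ** 2
        return p / p.sum()

    def crest_factor(self) -> float:
        """Peak-to-average power ratio of |samples|."""
        pwr = np.abs(self.samples) ** 2
        return float(pwr.max() / pwr.mean())


def synthesize_comb(spec: CombSpec) -> CombWaveform:
    """Build one comb frame by inverse DFT of unit-magnitude subcarriers.

    Occupied bins get amplitude 1 and the spec's phase schedule; the DC bin is
    zeroed when the carrier is suppressed.  The frame is exactly periodic with
    period ``n_subcarriers / dac_rate_hz``, so the comb spectrum is supported
    only on multiples of the tooth spacing.
    """
    mask = spec.occupied_bins()
    x = np.zeros(spec.n_subcarriers, dtype=complex)
    x[mask] = np.exp(1j * spec.phases()[mask])
    samples = np.fft.ifft(x)
    return CombWaveform(samples=samples, spec=spec)


def tooth_spacing(spec: CombSpec) -> float:
    """Comb tooth spacing Δf = DAC rate / sequence length, Hz."""
    return spec.tooth_spacing_hz


def hz_to_wavelength_span(delta_f_hz: float, wavelength_m: float = 1550e-9) -> float:
    """Convert a frequency span to the equivalent wavelength span at a carrier.

    dλ = λ² Δf / c; e.g. 40 GHz ≈ 320 pm and 1.66 GHz ≈ 13.3 pm at 1550 nm.
    """
    if delta_f_hz < 0 or wavelength_m <= 0:
        raise ValueError("delta_f_hz must be >= 0 and wavelength_m > 0")
    return wavelength_m**2 * delta_f_hz / SPEED_OF_LIGHT_M_PER_S
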