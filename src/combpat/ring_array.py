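"""Micro-ring sensor array: Lorentzian transmission model and spectrum-capacity arithmetic.

A micro-ring resonator coupled to a bus waveguide imprints a narrow Lorentzian
dip on the transmitted optical spectrum.  Acoustic pressure shifts the resonance
through the elasto-optic effect, so tracking the dip position in time reads out
the ultrasound waveform.  An array of rings on one bus shows one dip per ring;
after photosensitive tuning the dips are ordered and equally spaced so that a
frequency comb can interrogate all of them at once.

All optical frequencies in this module are *offsets* from the comb centre (Hz)
unless a name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_OPTICAL_CARRIER_HZ

__all__ = [
    "RingResonance",
    "RingArraySpec",
    "CapacityError",
    "fwhm_from_q",
    "transmission_spectrum",
    "transmission_spectrum_frames",
    "assign_resonances",
    "max_rings_by_spacing",
    "sampling_points_in_fwhm",
]

#: default pressure-to-frequency transduction, Hz of resonance shift per Pa.
#: Not a measured device number: chosen as the package calibration point so that
#: the default receiver noise reproduces the parallel-mode noise-equivalent
#: pressure scale (tens of Pa over ~20 MHz).  Configurable everywhere.
DEFAULT_SENSITIVITY_HZ_PER_PA = 1.0e5

DEFAULT_DIP_DEPTH = 0.9
DEFAULT_Q_FACTOR = 6.0e5


class CapacityError(ValueError):
    """Requested ring count does not fit in the available optical band."""


@dataclass
class RingResonance:
    """One micro-ring modelled as a Lorentzian transmission dip.

    Parameters
    ----------
    center_offset_hz:
        Resonant-frequency offset from the comb centre, Hz.
    q_factor:
        Quality factor Q = absolute resonance frequency / FWHM.
    dip_depth:
        Fractional transmission drop at resonance, in (0, 1].
    sensitivity_hz_per_pa:
        Resonance shift per unit acoustic pressure, Hz/Pa.
    label:
        1-based index of the ring in its array.
    """

    center_offset_hz: float
    q_factor: float = DEFAULT_Q_FACTOR
    dip_depth: float = DEFAULT_DIP_DEPTH
    sensitivity_hz_per_pa: float = DEFAULT_SENSITIVITY_HZ_PER_PA
    label: int = 1

    def __post_init__(self) -> None:
        if not self.q_factor > 0:
            raise ValueError(f"q_factor must be positive, got {self.q_factor}")
        if not 0 < self.dip_depth <= 1:
            raise ValueError(f"dip_depth must be in (0, 1], got {self.dip_depth}")
        if not math.isfinite(self.sensitivity_hz_per_pa):
            raise ValueError("sensitivity_hz_per_pa must be finite")

    def fwhm_hz(self, optical_carrier_hz: float = DEFAULT_OPTICAL_CARRIER_HZ) -> float:
        """Full width at half maximum of the dip, Hz."""
        return fwhm_from_q(self.q_factor, optical_carrier_hz)


@dataclass
class RingArraySpec:
    """An ordered micro-ring array on one bus waveguide.

    Ring centre offsets must be strictly increasing with label order, as they
    are after the photosensitive frequency-tuning step.
    """

    rings: list[RingResonance]
    optical_carrier_hz: float = DEFAULT_OPTICAL_CARRIER_HZ
    spacing_hz: float = 1.66e9

    def __post_init__(self) -> None:
        if not self.rings:
            raise ValueError("array needs at least one ring")
        offsets = [r.center_offset_hz for r in self.rings]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("ring centre offsets must be strictly increasing")
        if not self.optical_carrier_hz > 0:
            raise ValueError("optical_carrier_hz must be positive")

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def center_offsets_hz(self) -> np.ndarray:
        return np.array([r.center_offset_hz for r in self.rings])

    @property
    def occupied_span_hz(self) -> float:
        """Span between the first and last resonance (centre-to-centre)."""
        offs = self.center_offsets_hz
        return float(offs[-1] - offs[0])

    def fwhm_hz(self) -> np.ndarray:
        return np.array([r.fwhm_hz(self.optical_carrier_hz) for r in self.rings])

    def check_within_band(self, bandwidth_hz: float) -> None:
        """Raise if any resonance lies outside a band of the given width centred at 0."""
        half = bandwidth_hz / 2
        offs = self.center_offsets_hz
        if offs.min() < -half or offs.max() > half:
            raise ValueError(
                f"ring offsets [{offs.min():.3e}, {offs.max():.3e}] Hz exceed the "
                f"±{half:.3e} Hz analysis band"
            )


def fwhm_from_q(q_factor: float, optical_carrier_hz: float = DEFAULT_OPTICAL_CARRIER_HZ) -> float:
    """Resonance full width at half maximum, Hz.

    By definition of the quality factor, FWHM = f_carrier / Q.  At 1550 nm a Q
    of 5e5 gives ~387 MHz and 7e5 gives ~276 MHz.
    """
    if not (q_factor > 0 and optical_carrier_hz > 0):
        raise ValueError("q_factor and optical_carrier_hz must be positive")
    return optical_carrier_hz / q_factor


def _lorentzian_dip(freq_hz: np.ndarray, center_hz: float, hwhm_hz: float, depth: float) -> np.ndarray:
    x = (freq_hz - center_hz) / hwhm_hz
    return 1.0 - depth / (1.0 + x * x)


def transmission_spectrum(
    array: RingArraySpec,
    freq_grid_hz: np.ndarray,
    pressures_pa: np.ndarray | list[float] | None = None,
) -> np.ndarray:
    """Array transmission over a frequency-offset grid under per-ring pressures.

    Each ring contributes a Lorentzian dip centred at its tuned offset plus
    ``sensitivity * pressure``; independent rings on one bus combine
    multiplicatively.  Output values lie in (0, 1].

    Parameters
    ----------
    freq_grid_hz:
        Monotone grid of optical frequency offsets, Hz.
    pressures_pa:
        One pressure per ring (Pa).  ``None`` means the null case (all zero).
    """
    freq = np.asarray(freq_grid_hz, dtype=float)
    if freq.ndim != 1 or freq.size < 1:
        raise ValueError("freq_grid_hz must be a 1-D array")
    d = np.diff(freq)
    if d.size and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("freq_grid_hz must be monotone")
    if pressures_pa is None:
        pressures_pa = np.zeros(array.n_rings)
    p = np.asarray(pressures_pa, dtype=float)
    if p.shape != (array.n_rings,):
        raise ValueError(f"need one pressure per ring: expected {(array.n_rings,)}, got {p.shape}")
    t = np.ones_like(freq)
    for ring, pi in zip(array.rings, p):
        hwhm = ring.fwhm_hz(array.optical_carrier_hz) / 2
        center = ring.center_offset_hz + ring.sensitivity_hz_per_pa * pi
        t *= _lorentzian_dip(freq, center, hwhm, ring.dip_depth)
    return t


def transmission_spectrum_frames(
    array: RingArraySpec,
    freq_grid_hz: np.ndarray,
    pressures_frames_pa: np.ndarray,
) -> np.ndarray:
    """Vectorised ``transmission_spectrum`` over many frames.

    ``pressures_frames_pa`` has shape (n_frames, n_rings); the result has shape
    (n_frames, len(freq_grid_hz)).  Used by the interrogation loop, where the
    quasi-static approximation holds each frame's pressures constant.
    """
    freq = np.asarray(freq_grid_hz, dtype=float)[None, :]
    p = np.asarray(pressures_frames_pa, dtype=float)
    if p.ndim != 2 or p.shape[1] != array.n_rings:
        raise ValueError("pressures_frames_pa must have shape (n_frames, n_rings)")
    t = np.ones((p.shape[0], freq.shape[1]))
    for i, ring in enumerate(array.rings):
        hwhm = ring.fwhm_hz(array.optical_carrier_hz) / 2
        centers = ring.center_offset_hz + ring.sensitivity_hz_per_pa * p[:, i : i + 1]
        x = (freq - centers) / hwhm
        t *= 1.0 - ring.dip_depth / (1.0 + x * x)
    return t


def max_rings_by_spacing(bandwidth_hz: float, spacing_hz: float) -> int:
    """Maximum number of rings that fit in a band at a given spectral allocation.

    Each ring occupies one ``spacing_hz`` slot of the analysis band, so the
    capacity is floor(bandwidth / spacing): 24 rings for 1.66-GHz slots in a
    40-GHz comb, or 200 for 200-MHz slots.
    """
    if not (bandwidth_hz > 0 and spacing_hz > 0):
        raise ValueError("bandwidth_hz and spacing_hz must be positive")
    return int(math.floor(bandwidth_hz / spacing_hz + 1e-12))


def sampling_points_in_fwhm(fwhm_hz: float, tooth_spacing_hz: float) -> int:
    """Number of comb teeth falling inside one resonance FWHM.

    With a 39.0625-MHz comb and Q of 5e5-7e5 this is 7-10 points, enough to fit
    the Lorentzian dip and locate its minimum to a fraction of a tooth.
    """
    if not (fwhm_hz > 0 and tooth_spacing_hz > 0):
        raise ValueError("fwhm_hz and tooth_spacing_hz must be positive")
    return int(math.floor(fwhm_hz / tooth_spacing_hz + 1e-12))


def assign_resonances(
    n_rings: int,
    spacing_hz: float,
    band_hz: tuple[float, float],
    *,
    q_factor: float = DEFAULT_Q_FACTOR,
    dip_depth: float = DEFAULT_DIP_DEPTH,
    sensitivity_hz_per_pa: float = DEFAULT_SENSITIVITY_HZ_PER_PA,
    optical_carrier_hz: float = DEFAULT_OPTICAL_CARRIER_HZ,
    edge_margin_hz: float | None = None,
    start_offset_hz: float | None = None,
) -> RingArraySpec:
    """Place ``n_rings`` ordered, equally spaced resonances inside a band.

    Emulates the outcome of photosensitive frequency tuning: dips ordered by
    label, separated by ``spacing_hz``, symmetric about the band midpoint unless
    ``start_offset_hz`` pins the first ring explicitly.

    Each ring is budgeted one ``spacing_hz`` slot (consistent with
    :func:`max_rings_by_spacing`); ``edge_margin_hz`` (default: half a resonance
    FWHM per side, guarding the demodulation edge effect) is additionally
    reserved at both band edges.

    Raises
    ------
    CapacityError
        If the band cannot hold ``n_rings`` slots; the message names the
        maximum count that fits.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    if spacing_hz <= 0:
        raise ValueError("spacing_hz must be positive")
    lo, hi = float(band_hz[0]), float(band_hz[1])
    if hi <= lo:
        raise ValueError("band upper edge must exceed lower edge")
    if edge_margin_hz is None:
        edge_margin_hz = fwhm_from_q(q_factor, optical_carrier_hz) / 2
    usable = (hi - lo) - 2 * edge_margin_hz
    n_max = int(math.floor(usable / spacing_hz + 1e-12)) if usable > 0 else 0
    if n_rings > n_max:
        raise CapacityError(
            f"band of width {hi - lo:.4g} Hz (margin {edge_margin_hz:.4g} Hz/side) "
            f"holds at most {n_max} rings at {spacing_hz:.4g} Hz spacing; "
            f"requested {n_rings}"
        )
    if start_offset_hz is None:
        mid = (lo + hi) / 2
        first = mid - (n_rings - 1) * spacing_hz / 2
    else:
        first = float(start_offset_hz)
    offsets = first + spacing_hz * np.arange(n_rings)
    if offsets[0] < lo + edge_margin_hz - 1e-6 or offsets[-1] > hi - edge_margin_hz + 1e-6:
        raise CapacityError(
            f"resonances [{offsets[0]:.4g}, {offsets[-1]:.4g}] Hz fall outside the "
            f"usable band [{lo + edge_margin_hz:.4g}, {hi - edge_margin_hz:.4g}] Hz"
        )
    rings = [
        RingResonance(
            center_offset_hz=float(off),
            q_factor=q_factor,
            dip_depth=dip_depth,
            sensitivity_hz_per_pa=sensitivity_hz_per_pa,
            label=i + 1,
        )
        for i, off in enumerate(offsets)
    ]
    return RingArraySpec(rings=rings, optical_carrier_hz=optical_carrier_hz, spacing_hz=spacing_hz)
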