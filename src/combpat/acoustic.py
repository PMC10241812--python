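"""Synthetic photoacoustic forward model: phantoms, sensor response, propagation.

Generates per-sensor acoustic pressure records for point/line/disk absorbers in
a homogeneous medium.  Sources and sensors are coplanar (2-D imaging plane, the
array along +x), but propagation keeps the 3-D spherical 1/r spreading.  Each
source contributes a delayed bipolar pulse scaled by 1/r, weighted by the
sensor's frequency-dependent angular response, optionally attenuated with a
power law, and filtered by the sensor's band-pass receive kernel.

The synthesis runs in the frequency domain so that time-of-flight delays are
exact (no sample rounding) and the angular/attenuation filters are applied per
source-sensor pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.signal import windows

__all__ = [
    "AcousticMedium",
    "Absorber",
    "SourcePhantom",
    "SensorGeometry",
    "SensorResponse",
    "PressureRecordSet",
    "angular_weight",
    "simulate_pressure",
    "make_phantom_figure8",
    "make_phantom_microsphere",
    "make_phantom_hairs",
    "make_phantom_leaf",
    "linear_array_geometry",
]

_LN10 = math.log(10.0)


@dataclass
class AcousticMedium:
    """Homogeneous acoustic propagation medium (water-like by default)."""

    sound_speed_m_per_s: float = 1500.0
    attenuation_db_per_cm_mhz: float = 0.0
    attenuation_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.sound_speed_m_per_s <= 0:
            raise ValueError("sound_speed must be positive")
        if self.attenuation_db_per_cm_mhz < 0:
            raise ValueError("attenuation must be >= 0")

    def attenuation_amplitude(self, freq_hz: np.ndarray, distance_m: float) -> np.ndarray:
        """Amplitude attenuation factor over a path, power-law in frequency."""
        if self.attenuation_db_per_cm_mhz == 0:
            return np.ones_like(np.asarray(freq_hz, dtype=float))
        db = (
            self.attenuation_db_per_cm_mhz
            * (np.abs(freq_hz) / 1e6) ** self.attenuation_exponent
            * (distance_m * 100.0)
        )
        return 10.0 ** (-db / 20.0)


@dataclass
class Absorber:
    """One optical absorber acting as an acoustic point/disk source.

    ``amplitude_pa_m`` is the pressure at 1 m on-axis (Pa·m); ``radius_m = 0``
    means an ideal point whose temporal signature is a Gaussian derivative set
    by the excitation pulse width, radius > 0 adds the finite-size bipolar
    N-shape of a uniformly heated sphere.
    """

    position_m: tuple[float, float] = (0.0, 0.0)
    radius_m: float = 0.0
    amplitude_pa_m: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_m < 0:
            raise ValueError("radius must be >= 0")


@dataclass
class SourcePhantom:
    """A collection of absorbers, optionally carried along a trajectory.

    ``trajectory``, if given, maps time (s) to a 2-D displacement applied to
    every element — used for the moving hot-spot and microsphere experiments,
    where each laser shot sees a static snapshot of the phantom.
    """

    elements: list[Absorber]
    trajectory: Callable[[float], tuple[float, float]] | None = None
    name: str = "phantom"

    def positions_at(self, t_s: float = 0.0) -> np.ndarray:
        pos = np.array([e.position_m for e in self.elements], dtype=float)
        if pos.size == 0:
            return pos.reshape(0, 2)
        if self.trajectory is not None:
            pos = pos + np.asarray(self.trajectory(t_s), dtype=float)
        return pos

    def snapshot(self, t_s: float) -> "SourcePhantom":
        """Freeze the phantom at time ``t_s`` (trajectory baked into positions)."""
        pos = self.positions_at(t_s)
        els = [
            Absorber(position_m=tuple(p), radius_m=e.radius_m, amplitude_pa_m=e.amplitude_pa_m)
            for p, e in zip(pos, self.elements)
        ]
        return SourcePhantom(elements=els, trajectory=None, name=self.name)


@dataclass
class SensorGeometry:
    """Sensor positions and the acquisition schedule.

    mode:
        "static" — one acquisition with the array as placed;
        "linear_scan" — the whole array is shifted along +x by each entry of
        ``scan_offsets_m``;
        "rotational" — detector positions (and normals) are rotated about
        ``rotation_center_m`` by each entry of ``rotation_angles_deg``
        (equivalent, up to sign convention, to rotating the sample on a stage).
    """

    positions_m: np.ndarray
    mode: str = "static"
    rotation_angles_deg: np.ndarray | None = None
    scan_offsets_m: np.ndarray | None = None
    normal: tuple[float, float] = (0.0, 1.0)
    rotation_center_m: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.positions_m = np.atleast_2d(np.asarray(self.positions_m, dtype=float))
        if self.positions_m.shape[1] != 2:
            raise ValueError("positions_m must be (n_sensors, 2)")
        if len(np.unique(self.positions_m, axis=0)) != len(self.positions_m):
            raise ValueError("sensor positions must be distinct")
        if self.mode not in ("static", "linear_scan", "rotational"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "rotational":
            if self.rotation_angles_deg is None or len(self.rotation_angles_deg) == 0:
                raise ValueError("rotational mode needs a nonempty rotation_angles_deg")
            self.rotation_angles_deg = np.asarray(self.rotation_angles_deg, dtype=float)
        if self.mode == "linear_scan":
            if self.scan_offsets_m is None or len(self.scan_offsets_m) == 0:
                raise ValueError("linear_scan mode needs a nonempty scan_offsets_m")
            self.scan_offsets_m = np.asarray(self.scan_offsets_m, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = tuple(n / np.hypot(*n))

    @property
    def n_sensors(self) -> int:
        return len(self.positions_m)

    @property
    def n_steps(self) -> int:
        if self.mode == "rotational":
            return len(self.rotation_angles_deg)
        if self.mode == "linear_scan":
            return len(self.scan_offsets_m)
        return 1

    def step_positions(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        """Effective (positions, normals) at one acquisition step."""
        normals = np.tile(np.asarray(self.normal, dtype=float), (self.n_sensors, 1))
        if self.mode == "static":
            return self.positions_m.copy(), normals
        if self.mode == "linear_scan":
            off = np.array([self.scan_offsets_m[step], 0.0])
            return self.positions_m + off, normals
        ang = math.radians(self.rotation_angles_deg[step])
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        center = np.asarray(self.rotation_center_m, dtype=float)
        pos = (self.positions_m - center) @ rot.T + center
        return pos, normals @ rot.T


def linear_array_geometry(
    n_sensors: int = 15,
    pitch_m: float = 400e-6,
    standoff_m: float = 5e-3,
    mode: str = "static",
    **kwargs,
) -> SensorGeometry:
    """The default 15-element line array: 400-μm pitch along x at y = -standoff,
    looking toward +y (the sample sits near the origin)."""
    x = (np.arange(n_sensors) - (n_sensors - 1) / 2) * pitch_m
    pos = np.column_stack([x, np.full(n_sensors, -standoff_m)])
    return SensorGeometry(positions_m=pos, mode=mode, normal=(0.0, 1.0), **kwargs)


def _solve_band_shape(bw_3db_hz: float, bw_6db_hz: float) -> tuple[float, float]:
    """Parameters (f_peak, sigma) of the truncated-Gaussian receive band.

    The receive magnitude is modelled as exp(-(f - f_peak)^2 / (2 sigma^2))
    restricted to f >= 0 with f_peak <= 0, i.e. a smooth low-pass-like decay
    whose contiguous -3 dB and -6 dB widths match the configured values.
    Requires bw_6db >= sqrt(2) * bw_3db (otherwise the decaying shape cannot
    realise both widths).
    """
    f3, f6 = float(bw_3db_hz), float(bw_6db_hz)
    if not 0 < f3 <= f6:
        raise ValueError("need 0 < bw_3db <= bw_6db")
    if f6 < math.sqrt(2) * f3 * (1 - 1e-9):
        raise ValueError(
            "bw_6db must be at least sqrt(2) x bw_3db for the decaying band model"
        )
    l3 = (3.0 / 20.0) * _LN10
    f_peak = (f6**2 - 2 * f3**2) / (2 * (f6 - 2 * f3))
    sigma2 = (f3**2 - 2 * f_peak * f3) / (2 * l3)
    return f_peak, math.sqrt(sigma2)


@dataclass
class SensorResponse:
    """Frequency and angular response of one micro-ring ultrasound sensor.

    The receive band is a smooth decay whose contiguous −3 dB / −6 dB widths
    equal ``bw_3db_hz`` / ``bw_6db_hz`` (defaults 115 / 175 MHz).  The angular
    response is a spatial-aperture (sinc) model pinned to −3 dB at
    ``acceptance_half_angle_deg`` for ``acceptance_ref_freq_hz`` and narrowing
    with frequency; beyond the first null the gain is clamped to zero, making
    the pattern monotone nonincreasing in |angle|.
    """

    center_freq_hz: float = 60e6
    bw_6db_hz: float = 175e6
    bw_3db_hz: float = 115e6
    acceptance_half_angle_deg: float = 30.0
    acceptance_ref_freq_hz: float = 25e6

    def __post_init__(self) -> None:
        if not self.bw_3db_hz <= self.bw_6db_hz:
            raise ValueError("bw_3db must not exceed bw_6db")
        if not 0 < self.acceptance_half_angle_deg < 90:
            raise ValueError("acceptance half angle must be in (0, 90) deg")
        self._f_peak, self._sigma = _solve_band_shape(self.bw_3db_hz, self.bw_6db_hz)
        # sinc argument x0 with sin(x0)/x0 = 10^(-3/20), pins the -3 dB angle
        target = 10 ** (-3 / 20)
        x0 = brentq(lambda x: math.sin(x) / x - target, 1e-6, math.pi - 1e-9)
        self._aperture_coef = x0 / (
            self.acceptance_ref_freq_hz
            * math.sin(math.radians(self.acceptance_half_angle_deg))
        )

    def spectrum_magnitude(self, freq_hz: np.ndarray) -> np.ndarray:
        """Receive-band magnitude, normalised to 1 at its peak, for f >= 0."""
        f = np.asarray(freq_hz, dtype=float)
        m = np.exp(-((f - self._f_peak) ** 2 - self._f_peak**2) / (2 * self._sigma**2))
        return np.where(f >= 0, m, 0.0)

    def impulse_kernel(self, fs_hz: float, n_taps: int = 257) -> np.ndarray:
        """Unit-energy zero-phase FIR receive kernel sampled at ``fs_hz``."""
        if n_taps % 2 == 0:
            n_taps += 1
        freqs = np.fft.rfftfreq(n_taps, d=1.0 / fs_hz)
        h = np.fft.irfft(self.spectrum_magnitude(freqs), n_taps)
        h = np.fft.fftshift(h) * windows.tukey(n_taps, 0.25)
        return h / np.sqrt(np.sum(h**2))


def angular_weight(
    response: SensorResponse,
    angle_deg: np.ndarray | float,
    freq_hz: np.ndarray | float,
) -> np.ndarray | float:
    """Directional gain of the sensor at a given incidence angle and frequency.

    Gain is 1 on axis, exactly −3 dB at the configured acceptance half-angle
    for the reference frequency (25 MHz by default), and narrows as frequency
    grows — a diffraction-limited spatial aperture.
    """
    ang = np.radians(np.abs(np.asarray(angle_deg, dtype=float)))
    if np.any(ang >= math.pi / 2):
        raise ValueError("|angle| must be < 90 degrees")
    f = np.abs(np.asarray(freq_hz, dtype=float))
    x = response._aperture_coef * f * np.sin(ang)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(x > 0, np.sin(np.minimum(x, math.pi)) / np.where(x > 0, x, 1.0), 1.0)
    g = np.where(x >= math.pi, 0.0, g)
    if np.ndim(angle_deg) == 0 and np.ndim(freq_hz) == 0:
        return float(g)
    return g


@dataclass
class PressureRecordSet:
    """Per-sensor pressure vs time over an acquisition schedule.

    ``pressures_pa`` has shape (n_steps, n_sensors, n_samples) on the uniform
    grid ``times_s``.
    """

    times_s: np.ndarray
    pressures_pa: np.ndarray
    geometry: SensorGeometry
    medium: AcousticMedium
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.pressures_pa = np.asarray(self.pressures_pa, dtype=float)
        dt = np.diff(self.times_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("time grid must be uniform")
        expect = (self.geometry.n_steps, self.geometry.n_sensors, len(self.times_s))
        if self.pressures_pa.shape != expect:
            raise ValueError(
                f"pressures_pa shape {self.pressures_pa.shape} != (steps, sensors, samples) {expect}"
            )

    @property
    def fs_hz(self) -> float:
        return 1.0 / (self.times_s[1] - self.times_s[0])


def _source_spectrum(
    freq_hz: np.ndarray,
    radius_m: float,
    sound_speed: float,
    pulse_sigma_s: float,
) -> np.ndarray:
    """Analytic spectrum of the source temporal signature (unit peak scale).

    Point sources: Gaussian-derivative (bipolar) pulse, spectrum i·2πf·G(f).
    Finite spheres: the ideal N-wave of a uniformly heated sphere of radius R
    (duration 2R/v), smoothed by the excitation Gaussian.
    """
    f = np.asarray(freq_hz, dtype=float)
    w = 2 * np.pi * f
    gauss = np.exp(-0.5 * (w * pulse_sigma_s) ** 2)
    if radius_m <= 0:
        # normalise so the time-domain peak is ~1 for unit amplitude
        return 1j * w * gauss * (pulse_sigma_s * math.sqrt(math.e))
    big_t = radius_m / sound_speed
    wt = w * big_t
    with np.errstate(invalid="ignore", divide="ignore"):
        nspec = np.where(
            np.abs(wt) > 1e-6,
            (2j / big_t) * (np.sin(wt) / np.maximum(w, 1e-300) ** 2 - big_t * np.cos(wt) / np.maximum(w, 1e-300)),
            1j * w * big_t**2 * (2.0 / 3.0),
        )
    return nspec * gauss / big_t  # peak pressure of the N-wave is ~1 at t = ±T


def simulate_pressure(
    phantom: SourcePhantom,
    geometry: SensorGeometry,
    medium: AcousticMedium,
    response: SensorResponse | None,
    fs_hz: float = 500e6,
    duration_s: float = 8e-6,
    *,
    pulse_sigma_s: float = 1.1e-9,
    step_times_s: np.ndarray | None = None,
    include_angular: bool = True,
) -> PressureRecordSet:
    """Synthesize pressure records for a phantom over the acquisition schedule.

    Each absorber contributes a delayed bipolar pulse scaled by 1/r, weighted
    by the sensor's angular response at the source's incidence angle, filtered
    by the receive band (``response=None`` skips the band filter — ideal
    wideband hydrophone), with optional power-law attenuation.  Superposition
    over absorbers; sources whose first arrival falls outside the record window
    trigger a warning and are truncated.

    ``pulse_sigma_s`` is the Gaussian std of the excitation; defaults to the
    ns-scale pulse used for point-source characterization.
    ``step_times_s`` gives the wall-clock time of each acquisition step, used
    to sample a moving phantom's trajectory (default: all zero).
    """
    if response is not None:
        band_edge = response.bw_6db_hz
        if fs_hz < 2 * band_edge:
            raise ValueError(
                f"fs {fs_hz:.3g} Hz < 2x the sensor band edge {band_edge:.3g} Hz"
            )
    nt = int(round(fs_hz * duration_s))
    times = np.arange(nt) / fs_hz
    freqs = np.fft.rfftfreq(nt, d=1.0 / fs_hz)
    kernel = response.spectrum_magnitude(freqs) if response is not None else 1.0
    v = medium.sound_speed_m_per_s
    n_steps, n_sensors = geometry.n_steps, geometry.n_sensors
    if step_times_s is None:
        step_times_s = np.zeros(n_steps)
    out = np.zeros((n_steps, n_sensors, nt))
    warned = False
    radii = np.array([e.radius_m for e in phantom.elements])
    amps = np.array([e.amplitude_pa_m for e in phantom.elements])
    # one source spectrum per distinct radius (rasterized phantoms share one)
    src_spectra = {
        rad: _source_spectrum(freqs, rad, v, pulse_sigma_s) for rad in np.unique(radii)
    }
    spec_rows = np.stack([src_spectra[rad] for rad in radii]) if len(radii) else None
    for step in range(n_steps):
        positions, normals = geometry.step_positions(step)
        src = phantom.positions_at(float(step_times_s[step]))
        if len(src) == 0:
            continue
        for j in range(n_sensors):
            spos, nrm = positions[j], normals[j]
            dvec = src - spos  # (n_src, 2)
            r = np.hypot(dvec[:, 0], dvec[:, 1])
            keep = r > 0
            tof = np.where(keep, r / v, 0.0)
            if not warned and np.any(tof > duration_s):
                warnings.warn(
                    f"sources arriving after the {duration_s * 1e6:.2f}-us record "
                    "window are truncated",
                    stacklevel=2,
                )
                warned = True
            gain = np.where(keep, amps / np.where(keep, r, 1.0), 0.0)
            if include_angular and response is not None:
                cosang = (dvec @ nrm) / np.where(keep, r, 1.0)
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                front = ang < 90.0
                gain = np.where(front, gain, 0.0)
                w = angular_weight(response, np.clip(ang, 0, 89.999)[:, None], freqs[None, :])
            else:
                w = 1.0
            phase = np.exp(-2j * np.pi * tof[:, None] * freqs[None, :])
            term = gain[:, None] * spec_rows * phase * w
            if medium.attenuation_db_per_cm_mhz > 0:
                att = np.stack([medium.attenuation_amplitude(freqs, ri) for ri in r])
                term = term * att
            out[step, j] = np.fft.irfft(term.sum(axis=0) * kernel, nt)
    return PressureRecordSet(
        times_s=times,
        pressures_pa=out,
        geometry=geometry,
        medium=medium,
        metadata={"phantom": phantom.name, "fs_hz": fs_hz, "pulse_sigma_s": pulse_sigma_s},
    )


# ---------------------------------------------------------------------------
# Phantom factories.  Geometries are qualitative stand-ins for the imaging
# targets (hot spot on an '8' trajectory, flowing microsphere, crossed hairs,
# leaf-vein skeleton); deterministic for a given seed.
# ---------------------------------------------------------------------------


def make_phantom_figure8(
    width_m: float = 2e-3,
    height_m: float = 4e-3,
    period_s: float = 5e-3,
    center_m: tuple[float, float] = (0.0, 0.0),
    spot_radius_m: float = 50e-6,
    amplitude_pa_m: float = 1.0,
) -> SourcePhantom:
    """A hot spot sweeping a figure-of-eight (Gerono lemniscate) trajectory.

    Half a period later the spot sits on the opposite lobe (x unchanged,
    y negated).
    """
    cx, cy = center_m

    def trajectory(t: float) -> tuple[float, float]:
        th = 2 * math.pi * t / period_s
        return (cx + 0.5 * width_m * math.sin(2 * th), cy + 0.5 * height_m * math.sin(th))

    el = Absorber(position_m=(0.0, 0.0), radius_m=spot_radius_m, amplitude_pa_m=amplitude_pa_m)
    return SourcePhantom(elements=[el], trajectory=trajectory, name="figure8")


def make_phantom_microsphere(
    speed_m_per_s: float = 4.8e-3,
    start_m: tuple[float, float] = (0.0, 2e-3),
    direction: tuple[float, float] = (0.0, -1.0),
    radius_m: float = 100e-6,
    amplitude_pa_m: float = 1.0,
) -> SourcePhantom:
    """A 200-μm polystyrene microsphere drifting at constant speed (default
    4.8 mm/s, the flow speed in the tube experiment)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.hypot(*d)
    sx, sy = start_m

    def trajectory(t: float) -> tuple[float, float]:
        return (sx + speed_m_per_s * t * d[0], sy + speed_m_per_s * t * d[1])

    el = Absorber(position_m=(0.0, 0.0), radius_m=radius_m, amplitude_pa_m=amplitude_pa_m)
    return SourcePhantom(elements=[el], trajectory=trajectory, name="microsphere")


def _rasterize_segment(
    p0: np.ndarray, p1: np.ndarray, step_m: float, radius_m: float, amplitude: float
) -> list[Absorber]:
    length = float(np.hypot(*(p1 - p0)))
    n = max(2, int(round(length / step_m)) + 1)
    return [
        Absorber(position_m=tuple(p0 + (p1 - p0) * f), radius_m=radius_m, amplitude_pa_m=amplitude)
        for f in np.linspace(0, 1, n)
    ]


def make_phantom_hairs(
    seed: int = 0,
    n_hairs: int = 3,
    length_m: float = 6e-3,
    hair_radius_m: float = 25e-6,
    raster_step_m: float = 60e-6,
    amplitude_pa_m: float = 1.0,
) -> SourcePhantom:
    """Interleaved straight hairs crossing near the origin at distinct angles."""
    rng = np.random.default_rng(seed)
    base_angles = np.linspace(15, 165, n_hairs, endpoint=False)
    angles = base_angles + rng.uniform(-8, 8, n_hairs)
    centers = rng.uniform(-0.4e-3, 0.4e-3, size=(n_hairs, 2))
    elements: list[Absorber] = []
    for ang, c in zip(angles, centers):
        u = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
        elements += _rasterize_segment(
            c - u * length_m / 2, c + u * length_m / 2, raster_step_m, hair_radius_m, amplitude_pa_m
        )
    return SourcePhantom(elements=elements, name="hairs")


def make_phantom_leaf(
    seed: int = 0,
    trunk_length_m: float = 5e-3,
    levels: int = 3,
    branches_per_node: int = 2,
    raster_step_m: float = 80e-6,
    vein_radius_m: float = 20e-6,
    amplitude_pa_m: float = 1.0,
) -> SourcePhantom:
    """A branching vein skeleton: a trunk with recursively spawned side branches."""
    rng = np.random.default_rng(seed)
    elements: list[Absorber] = []

    def grow(p0: np.ndarray, angle_deg: float, length: float, level: int) -> None:
        u = np.array([math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))])
        p1 = p0 + u * length
        elements.extend(
            _rasterize_segment(p0, p1, raster_step_m, vein_radius_m, amplitude_pa_m)
        )
        if level >= levels:
            return
        for frac in np.linspace(0.3, 0.9, branches_per_node):
            base = p0 + u * length * frac
            side = rng.choice([-1.0, 1.0])
            grow(
                base,
                angle_deg + side * rng.uniform(25, 55),
                length * rng.uniform(0.35, 0.55),
                level + 1,
            )

    grow(np.array([0.0, -trunk_length_m / 2]), 90.0, trunk_length_m, 1)
    return SourcePhantom(elements=elements, name="leaf")
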