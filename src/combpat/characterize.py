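"""Sensor characterization: impulse gating, bandwidth, acceptance angle, NEP.

Mirrors the standard point-source characterization workflow: fire a point-like
ultrasound source at the sensor, time-gate the first arrival to drop substrate
echoes, Fourier-transform the gated record to estimate the frequency response,
sweep the sensor laterally to map response vs acceptance angle, and convert
the no-source noise floor into a noise-equivalent pressure (NEP) spectral
density.  Closed-form resolution predictions follow the usual partial-view
estimates: lateral 0.71 v / (NA f0), axial 0.88 v / Δf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch, windows

from .acoustic import PressureRecordSet

__all__ = [
    "CharacterizationParams",
    "time_gate",
    "frequency_response",
    "bandwidth_at_db",
    "band_centroid",
    "angle_map",
    "extract_angle_contour",
    "nep",
    "lateral_resolution",
    "axial_resolution",
]


@dataclass
class CharacterizationParams:
    """Inputs to the closed-form resolution estimates.

    NA is sin(acceptance half-angle); f0 the response centre frequency; Δf
    (``bw_3db_hz``) the −3 dB acoustic bandwidth.
    """

    sound_speed_m_per_s: float = 1500.0
    numerical_aperture: float = 0.5
    center_freq_hz: float = 60e6
    bw_3db_hz: float = 115e6

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture <= 1:
            raise ValueError("NA must be in (0, 1]")
        if self.center_freq_hz <= 0 or self.bw_3db_hz <= 0:
            raise ValueError("f0 and bandwidth must be positive")


def time_gate(
    record: np.ndarray,
    fs_hz: float,
    window_s: tuple[float, float],
    *,
    taper_s: float = 0.0,
) -> np.ndarray:
    """Zero everything outside a time window, keeping only the first arrival.

    ``taper_s`` > 0 applies a raised-cosine roll on/off of that duration at the
    window edges (a hard gate otherwise).
    """
    record = np.asarray(record, dtype=float)
    t = np.arange(record.shape[-1]) / fs_hz
    t0, t1 = window_s
    if t1 <= t0:
        raise ValueError("gate window must have positive length")
    if t0 > t[-1] or t1 < 0:
        raise ValueError("gate window lies outside the record span")
    gate = np.zeros_like(t)
    inside = (t >= t0) & (t <= t1)
    gate[inside] = 1.0
    if taper_s > 0:
        rise = (t >= t0 - taper_s) & (t < t0)
        gate[rise] = 0.5 * (1 + np.cos(np.pi * (t0 - t[rise]) / taper_s))
        fall = (t > t1) & (t <= t1 + taper_s)
        gate[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - t1) / taper_s))
    return record * gate


def frequency_response(
    gated: np.ndarray,
    fs_hz: float,
    *,
    source_spectrum: np.ndarray | None = None,
    eps: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrum of a gated impulse record, normalised to its peak.

    ``source_spectrum``, if given (same rfft grid), deconvolves the known
    excitation signature so the result reflects the sensor band alone; bins
    where the source magnitude falls below ``eps`` of its peak are zeroed
    rather than amplified.  Returns (freqs Hz, magnitude).
    """
    gated = np.asarray(gated, dtype=float)
    if not np.any(gated):
        raise ValueError("gated record is identically zero")
    freqs = np.fft.rfftfreq(gated.shape[-1], d=1.0 / fs_hz)
    mag = np.abs(np.fft.rfft(gated))
    if source_spectrum is not None:
        s = np.abs(np.asarray(source_spectrum))
        if s.shape != mag.shape:
            raise ValueError("source_spectrum must match the rfft grid of the record")
        good = s > eps * s.max()
        mag = np.where(good, mag / np.where(good, s, 1.0), 0.0)
    return freqs, mag / mag.max()


def bandwidth_at_db(
    freqs_hz: np.ndarray, magnitude: np.ndarray, level_db: float
) -> tuple[float, float, float]:
    """Contiguous width around the spectral peak where magnitude >= the level.

    ``level_db`` must be negative (e.g. −6).  Returns (width Hz, lower edge,
    upper edge); edges are linearly interpolated crossings, clamped at the
    grid ends.  Secondary lobes outside the contiguous band are ignored.
    """
    if level_db >= 0:
        raise ValueError("level_db must be negative")
    f = np.asarray(freqs_hz, dtype=float)
    m = np.asarray(magnitude, dtype=float)
    m = m / m.max()
    thr = 10 ** (level_db / 20)
    pk = int(np.argmax(m))
    lo = f[0]
    for i in range(pk, 0, -1):
        if m[i - 1] < thr <= m[i]:
            frac = (m[i] - thr) / (m[i] - m[i - 1])
            lo = f[i] - frac * (f[i] - f[i - 1])
            break
    hi = f[-1]
    for i in range(pk, len(m) - 1):
        if m[i + 1] < thr <= m[i]:
            frac = (m[i] - thr) / (m[i] - m[i + 1])
            hi = f[i] + frac * (f[i + 1] - f[i])
            break
    return float(hi - lo), float(lo), float(hi)


def band_centroid(freqs_hz: np.ndarray, magnitude: np.ndarray, level_db: float = -6.0) -> float:
    """Spectral centroid over the contiguous band around the peak."""
    _, lo, hi = bandwidth_at_db(freqs_hz, magnitude, level_db)
    sel = (freqs_hz >= lo) & (freqs_hz <= hi)
    return float(np.average(freqs_hz[sel], weights=magnitude[sel]))


def angle_map(
    records: PressureRecordSet,
    source_position_m: tuple[float, float],
    *,
    gate_window_s: tuple[float, float] | None = None,
    compensate_spreading: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequency response vs acceptance angle from a linear sensor sweep.

    The record set must come from a single-sensor ``linear_scan`` past a fixed
    source.  Per sweep offset, the incidence angle is atan2(lateral offset,
    standoff) and the (optionally gated) record's magnitude spectrum forms one
    column of the map.  1/r spreading is compensated from the known geometry.

    Returns (angles_deg ascending, freqs_hz, map[angle, freq]).
    """
    geom = records.geometry
    if geom.mode != "linear_scan" or geom.n_sensors != 1:
        raise ValueError("angle_map expects a single-sensor linear_scan record set")
    sx, sy = source_position_m
    fs = records.fs_hz
    angles = np.empty(geom.n_steps)
    spectra = []
    for step in range(geom.n_steps):
        pos, _ = geom.step_positions(step)
        dx = sx - pos[0, 0]
        standoff = abs(sy - pos[0, 1])
        if standoff == 0:
            raise ValueError("zero standoff between source and sweep line")
        angles[step] = math.degrees(math.atan2(dx, standoff))
        rec = records.pressures_pa[step, 0]
        if gate_window_s is not None:
            rec = time_gate(rec, fs, gate_window_s)
        mag = np.abs(np.fft.rfft(rec))
        if compensate_spreading:
            mag = mag * math.hypot(dx, standoff)
        spectra.append(mag)
    freqs = np.fft.rfftfreq(records.pressures_pa.shape[-1], d=1.0 / fs)
    order = np.argsort(angles)
    return angles[order], freqs, np.asarray(spectra)[order]


def extract_angle_contour(
    angles_deg: np.ndarray,
    freqs_hz: np.ndarray,
    amap: np.ndarray,
    *,
    level_db: float = -3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frequency half-angles where the response crosses a level re on-axis.

    Each frequency row is normalised by its on-axis (angle nearest 0) value;
    the positive and negative crossing angles are linearly interpolated.
    Returns (freqs_hz, positive-angle contour, negative-angle contour), with
    NaN where the response never crosses the level.
    """
    thr = 10 ** (level_db / 20)
    i0 = int(np.argmin(np.abs(angles_deg)))
    pos = np.full(len(freqs_hz), np.nan)
    neg = np.full(len(freqs_hz), np.nan)
    for k in range(len(freqs_hz)):
        row = amap[:, k]
        ref = row[i0]
        if ref <= 0:
            continue
        rel = row / ref
        for i in range(i0, len(angles_deg) - 1):
            if rel[i] >= thr > rel[i + 1]:
                frac = (rel[i] - thr) / (rel[i] - rel[i + 1])
                pos[k] = angles_deg[i] + frac * (angles_deg[i + 1] - angles_deg[i])
                break
        for i in range(i0, 0, -1):
            if rel[i] >= thr > rel[i - 1]:
                frac = (rel[i] - thr) / (rel[i] - rel[i - 1])
                neg[k] = angles_deg[i] - frac * (angles_deg[i] - angles_deg[i - 1])
                break
    return freqs_hz, pos, neg


def nep(
    noise_record: np.ndarray,
    fs_hz: float,
    sensitivity_output_per_pa: float,
    band_hz: tuple[float, float],
    *,
    nperseg: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Noise-equivalent pressure from a source-free noise record.

    Welch (Hann-segment) amplitude spectral density of the raw output divided
    by the end-to-end sensitivity gives the NEP density in Pa/√Hz; the
    integrated NEP over the band is sqrt(∫ density² df).  Returns
    (freqs, density Pa/√Hz, integrated Pa).
    """
    lo, hi = band_hz
    if not 0 <= lo < hi <= fs_hz / 2 * (1 + 1e-12):
        raise ValueError("band must lie within [0, Nyquist]")
    if sensitivity_output_per_pa <= 0:
        raise ValueError("sensitivity must be positive")
    x = np.asarray(noise_record, dtype=float)
    if nperseg is None:
        nperseg = min(len(x), 4096)
    f, psd = welch(x, fs=fs_hz, window=windows.hann(nperseg), nperseg=nperseg)
    density = np.sqrt(psd) / sensitivity_output_per_pa
    sel = (f >= lo) & (f <= hi)
    integrated = float(np.sqrt(np.trapezoid(density[sel] ** 2, f[sel])))
    return f, density, integrated


def lateral_resolution(params: CharacterizationParams) -> float:
    """Partial-view lateral resolution estimate 0.71 v / (NA f0), metres."""
    return 0.71 * params.sound_speed_m_per_s / (
        params.numerical_aperture * params.center_freq_hz
    )


def axial_resolution(params: CharacterizationParams) -> float:
    """Axial resolution estimate 0.88 v / Δf from the −3 dB bandwidth, metres."""
    return 0.88 * params.sound_speed_m_per_s / params.bw_3db_hz
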