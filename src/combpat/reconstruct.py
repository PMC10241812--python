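"""Photoacoustic image formation by universal back-projection, plus metrics.

Universal back-projection (UBP) inverts the photoacoustic wave equation by
accumulating, at each image pixel r, the filtered detector term
b(r0, t) = 2 p(r0, t) − 2 t ∂p/∂t evaluated at the time of flight
t = |r − r0| / v, summed over all detector positions r0 with uniform weights.
Rotational scans sum the back-projections of all angles coherently in the
sample frame (full-view compounding); linear scans can be restricted to a
partial aperture to study limited-view artifacts.

Metrics: Hilbert-envelope images, contrast-to-noise ratio (peak over
background standard deviation, in dB), moving-target speed from per-frame
centroids, and profile FWHM for resolution estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import hilbert

from .acoustic import AcousticMedium, PressureRecordSet, SensorGeometry

__all__ = [
    "ImageGrid",
    "ubp_reconstruct",
    "envelope_image",
    "cnr",
    "estimate_speed",
    "profile_fwhm",
    "waveforms_to_records",
]


@dataclass
class ImageGrid:
    """A reconstructed image with physical pixel coordinates.

    ``origin_m`` is the (x, y) of pixel [0, 0]; row index increases with y,
    column index with x.
    """

    origin_m: tuple[float, float]
    pixel_size_m: float
    shape: tuple[int, int]  # (rows, cols)
    values: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size must be positive")
        if self.values is None:
            self.values = np.zeros(self.shape)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.shape):
            raise ValueError("values shape must match grid shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @classmethod
    def centered(
        cls, extent_m: float, pixel_size_m: float, center_m: tuple[float, float] = (0.0, 0.0)
    ) -> "ImageGrid":
        """Square grid of side ``extent_m`` centred on ``center_m``."""
        n = int(round(extent_m / pixel_size_m)) + 1
        ox = center_m[0] - (n - 1) / 2 * pixel_size_m
        oy = center_m[1] - (n - 1) / 2 * pixel_size_m
        return cls(origin_m=(ox, oy), pixel_size_m=pixel_size_m, shape=(n, n))

    @property
    def x_coords_m(self) -> np.ndarray:
        return self.origin_m[0] + np.arange(self.shape[1]) * self.pixel_size_m

    @property
    def y_coords_m(self) -> np.ndarray:
        return self.origin_m[1] + np.arange(self.shape[0]) * self.pixel_size_m

    def like(self, values: np.ndarray, **meta) -> "ImageGrid":
        return ImageGrid(
            origin_m=self.origin_m,
            pixel_size_m=self.pixel_size_m,
            shape=self.shape,
            values=values,
            metadata={**self.metadata, **meta},
        )

    def argmax_position_m(self) -> tuple[float, float]:
        """Physical (x, y) of the peak of |values|."""
        r, c = np.unravel_index(np.argmax(np.abs(self.values)), self.values.shape)
        return (float(self.x_coords_m[c]), float(self.y_coords_m[r]))


def waveforms_to_records(
    waves, geometry: SensorGeometry, medium: AcousticMedium
) -> PressureRecordSet:
    """Wrap a recovered :class:`~combpat.interrogation.PAWaveformSet` as a
    single-step PressureRecordSet for reconstruction."""
    p = np.asarray(waves.pressures_pa, dtype=float).T[None, :, :]
    return PressureRecordSet(
        times_s=waves.times_s, pressures_pa=p, geometry=geometry, medium=medium
    )


def ubp_reconstruct(
    records: PressureRecordSet,
    grid: ImageGrid,
    *,
    aperture_x_range_m: tuple[float, float] | None = None,
    sensor_indices: list[int] | None = None,
    time_offset_s: float = 0.0,
) -> ImageGrid:
    """Universal back-projection of a pressure record set onto an image grid.

    The back-projection term b(r0, t) = 2p − 2t ∂p/∂t is sampled by linear
    interpolation at each pixel's time of flight and accumulated with uniform
    detector weights over the (optionally subset) aperture.

    ``aperture_x_range_m`` keeps only detector positions whose effective x lies
    in the range (the partial-aperture experiments); ``sensor_indices`` keeps a
    subset of array elements.  An empty aperture raises.
    """
    geom, med = records.geometry, records.medium
    v = med.sound_speed_m_per_s
    times = records.times_s
    dt = times[1] - times[0]
    xs, ys = grid.x_coords_m, grid.y_coords_m
    gx, gy = np.meshgrid(xs, ys)  # (rows, cols)
    image = np.zeros(grid.shape)
    n_used = 0
    n_outside = 0
    sensors = range(geom.n_sensors) if sensor_indices is None else sensor_indices
    for step in range(geom.n_steps):
        positions, _ = geom.step_positions(step)
        for j in sensors:
            sx, sy = positions[j]
            if aperture_x_range_m is not None:
                lo, hi = aperture_x_range_m
                if not lo <= sx <= hi:
                    continue
            p = records.pressures_pa[step, j]
            dp = np.gradient(p, dt)
            b = 2.0 * p - 2.0 * (times + time_offset_s) * dp
            r = np.hypot(gx - sx, gy - sy)
            tof = r / v - time_offset_s
            vals = np.interp(tof, times, b, left=0.0, right=0.0)
            n_outside += int(np.count_nonzero(tof > times[-1]))
            image += vals
            n_used += 1
    if n_used == 0:
        raise ValueError("aperture subset selected no detectors")
    image /= n_used
    return grid.like(
        image,
        n_detectors=n_used,
        n_pixels_outside_window=n_outside,
        sound_speed_m_per_s=v,
    )


def envelope_image(image: ImageGrid, axis: int = 0) -> ImageGrid:
    """Analytic-signal magnitude along the axial direction (rows by default)."""
    env = np.abs(hilbert(image.values, axis=axis))
    return image.like(env, envelope=True)


def _region_mask(grid: ImageGrid, region: tuple[float, float, float, float]) -> np.ndarray:
    x0, x1, y0, y1 = region
    gx, gy = np.meshgrid(grid.x_coords_m, grid.y_coords_m)
    return (gx >= x0) & (gx <= x1) & (gy >= y0) & (gy <= y1)


def cnr(
    image: ImageGrid,
    signal_region: tuple[float, float, float, float],
    background_region: tuple[float, float, float, float],
) -> float:
    """Contrast-to-noise ratio in dB: 20 log10(peak(signal) / std(background)).

    Regions are axis-aligned rectangles (x0, x1, y0, y1) in metres and must be
    disjoint; the background region must be nonempty with nonzero spread.
    """
    ms = _region_mask(image, signal_region)
    mb = _region_mask(image, background_region)
    if not ms.any() or not mb.any():
        raise ValueError("signal/background region contains no pixels")
    if (ms & mb).any():
        raise ValueError("signal and background regions must be disjoint")
    peak = float(np.max(np.abs(image.values[ms])))
    std = float(np.std(image.values[mb]))
    if std == 0:
        raise ValueError("background standard deviation is zero")
    return 20.0 * math.log10(peak / std)


def estimate_speed(
    frames: list[ImageGrid],
    frame_times_s: np.ndarray,
    *,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Speed of a single dominant moving target across reconstructed frames.

    Per frame, the intensity-weighted centroid of the envelope above
    ``threshold``×max is taken as the target position; speed is the magnitude
    of the straight-line velocity fitted to centroid-vs-time.  Frames with no
    detectable target are skipped.  Returns (speed m/s, rms residual m).
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    pos, ts = [], []
    for img, t in zip(frames, frame_times_s):
        env = np.abs(hilbert(img.values, axis=0))
        peak = env.max()
        if peak <= 0:
            continue
        mask = env >= threshold * peak
        w = env[mask]
        gx, gy = np.meshgrid(img.x_coords_m, img.y_coords_m)
        pos.append((np.average(gx[mask], weights=w), np.average(gy[mask], weights=w)))
        ts.append(t)
    if len(pos) < 2:
        raise ValueError("fewer than two frames contained a detectable target")
    pos = np.asarray(pos)
    ts = np.asarray(ts)
    vx, x0 = np.polyfit(ts, pos[:, 0], 1)
    vy, y0 = np.polyfit(ts, pos[:, 1], 1)
    fit = np.column_stack([vx * ts + x0, vy * ts + y0])
    resid = float(np.sqrt(np.mean(np.sum((pos - fit) ** 2, axis=1))))
    return float(math.hypot(vx, vy)), resid


def _extract_profile(
    image: ImageGrid, line_spec: dict, n_points: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the image along a line; returns (arc length m, values)."""
    if "axis" in line_spec:
        ax = line_spec["axis"]
        at = line_spec["at_m"]
        if ax == "x":  # profile along x at fixed y
            row = (at - image.origin_m[1]) / image.pixel_size_m
            n = n_points or image.shape[1]
            cols = np.linspace(0, image.shape[1] - 1, n)
            coords = np.vstack([np.full(n, row), cols])
            s = cols * image.pixel_size_m
        elif ax == "y":
            col = (at - image.origin_m[0]) / image.pixel_size_m
            n = n_points or image.shape[0]
            rows = np.linspace(0, image.shape[0] - 1, n)
            coords = np.vstack([rows, np.full(n, col)])
            s = rows * image.pixel_size_m
        else:
            raise ValueError("axis must be 'x' or 'y'")
    else:
        p0 = np.asarray(line_spec["start_m"], dtype=float)
        p1 = np.asarray(line_spec["end_m"], dtype=float)
        n = n_points or max(image.shape)
        xs = np.linspace(p0[0], p1[0], n)
        ys = np.linspace(p0[1], p1[1], n)
        coords = np.vstack(
            [
                (ys - image.origin_m[1]) / image.pixel_size_m,
                (xs - image.origin_m[0]) / image.pixel_size_m,
            ]
        )
        s = np.linspace(0, float(np.hypot(*(p1 - p0))), n)
    vals = map_coordinates(image.values, coords, order=1, mode="constant", cval=0.0)
    return s, vals


def profile_fwhm(
    image: ImageGrid,
    line_spec: dict,
    *,
    envelope: str = "auto",
    n_points: int | None = None,
) -> float:
    """Full width at half maximum of a 1-D profile through the image, metres.

    ``line_spec`` is either {"axis": "x"|"y", "at_m": pos} or
    {"start_m": (x, y), "end_m": (x, y)}.  ``envelope`` = "auto" applies the
    analytic-signal magnitude only when the profile oscillates (has a
    significant negative excursion), so smooth nonnegative profiles keep their
    exact width; "always"/"never" force the choice.  Half-max crossings are
    located by linear interpolation around the global peak; a profile that
    never falls below half maximum on either side raises (target larger than
    the window).
    """
    s, vals = _extract_profile(image, line_spec, n_points)
    if envelope == "always" or (
        envelope == "auto" and vals.min() < -0.05 * np.abs(vals).max()
    ):
        vals = np.abs(hilbert(vals))
    else:
        vals = np.abs(vals)
    peak_idx = int(np.argmax(vals))
    peak = vals[peak_idx]
    if peak <= 0:
        raise ValueError("profile has no positive peak")
    half = peak / 2
    # walk outwards to the first crossings below half max
    left = None
    for i in range(peak_idx, 0, -1):
        if vals[i - 1] < half <= vals[i]:
            frac = (vals[i] - half) / (vals[i] - vals[i - 1])
            left = s[i] - frac * (s[i] - s[i - 1])
            break
    right = None
    for i in range(peak_idx, len(vals) - 1):
        if vals[i + 1] < half <= vals[i]:
            frac = (vals[i] - half) / (vals[i] - vals[i + 1])
            right = s[i] + frac * (s[i + 1] - s[i])
            break
    if left is None or right is None:
        raise ValueError("profile never falls below half maximum inside the window")
    return float(right - left)
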