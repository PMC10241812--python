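"""Universal back-projection and the image metrics built on it."""

import numpy as np
import pytest

from combpat.acoustic import (
    Absorber,
    PressureRecordSet,
    SourcePhantom,
    linear_array_geometry,
    simulate_pressure,
)
from combpat.reconstruct import (
    ImageGrid,
    cnr,
    envelope_image,
    estimate_speed,
    profile_fwhm,
    ubp_reconstruct,
)


@pytest.fixture(scope="module")
def point_records(medium, response):
    """Noiseless records of one off-centre point source, static 15-element array."""
    phantom = SourcePhantom(elements=[Absorber(position_m=(0.4e-3, 0.8e-3))])
    return simulate_pressure(
        phantom, linear_array_geometry(), medium, response, fs_hz=400e6, duration_s=6e-6
    )


class TestUbp:
    def test_all_zero_waveforms_give_all_zero_image(self, medium, static_array_geometry):
        rec = PressureRecordSet(
            times_s=np.arange(1000) / 400e6,
            pressures_pa=np.zeros((1, 15, 1000)),
            geometry=static_array_geometry,
            medium=medium,
        )
        img = ubp_reconstruct(rec, ImageGrid.centered(2e-3, 50e-6))
        assert np.all(img.values == 0.0)

    def test_linearity_in_input_waveforms(self, point_records, medium):
        grid = ImageGrid.centered(3e-3, 50e-6)
        img1 = ubp_reconstruct(point_records, grid)
        doubled = PressureRecordSet(
            times_s=point_records.times_s,
            pressures_pa=2.0 * point_records.pressures_pa,
            geometry=point_records.geometry,
            medium=medium,
        )
        img2 = ubp_reconstruct(doubled, grid)
        assert np.allclose(img2.values, 2.0 * img1.values, atol=1e-9)

    def test_empty_aperture_subset_raises(self, point_records):
        with pytest.raises(ValueError, match="no detectors"):
            ubp_reconstruct(
                point_records,
                ImageGrid.centered(2e-3, 50e-6),
                aperture_x_range_m=(1.0, 2.0),
            )

    def test_static_array_localizes_point_laterally(self, point_records):
        img = envelope_image(ubp_reconstruct(point_records, ImageGrid.centered(3e-3, 25e-6)))
        px, py = img.argmax_position_m()
        assert px == pytest.approx(0.4e-3, abs=5e-5)
        assert py == pytest.approx(0.8e-3, abs=5e-5)


class TestEnvelope:
    def test_zero_image_stays_zero(self):
        img = ImageGrid.centered(1e-3, 50e-6)
        assert np.all(envelope_image(img).values == 0.0)

    def test_pure_sinusoid_line_has_constant_envelope(self):
        grid = ImageGrid.centered(2e-3, 10e-6)
        y = grid.y_coords_m
        vals = np.tile(np.sin(2 * np.pi * y / 200e-6)[:, None], (1, grid.shape[1]))
        env = envelope_image(grid.like(vals), axis=0)
        interior = env.values[20:-20, 0]
        assert np.allclose(interior, 1.0, atol=0.02)

    def test_envelope_is_nonnegative_and_bounds_signal(self, point_records):
        img = ubp_reconstruct(point_records, ImageGrid.centered(3e-3, 50e-6))
        env = envelope_image(img)
        assert np.all(env.values >= 0)
        assert np.all(env.values >= np.abs(img.values) - 1e-9)


class TestCnr:
    def _image_with_peak(self, peak, noise_std, rng):
        grid = ImageGrid.centered(2e-3, 50e-6)
        vals = rng.normal(0, noise_std, grid.shape)
        vals[grid.shape[0] // 2 + 10, grid.shape[1] // 2] = peak
        return grid.like(vals)

    def test_definition_peak_over_background_std(self, rng):
        img = self._image_with_peak(10.0, 1.0, rng)
        val = cnr(img, (-0.2e-3, 0.2e-3, 0.3e-3, 0.8e-3), (-0.9e-3, 0.9e-3, -0.9e-3, -0.2e-3))
        std = img.values[(np.abs(img.values) < 9)].std()  # sanity: ~1
        assert val == pytest.approx(20 * np.log10(10.0 / std), abs=0.5)

    def test_scale_invariance(self, rng):
        img = self._image_with_peak(10.0, 1.0, rng)
        sig, bkg = (-0.2e-3, 0.2e-3, 0.3e-3, 0.8e-3), (-0.9e-3, 0.9e-3, -0.9e-3, -0.2e-3)
        assert cnr(img, sig, bkg) == pytest.approx(
            cnr(img.like(7.3 * img.values), sig, bkg), rel=1e-12
        )

    def test_overlapping_regions_rejected(self, rng):
        img = self._image_with_peak(10.0, 1.0, rng)
        with pytest.raises(ValueError, match="disjoint"):
            cnr(img, (-1e-3, 1e-3, -1e-3, 1e-3), (-0.5e-3, 0.5e-3, -0.5e-3, 0.5e-3))

    def test_zero_background_std_rejected(self):
        img = ImageGrid.centered(2e-3, 50e-6)
        img.values[20, 20] = 1.0
        with pytest.raises(ValueError, match="zero"):
            cnr(img, (-0.1e-3, 0.1e-3, -0.1e-3, 0.1e-3), (0.5e-3, 0.9e-3, 0.5e-3, 0.9e-3))


class TestSpeedEstimation:
    def _synthetic_frames(self, positions):
        frames = []
        grid = ImageGrid.centered(4e-3, 50e-6)
        gx, gy = np.meshgrid(grid.x_coords_m, grid.y_coords_m)
        for x, y in positions:
            vals = np.exp(-(((gx - x) ** 2 + (gy - y) ** 2) / (2 * (0.1e-3) ** 2)))
            frames.append(grid.like(vals))
        return frames

    def test_constant_velocity_recovered(self):
        times = np.arange(6) * 0.05
        pos = [(4.8e-3 * t * 0.6, -4.8e-3 * t * 0.8) for t in times]
        frames = self._synthetic_frames(pos)
        speed, resid = estimate_speed(frames, times)
        assert speed == pytest.approx(4.8e-3, rel=0.02)
        assert resid < 5e-5

    def test_static_target_zero_speed(self):
        times = np.arange(4) * 0.05
        frames = self._synthetic_frames([(0.3e-3, -0.2e-3)] * 4)
        speed, _ = estimate_speed(frames, times)
        assert speed == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_frame_subsampling(self):
        times = np.arange(8) * 0.05
        pos = [(3e-3 * t, 1e-3 * t) for t in times]
        frames = self._synthetic_frames(pos)
        full, _ = estimate_speed(frames, times)
        half, _ = estimate_speed(frames[::2], times[::2])
        assert half == pytest.approx(full, rel=1e-6)

    def test_needs_two_frames(self):
        frames = self._synthetic_frames([(0, 0)])
        with pytest.raises(ValueError):
            estimate_speed(frames, np.array([0.0]))


class TestProfileFwhm:
    def test_gaussian_closed_form(self):
        grid = ImageGrid.centered(2e-3, 10e-6)
        gx, gy = np.meshgrid(grid.x_coords_m, grid.y_coords_m)
        sigma = 0.12e-3
        img = grid.like(np.exp(-(gx**2 + gy**2) / (2 * sigma**2)))
        w = profile_fwhm(img, {"axis": "x", "at_m": 0.0})
        assert w == pytest.approx(2.355 * sigma, abs=grid.pixel_size_m)

    def test_amplitude_scale_invariance(self):
        grid = ImageGrid.centered(2e-3, 10e-6)
        gx, gy = np.meshgrid(grid.x_coords_m, grid.y_coords_m)
        img = grid.like(np.exp(-(gx**2 + gy**2) / (2 * (0.1e-3) ** 2)))
        w1 = profile_fwhm(img, {"axis": "x", "at_m": 0.0})
        w2 = profile_fwhm(img.like(13.0 * img.values), {"axis": "x", "at_m": 0.0})
        assert w1 == pytest.approx(w2, rel=1e-12)

    def test_envelope_applied_to_oscillatory_profile(self):
        # modulated Gaussian: envelope FWHM must beat the zero-crossing ripple
        grid = ImageGrid.centered(2e-3, 5e-6)
        gx, gy = np.meshgrid(grid.x_coords_m, grid.y_coords_m)
        sigma = 0.15e-3
        carrier = np.cos(2 * np.pi * gy / 60e-6)
        img = grid.like(np.exp(-(gx**2 + gy**2) / (2 * sigma**2)) * carrier)
        w = profile_fwhm(img, {"axis": "y", "at_m": 0.0})
        assert w == pytest.approx(2.355 * sigma, rel=0.1)

    def test_flat_profile_rejected(self):
        img = ImageGrid.centered(1e-3, 50e-6)
        img.values[:] = 1.0
        with pytest.raises(ValueError, match="half maximum"):
            profile_fwhm(img, {"axis": "x", "at_m": 0.0})

    def test_arbitrary_line_spec(self):
        grid = ImageGrid.centered(2e-3, 10e-6)
        gx, gy = np.meshgrid(grid.x_coords_m, grid.y_coords_m)
        sigma = 0.1e-3
        img = grid.like(np.exp(-(gx**2 + gy**2) / (2 * sigma**2)))
        w = profile_fwhm(
            img, {"start_m": (-0.8e-3, -0.8e-3), "end_m": (0.8e-3, 0.8e-3)}
        )
        assert w == pytest.approx(2.355 * sigma, rel=0.05)
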