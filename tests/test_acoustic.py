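"""Acoustic forward model: propagation, sensor response, phantom factories."""

import numpy as np
import pytest

from combpat.acoustic import (
    Absorber,
    AcousticMedium,
    SensorGeometry,
    SensorResponse,
    SourcePhantom,
    angular_weight,
    linear_array_geometry,
    make_phantom_figure8,
    make_phantom_hairs,
    make_phantom_leaf,
    make_phantom_microsphere,
    simulate_pressure,
)


def _two_sensor_geometry():
    return SensorGeometry(
        positions_m=np.array([[-1e-3, -5e-3], [1e-3, -5e-3]]), mode="static"
    )


class TestPropagation:
    def test_equidistant_sensors_see_identical_waveforms(self, medium, response):
        phantom = SourcePhantom(elements=[Absorber(position_m=(0.0, 0.0))])
        rec = simulate_pressure(
            phantom, _two_sensor_geometry(), medium, response, fs_hz=400e6, duration_s=6e-6
        )
        assert np.allclose(rec.pressures_pa[0, 0], rec.pressures_pa[0, 1], atol=1e-12)

    def test_inverse_distance_amplitude_scaling(self, medium):
        # on-axis sources at r and 2r, no band filter or angular weighting
        geometry = SensorGeometry(positions_m=np.array([[0.0, 0.0]]), mode="static")
        peaks = []
        for y in (2e-3, 4e-3):
            phantom = SourcePhantom(elements=[Absorber(position_m=(0.0, y))])
            rec = simulate_pressure(
                phantom, geometry, medium, None, fs_hz=400e6, duration_s=6e-6
            )
            peaks.append(np.abs(rec.pressures_pa).max())
        assert peaks[0] / peaks[1] == pytest.approx(2.0, rel=1e-3)

    def test_time_of_flight_of_first_arrival(self, medium, response):
        geometry = SensorGeometry(positions_m=np.array([[0.0, -5e-3]]), mode="static")
        phantom = SourcePhantom(elements=[Absorber(position_m=(0.0, 0.0))])
        fs = 500e6
        rec = simulate_pressure(phantom, geometry, medium, response, fs_hz=fs, duration_s=6e-6)
        trace = np.abs(rec.pressures_pa[0, 0])
        arrival = rec.times_s[np.argmax(trace > 0.02 * trace.max())]
        assert arrival == pytest.approx(5e-3 / 1500.0, abs=0.05e-6)

    def test_superposition_of_two_sources(self, medium, response):
        geometry = _two_sensor_geometry()
        a = SourcePhantom(elements=[Absorber(position_m=(0.0, 0.0))])
        b = SourcePhantom(elements=[Absorber(position_m=(0.5e-3, 1e-3))])
        both = SourcePhantom(elements=a.elements + b.elements)
        kw = dict(fs_hz=400e6, duration_s=6e-6)
        ra = simulate_pressure(a, geometry, medium, response, **kw)
        rb = simulate_pressure(b, geometry, medium, response, **kw)
        rab = simulate_pressure(both, geometry, medium, response, **kw)
        assert np.allclose(
            rab.pressures_pa, ra.pressures_pa + rb.pressures_pa, atol=1e-9
        )

    def test_attenuation_lowers_spectral_centroid_with_distance(self, response):
        lossy = AcousticMedium(attenuation_db_per_cm_mhz=1.0)
        geometry = SensorGeometry(positions_m=np.array([[0.0, 0.0]]), mode="static")
        centroids = []
        for y in (2e-3, 8e-3):
            phantom = SourcePhantom(elements=[Absorber(position_m=(0.0, y))])
            rec = simulate_pressure(phantom, geometry, lossy, response, fs_hz=500e6, duration_s=8e-6)
            spec = np.abs(np.fft.rfft(rec.pressures_pa[0, 0]))
            freqs = np.fft.rfftfreq(len(rec.times_s), d=1 / 500e6)
            centroids.append(np.average(freqs, weights=spec**2))
        assert centroids[1] < centroids[0]

    def test_out_of_window_source_warns(self, medium, response):
        geometry = SensorGeometry(positions_m=np.array([[0.0, -5e-3]]), mode="static")
        phantom = SourcePhantom(elements=[Absorber(position_m=(0.0, 10e-3))])
        with pytest.warns(UserWarning, match="truncated"):
            simulate_pressure(phantom, geometry, medium, response, fs_hz=400e6, duration_s=2e-6)

    def test_undersampled_rate_rejected(self, medium, response):
        geometry = SensorGeometry(positions_m=np.array([[0.0, -5e-3]]), mode="static")
        phantom = SourcePhantom(elements=[Absorber(position_m=(0.0, 0.0))])
        with pytest.raises(ValueError, match="band edge"):
            simulate_pressure(phantom, geometry, medium, response, fs_hz=200e6, duration_s=5e-6)


class TestAngularResponse:
    def test_on_axis_gain_is_unity(self, response):
        assert angular_weight(response, 0.0, 25e6) == pytest.approx(1.0)

    def test_minus3db_at_acceptance_angle_for_reference_freq(self, response):
        g = angular_weight(response, 30.0, 25e6)
        assert g == pytest.approx(10 ** (-3 / 20), abs=1e-6)

    def test_monotone_nonincreasing_in_angle(self, response):
        angles = np.linspace(0, 89, 200)
        for f in (10e6, 25e6, 60e6, 120e6):
            g = angular_weight(response, angles, f)
            assert np.all(np.diff(g) <= 1e-12)
        assert angular_weight(response, 45.0, 25e6) < angular_weight(response, 30.0, 25e6)

    def test_narrower_at_higher_frequency(self, response):
        assert angular_weight(response, 20.0, 100e6) < angular_weight(response, 20.0, 25e6)

    def test_rejects_grazing_angles(self, response):
        with pytest.raises(ValueError):
            angular_weight(response, 95.0, 25e6)


class TestSensorResponseBand:
    def test_configured_band_edges(self, response):
        freqs = np.linspace(0, 250e6, 2501)
        m = response.spectrum_magnitude(freqs)
        # the shape is solved so the -3/-6 dB contiguous widths match spec
        from combpat.characterize import bandwidth_at_db

        bw6, _, _ = bandwidth_at_db(freqs, m, -6.0)
        bw3, _, _ = bandwidth_at_db(freqs, m, -3.0)
        assert bw6 == pytest.approx(175e6, rel=0.01)
        assert bw3 == pytest.approx(115e6, rel=0.01)

    def test_kernel_is_unit_energy(self, response):
        h = response.impulse_kernel(500e6)
        assert np.sum(h**2) == pytest.approx(1.0)

    def test_inconsistent_bandwidths_rejected(self):
        with pytest.raises(ValueError):
            SensorResponse(bw_3db_hz=160e6, bw_6db_hz=175e6)


class TestPhantoms:
    def test_figure8_half_period_is_opposite_lobe(self):
        ph = make_phantom_figure8(period_s=4e-3)
        p1 = np.asarray(ph.positions_at(0.5e-3))[0]
        p2 = np.asarray(ph.positions_at(0.5e-3 + 2e-3))[0]
        assert p1[0] == pytest.approx(p2[0], abs=1e-12)  # same x
        assert p1[1] == pytest.approx(-p2[1], abs=1e-12)  # mirrored lobe

    def test_microsphere_displacement_matches_speed(self):
        ph = make_phantom_microsphere(speed_m_per_s=4.8e-3)
        d = np.asarray(ph.positions_at(1.0)) - np.asarray(ph.positions_at(0.0))
        assert np.hypot(*d[0]) == pytest.approx(4.8e-3, rel=1e-9)

    @pytest.mark.parametrize("factory", [make_phantom_hairs, make_phantom_leaf])
    def test_seeded_phantoms_are_deterministic(self, factory):
        a, b = factory(seed=3), factory(seed=3)
        pa = np.array([e.position_m for e in a.elements])
        pb = np.array([e.position_m for e in b.elements])
        assert np.array_equal(pa, pb)
        c = factory(seed=4)
        pc = np.array([e.position_m for e in c.elements])
        assert pa.shape != pc.shape or not np.allclose(pa, pc)

    def test_hairs_have_three_distinct_orientations(self):
        ph = make_phantom_hairs(seed=0)
        pos = np.array([e.position_m for e in ph.elements])
        # rough orientation clustering: fit each third of the elements
        n = len(pos) // 3
        angles = []
        for k in range(3):
            seg = pos[k * n : (k + 1) * n]
            d = seg[-1] - seg[0]
            angles.append(np.degrees(np.arctan2(d[1], d[0])) % 180)
        assert len({round(a / 10) for a in angles}) == 3

    def test_snapshot_freezes_trajectory(self):
        ph = make_phantom_microsphere()
        snap = ph.snapshot(0.5)
        assert snap.trajectory is None
        assert np.allclose(snap.positions_at(0.0), ph.positions_at(0.5))


class TestGeometry:
    def test_default_array_pitch_and_count(self, static_array_geometry):
        g = static_array_geometry
        assert g.n_sensors == 15
        dx = np.diff(g.positions_m[:, 0])
        assert np.allclose(dx, 400e-6)

    def test_rotational_steps_preserve_radii(self):
        g = linear_array_geometry(mode="rotational", rotation_angles_deg=[0, 90, 180])
        r0 = np.linalg.norm(g.step_positions(0)[0], axis=1)
        r1 = np.linalg.norm(g.step_positions(1)[0], axis=1)
        assert np.allclose(r0, r1)

    def test_linear_scan_offsets_applied_along_x(self):
        g = linear_array_geometry(mode="linear_scan", scan_offsets_m=[0.0, 1e-3])
        p0, _ = g.step_positions(0)
        p1, _ = g.step_positions(1)
        assert np.allclose(p1 - p0, [1e-3, 0.0])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SensorGeometry(positions_m=np.zeros((2, 2)), mode="static")
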