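"""Comb-through-array interrogation, demodulation and dip tracking."""

import numpy as np
import pytest

from combpat.comb import CombSpec
from combpat.interrogation import (
    NoiseSpec,
    Spectrogram,
    TrackingError,
    demodulate_frames,
    direct_interrogate,
    fit_dips,
    interrogate,
    optimal_bias_offset,
    transmission_slope,
)
from combpat.ring_array import transmission_spectrum


@pytest.fixture(scope="module")
def small_comb():
    """A reduced comb (256 teeth over 8 GHz) for cheap unit tests."""
    return CombSpec(n_subcarriers=256, dac_rate_hz=10e9, bandwidth_hz=8e9)


class TestInterrogateAndDemodulate:
    def test_null_case_reproduces_static_transmission(self, array3, default_comb_spec):
        zero = np.zeros((3, 16))
        meas = interrogate(array3, zero, default_comb_spec, None)
        sg = demodulate_frames(meas)
        expected = transmission_spectrum(array3, sg.freq_offsets_hz)
        assert np.allclose(sg.transmission, expected[None, :], atol=1e-9)
        assert np.allclose(sg.transmission, sg.transmission[0], atol=1e-12)

    def test_identity_array_roundtrip_is_flat(self, default_comb_spec):
        from combpat.ring_array import RingArraySpec, RingResonance

        # a vanishingly shallow ring: transmission ~1 across the band
        arr = RingArraySpec(
            rings=[RingResonance(center_offset_hz=0.5e9, dip_depth=1e-7)]
        )
        meas = interrogate(arr, np.zeros((1, 4)), default_comb_spec, None)
        sg = demodulate_frames(meas)
        assert np.all(sg.transmission > 0.999)

    def test_frame_time_axis_bookkeeping(self, array3, default_comb_spec):
        meas = interrogate(array3, np.zeros((3, 40)), default_comb_spec, None)
        sg = demodulate_frames(meas)
        assert len(sg.times_s) == 40
        assert sg.frame_duration_s == pytest.approx(25.6e-9)
        assert sg.times_s[-1] == pytest.approx(39 * 25.6e-9)

    def test_single_tone_modulates_only_driven_ring(self, array3, default_comb_spec):
        fd = default_comb_spec.frame_duration_s
        n = 512
        t = np.arange(n) * fd
        drives = np.zeros((3, n))
        drives[1] = 800.0 * np.sin(2 * np.pi * 1e6 * t)
        meas = interrogate(array3, drives, default_comb_spec, None)
        waves = fit_dips(demodulate_frames(meas), array3)
        spec = np.abs(np.fft.rfft(waves.shifts_hz, axis=0))
        freqs = np.fft.rfftfreq(n, d=fd)
        k = np.argmin(np.abs(freqs - 1e6))
        assert spec[k, 1] > 100 * spec[k, 0]
        assert spec[k, 1] > 100 * spec[k, 2]
        # driven ring recovers the tone amplitude through the sensitivity
        rec_amp = 2 * spec[k, 1] / n / array3.rings[1].sensitivity_hz_per_pa
        # windowed-fit bias stays within the sub-tooth accuracy contract:
        # 4% of the 80-MHz peak shift is ~3 MHz < tooth spacing / 10
        assert rec_amp == pytest.approx(800.0, rel=0.04)

    def test_aliasing_warning_and_error(self, array3, default_comb_spec):
        fs = 200e6  # record rate far above the frame rate
        t = np.arange(4000) / fs
        drives = np.tile(np.sin(2 * np.pi * 30e6 * t), (3, 1))  # 30 MHz > Δf/2
        with pytest.warns(UserWarning, match="detection bandwidth"):
            interrogate(array3, drives, default_comb_spec, None, records_fs_hz=fs)
        with pytest.raises(ValueError, match="detection bandwidth"):
            interrogate(
                array3, drives, default_comb_spec, None,
                records_fs_hz=fs, alias_action="error",
            )

    def test_noise_is_seed_reproducible(self, array3, default_comb_spec):
        a = interrogate(array3, np.zeros((3, 8)), default_comb_spec, NoiseSpec(seed=9))
        b = interrogate(array3, np.zeros((3, 8)), default_comb_spec, NoiseSpec(seed=9))
        assert np.array_equal(a.samples, b.samples)

    def test_missing_reference_raises(self, array3, default_comb_spec):
        meas = interrogate(array3, np.zeros((3, 4)), default_comb_spec, None)
        meas.reference_teeth = None
        with pytest.raises(ValueError, match="calibration"):
            demodulate_frames(meas)


class TestFitDips:
    def test_synthetic_lorentzian_recovered_at_machine_precision(self, array3, default_comb_spec):
        # forward-sample the known transmission onto the teeth, no noise:
        # demodulation must return exactly those samples
        meas = interrogate(array3, np.zeros((3, 8)), default_comb_spec, None)
        sg = demodulate_frames(meas)
        expected = transmission_spectrum(array3, sg.freq_offsets_hz)
        assert np.max(np.abs(sg.transmission - expected[None, :])) < 1e-10

    def test_center_between_teeth_located_finely(self, default_comb_spec):
        from combpat.ring_array import RingArraySpec, RingResonance

        df = default_comb_spec.tooth_spacing_hz
        # dip centred exactly between two teeth
        center = 100 * df + df / 2
        arr = RingArraySpec(rings=[RingResonance(center_offset_hz=center)], spacing_hz=1.66e9)
        meas = interrogate(arr, np.zeros((1, 4)), default_comb_spec, None)
        waves = fit_dips(demodulate_frames(meas), arr)
        assert np.all(np.abs(waves.shifts_hz) < df / 100)

    def test_step_shift_recovered_on_correct_ring(self, array15, default_comb_spec):
        drives = np.zeros((15, 24))
        drives[7, :] = 100e6 / array15.rings[7].sensitivity_hz_per_pa  # +100 MHz
        meas = interrogate(array15, drives, default_comb_spec, None)
        waves = fit_dips(demodulate_frames(meas), array15)
        # recovered within the sub-tooth (< tooth spacing / 10) contract
        assert np.allclose(waves.shifts_hz[:, 7], 100e6, atol=3.9e6)
        others = np.delete(waves.shifts_hz, 7, axis=1)
        assert np.max(np.abs(others)) < 1e6

    def test_shift_beyond_window_raises_tracking_error(self, array3, default_comb_spec):
        drives = np.zeros((3, 8))
        drives[1, :] = 1.0e9 / array3.rings[1].sensitivity_hz_per_pa  # > spacing/2
        meas = interrogate(array3, drives, default_comb_spec, None)
        with pytest.raises(TrackingError, match="ring 2"):
            fit_dips(demodulate_frames(meas), array3)

    def test_too_few_teeth_in_window_rejected(self, array3, small_comb):
        sg = Spectrogram(
            freq_offsets_hz=np.array([-1e9, 0.0, 1e9]),
            times_s=np.array([0.0]),
            transmission=np.ones((1, 3)),
        )
        with pytest.raises(ValueError, match="teeth in the fit window"):
            fit_dips(sg, array3, window_hz=0.4e9)

    def test_waveform_sample_rate_equals_tooth_spacing(self, array3, default_comb_spec):
        meas = interrogate(array3, np.zeros((3, 64)), default_comb_spec, None)
        waves = fit_dips(demodulate_frames(meas), array3)
        assert waves.sample_rate_hz == pytest.approx(default_comb_spec.tooth_spacing_hz)


class TestDirectInterrogation:
    def test_linear_regime_proportionality(self, array3, rng):
        ring = array3.rings[0]
        p = rng.normal(0, 50.0, 4096)
        out = direct_interrogate(
            ring, p, None, 500e6, optical_carrier_hz=array3.optical_carrier_hz
        )
        r = np.corrcoef(p, out)[0, 1]
        assert r > 0.9999

    def test_slope_extremum_location_on_dip_flank(self, array3):
        # dense sweep oracle: |dT/df| peaks at (FWHM/2)/sqrt(3) from centre
        ring = array3.rings[0]
        carrier = array3.optical_carrier_hz
        hwhm = ring.fwhm_hz(carrier) / 2
        offsets = np.linspace(0.01 * hwhm, 4 * hwhm, 3000)
        slopes = np.abs([transmission_slope(ring, o, carrier) for o in offsets])
        best = offsets[np.argmax(slopes)]
        assert best == pytest.approx(hwhm / np.sqrt(3), rel=1e-2)
        assert optimal_bias_offset(ring, carrier) == pytest.approx(hwhm / np.sqrt(3))

    def test_zero_slope_bias_rejected(self, array3):
        with pytest.raises(ValueError, match="zero slope"):
            direct_interrogate(
                array3.rings[0], np.zeros(8), None, 500e6,
                optical_carrier_hz=array3.optical_carrier_hz, bias_offset_hz=0.0,
            )

    def test_zero_pressure_gives_pure_noise_floor(self, array3):
        out = direct_interrogate(
            array3.rings[0], np.zeros(2048), NoiseSpec(receiver_noise_density=1e-9, seed=2),
            500e6, optical_carrier_hz=array3.optical_carrier_hz,
        )
        assert np.std(out) == pytest.approx(1e-9 * np.sqrt(500e6), rel=0.1)


class TestLinearity:
    def test_recovered_shifts_scale_with_pressure(self, array3, default_comb_spec):
        fd = default_comb_spec.frame_duration_s
        t = np.arange(256) * fd
        base = np.sin(2 * np.pi * 2e6 * t)
        results = []
        for alpha in (100.0, 300.0):
            drives = np.zeros((3, 256))
            drives[0] = alpha * base
            meas = interrogate(array3, drives, default_comb_spec, None)
            waves = fit_dips(demodulate_frames(meas), array3)
            results.append(waves.shifts_hz[:, 0])
        ratio = np.sqrt(np.mean(results[1] ** 2) / np.mean(results[0] ** 2))
        assert ratio == pytest.approx(3.0, rel=0.01)
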