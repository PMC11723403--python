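"""Generator: kinematics ground truth, Doppler sign rules, noise calibration."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from tapsonar import (BasebandSignal, ChannelSpec, KinematicsSpec,
                      compute_spectrogram, make_scenario, make_trajectory,
                      synthesize_baseband)
from tapsonar.synth import DEFAULT_PROJECTION

from conftest import C, F0, FS


class TestTrajectory:
    def test_constant_rate_gives_periodic_taps(self):
        traj = make_trajectory(KinematicsSpec(duration=7.0, rate_profile=2.0))
        assert len(traj.tap_times) in (13, 14)
        assert np.allclose(np.diff(traj.tap_times), 0.5, atol=1e-3)

    def test_displacement_is_projection_times_aperture(self):
        spec = KinematicsSpec(aperture_profile=0.05, projection=0.866)
        traj = make_trajectory(spec)
        assert np.allclose(traj.displacements, 0.0433, atol=1e-4)

    def test_decreasing_rate_delays_increase_vs_phase_integral_oracle(self):
        # oracle: invert phi(t) - 0.75*duty(t) = k on a dense grid, where
        # phi is the integral of the rate profile
        dur, g = 7.0, 0.095
        rate = lambda t: 3.0 - (2.0 / dur) * np.asarray(t, float)
        spec = KinematicsSpec(duration=dur, rate_profile=rate, stroke_duration=g)
        traj = make_trajectory(spec)

        phi = lambda t: 3.0 * t - t ** 2 / dur  # closed-form integral of rate
        oracle = []
        for k in range(len(traj.tap_times)):
            f = lambda t: phi(t) - k - 0.75 * g * rate(t)
            oracle.append(brentq(f, 0.0, dur))
        assert np.allclose(traj.tap_times, oracle, atol=2e-3)
        assert np.all(np.diff(np.diff(traj.tap_times)) > 0)  # delays strictly increase

    @given(rate=st.floats(0.8, 4.0), aperture=st.floats(0.01, 0.09))
    def test_truth_invariants_hold_for_any_constant_profile(self, rate, aperture):
        spec = KinematicsSpec(duration=5.0, rate_profile=rate,
                              aperture_profile=aperture,
                              stroke_duration=min(0.12, 0.8 / rate))
        traj = make_trajectory(spec)
        assert np.all(np.diff(traj.tap_times) > 0)
        assert np.allclose(traj.displacements, spec.projection * aperture)
        assert np.allclose(traj.rates, rate, rtol=5e-3)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KinematicsSpec(duration=0.0)
        with pytest.raises(ValueError):
            KinematicsSpec(projection=0.0)
        with pytest.raises(ValueError):
            make_trajectory(KinematicsSpec(rate_profile=lambda t: np.full_like(t, np.nan)))
        with pytest.raises(ValueError):
            make_trajectory(KinematicsSpec(aperture_profile=-0.01))


class TestBaseband:
    def test_static_target_concentrates_energy_at_dc(self):
        r = np.full(5000, 0.30)
        sig = synthesize_baseband(r, ChannelSpec(snr_db=None, dc_leak=0, clutter_amp=0), FS)
        spec = np.abs(np.fft.fftshift(np.fft.fft(sig.samples))) ** 2
        freqs = np.fft.fftshift(np.fft.fftfreq(len(r), 1 / FS))
        assert abs(freqs[np.argmax(spec)]) < 1.5

    @pytest.mark.parametrize("kappa,expected", [(1, -F0 / C), (2, -2 * F0 / C)])
    def test_receding_1ms_tone_at_minus_f0_over_c(self, kappa, expected):
        # receding at 1 m/s: r increasing; one-way Doppler -116.6 Hz, doubled at kappa=2
        t = np.arange(5000) / FS
        r = 0.30 + 1.0 * t
        chan = ChannelSpec(snr_db=None, dc_leak=0, clutter_amp=0, doppler_factor=kappa)
        sig = synthesize_baseband(r, chan, FS)
        spec = np.abs(np.fft.fftshift(np.fft.fft(sig.samples))) ** 2
        freqs = np.fft.fftshift(np.fft.fftfreq(len(t), 1 / FS))
        assert abs(freqs[np.argmax(spec)] - expected) <= FS / len(t)  # one FFT bin

    def test_closing_energy_positive_opening_negative(self):
        # noiseless scenario: per-frame energy during closing strokes sits at
        # positive frequencies only, during opening at negative only
        spec_k = KinematicsSpec(rate_profile=1.5, timing_jitter=0.0)
        traj = make_trajectory(spec_k)
        sig = synthesize_baseband(traj.radial_position,
                                  ChannelSpec(snr_db=None, dc_leak=0, clutter_amp=0), FS)
        sg = compute_spectrogram(sig)
        pos = sg.freqs > 30
        neg = sg.freqs < -30
        v = -np.gradient(traj.radial_position) * FS  # positive while closing
        half = 0.020  # s, half the analysis window
        for ti, frame in zip(sg.times, sg.power):
            lo = int((ti - half) * FS)
            hi = int((ti + half) * FS)
            vwin = v[max(lo, 0):hi]
            # only frames whose whole window lies inside one stroke phase
            if np.all(vwin > 0.3):
                assert frame[pos].sum() > 100 * frame[neg].sum()
            elif np.all(vwin < -0.3):
                assert frame[neg].sum() > 100 * frame[pos].sum()

    def test_instantaneous_frequency_matches_kinematics(self):
        traj = make_trajectory(KinematicsSpec(rate_profile=2.0))
        sig = synthesize_baseband(traj.radial_position,
                                  ChannelSpec(snr_db=None, dc_leak=0, clutter_amp=0), FS)
        f_inst = np.gradient(np.unwrap(np.angle(sig.samples))) * FS / (2 * np.pi)
        f_true = (F0 / C) * (-np.gradient(traj.radial_position) * FS)
        assert np.max(np.abs(f_inst - f_true)) <= 1e-6 * np.max(np.abs(f_true))

    def test_snr_calibration_within_half_db(self):
        traj = make_trajectory(KinematicsSpec(rate_profile=2.0))
        chan = ChannelSpec(seed=5, snr_db=20.0)
        noisy = synthesize_baseband(traj.radial_position, chan, FS)
        clean = synthesize_baseband(traj.radial_position,
                                    dataclasses.replace(chan, snr_db=None), FS)
        noise_power = np.mean(np.abs(noisy.samples - clean.samples) ** 2)
        measured = 10 * np.log10(chan.amplitude ** 2 / noise_power)
        assert abs(measured - 20.0) < 0.5

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            synthesize_baseband(np.array([]), ChannelSpec(), FS)
        with pytest.raises(ValueError):
            synthesize_baseband(np.array([0.3, np.nan]), ChannelSpec(), FS)
        with pytest.raises(ValueError):
            ChannelSpec(doppler_factor=3)


class TestScenarios:
    def test_same_seed_reproduces_samples_exactly(self):
        a = make_scenario("fast_regular", seed=42)
        b = make_scenario("fast_regular", seed=42)
        assert np.array_equal(a.signal.samples, b.signal.samples)
        assert np.array_equal(a.true_tap_times, b.true_tap_times)

    def test_decreasing_rate_has_increasing_delays(self):
        for seed in range(10):
            scn = make_scenario("decreasing_rate", seed=seed)
            assert np.all(np.diff(np.diff(scn.true_tap_times)) > 0)

    def test_narrow_displacements_below_wide(self):
        wide = make_scenario("wide_regular", seed=3)
        narrow = make_scenario("narrow_regular", seed=3)
        assert narrow.true_displacements.max() < wide.true_displacements.min()

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("jazz_hands", seed=0)
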