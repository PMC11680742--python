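"""Unit and property tests of the STA forward model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ktpulse.mtsim import bloch_simulate
from ktpulse.sta_core import (GAMMA, KTPointsPulse, SequenceTiming,
                              ShapeFactors, TransmitSetup, b1rms_map,
                              beta_min, excitation_kspace, flip_angle_map,
                              kt_beta_min, kt_waveform, nrmse,
                              pulse_shape_factors, system_matrix)

from conftest import uniform_setup


def make_pulse(rf, blips=None, timing=None):
    timing = timing or SequenceTiming()
    if blips is None:
        blips = np.zeros((timing.n_subpulses - 1, 3))
    return KTPointsPulse(rf=rf, blip_moments=blips, timing=timing)


class TestSequenceTiming:
    def test_total_duration(self, kt_timing):
        assert kt_timing.tau == pytest.approx(1.4e-3)
        assert kt_timing.n_time_samples == 100

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            SequenceTiming(dt=3e-6)          # does not divide 200 us
        with pytest.raises(ValueError):
            SequenceTiming(tr=1e-3)          # TR shorter than the pulse


class TestExcitationKspace:
    def test_no_blips_gives_zero_trajectory(self, kt_timing):
        p = make_pulse(np.ones((1, 5)))
        assert np.all(excitation_kspace(p) == 0.0)

    def test_single_blip_reversed_cumsum(self):
        t = SequenceTiming(n_subpulses=2)
        dk = np.array([[1.0, -2.0, 3.0]])
        p = make_pulse(np.ones((1, 2)), dk, t)
        k = excitation_kspace(p)
        nsps = t.samples_per_subpulse
        assert np.allclose(k[:nsps], -dk[0])
        assert np.all(k[nsps:] == 0.0)

    def test_matches_gradient_waveform_integral(self, kt_timing):
        """Per-subpulse k equals -gamma * remaining area of an explicit
        trapezoid-blip gradient waveform (independent oracle)."""
        rng = np.random.default_rng(0)
        blips = rng.uniform(-30, 30, (4, 3))
        p = make_pulse(np.ones((1, 5)), blips, kt_timing)
        k = excitation_kspace(p)

        # build the gradient waveform on a fine grid: triangles with
        # area blip/GAMMA centered in each gap
        fine = 1e-8
        n = round(kt_timing.tau / fine)
        tt = (np.arange(n) + 0.5) * fine
        g = np.zeros((n, 3))
        for j in range(4):
            t0 = (j + 1) * kt_timing.subpulse_duration \
                + j * kt_timing.blip_duration
            mid = t0 + kt_timing.blip_duration / 2.0
            tri = np.clip(1.0 - np.abs(tt - mid)
                          / (kt_timing.blip_duration / 2.0), 0.0, None)
            area = kt_timing.blip_duration / 2.0
            g += np.outer(tri / area, blips[j] / GAMMA)
        # k(t) = -gamma * integral_t^tau g dt'
        k_fine = -GAMMA * (g[::-1].cumsum(axis=0)[::-1] * fine)
        for isub, tn in enumerate(kt_timing.sample_times):
            idx = min(int(tn / fine) - 1, n - 1)
            assert np.allclose(k[isub], k_fine[idx], atol=1e-6 * 30)


class TestSystemMatrix:
    def test_on_resonance_entries(self, kt_timing, single_channel_setup):
        p = make_pulse(np.ones((1, 5)), timing=kt_timing)
        A = system_matrix(single_channel_setup, kt_timing,
                          excitation_kspace(p))
        expected = 1j * GAMMA * kt_timing.dt
        assert np.allclose(A, expected, atol=1e-20)
        assert np.allclose(np.abs(A), GAMMA * kt_timing.dt)

    def test_final_sample_phase_is_off_resonance_free(self, kt_timing):
        setup = uniform_setup(n_voxels=1)
        setup.delta_b0[:] = 137.0
        p = make_pulse(np.ones((1, 5)), timing=kt_timing)
        A = system_matrix(setup, kt_timing, excitation_kspace(p))
        assert A[0, -1] == pytest.approx(1j * GAMMA * kt_timing.dt)

    def test_matches_scalar_loop_oracle(self):
        """Element-by-element hand evaluation of the matrix formula."""
        t = SequenceTiming(n_subpulses=3, subpulse_duration=10e-6,
                           blip_duration=100e-6, dt=10e-6, tr=8e-3)
        setup = TransmitSetup(
            voxel_coords=np.array([[0.1, 0.0, 0.0], [-0.04, 0.02, 0.03]]),
            sensitivities=np.ones((1, 2), complex),
            delta_b0=np.array([100.0, -60.0]),
            mask=np.ones(2, bool))
        blips = np.array([[10.0, 0.0, 0.0], [5.0, -3.0, 2.0]])
        p = make_pulse(np.ones((1, 3)), blips, t)
        k = excitation_kspace(p)
        A = system_matrix(setup, t, k)
        for m in range(2):
            for n in range(3):
                tn = t.sample_times[n]
                ref = (1j * GAMMA * t.dt
                       * np.exp(1j * 2 * np.pi * setup.delta_b0[m]
                                * (tn - t.tau))
                       * np.exp(1j * setup.voxel_coords[m] @ k[n]))
                assert abs(A[m, n] - ref) < 1e-12 * abs(ref)


class TestFlipAngleMap:
    def test_closed_form_one_ms(self, kt_timing, single_channel_setup):
        """1 uT for 1 ms of RF-on time: alpha = gamma * B1 * tau_on."""
        p = make_pulse(np.ones((1, 5)), timing=kt_timing)
        a = flip_angle_map(p, single_channel_setup)
        assert a[0] == pytest.approx(GAMMA * 1e-6 * 1e-3, rel=1e-12)
        assert np.rad2deg(a[0]) == pytest.approx(15.33, abs=0.01)

    def test_linearity(self, kt_timing, single_channel_setup):
        p = make_pulse((0.3 + 0.4j) * np.ones((1, 5)), timing=kt_timing)
        a1 = flip_angle_map(p, single_channel_setup)
        a2 = flip_angle_map(p.scaled(2.0), single_channel_setup)
        assert np.allclose(a2, 2.0 * a1, rtol=1e-12)
        a0 = flip_angle_map(p.scaled(0.0), single_channel_setup)
        assert np.all(a0 == 0.0)


class TestB1rmsMap:
    def test_arithmetic(self, kt_timing, single_channel_setup):
        p = make_pulse(np.ones((1, 5)), timing=kt_timing)
        b = b1rms_map(p, single_channel_setup)
        assert b[0] == pytest.approx(np.sqrt(1.0 / 8.0), rel=1e-12)

    def test_opposed_channels_cancel(self, kt_timing):
        setup = uniform_setup(n_channels=2, n_voxels=3)
        setup.sensitivities[1] *= -1.0
        p = make_pulse(np.ones((2, 5)), timing=kt_timing)
        assert np.allclose(b1rms_map(p, setup), 0.0)

    def test_matches_waveform_rms_oracle(self, kt_timing):
        """Eq-level check against the time-domain RMS of the explicitly
        expanded |B1+(t)| waveform over the whole TR."""
        rng = np.random.default_rng(1)
        setup = uniform_setup(n_channels=8, n_voxels=5)
        setup.sensitivities[:] = (rng.standard_normal((8, 5))
                                  + 1j * rng.standard_normal((8, 5)))
        rf = 10 * (rng.standard_normal((8, 5))
                   + 1j * rng.standard_normal((8, 5)))
        blips = rng.uniform(-20, 20, (4, 3))
        p = make_pulse(rf, blips, kt_timing)
        beta = b1rms_map(p, setup)

        nsps = kt_timing.samples_per_subpulse
        nblip = round(kt_timing.blip_duration / kt_timing.dt)
        ntr = round(kt_timing.tr / kt_timing.dt)
        for m in range(5):
            wave = []
            for j in range(5):
                combined = setup.sensitivities[:, m] @ rf[:, j]
                wave += [combined] * nsps
                if j < 4:
                    wave += [0.0] * nblip
            wave += [0.0] * (ntr - len(wave))
            oracle = np.sqrt(np.mean(np.abs(np.array(wave)) ** 2))
            assert beta[m] == pytest.approx(oracle, rel=1e-12)

    def test_independent_of_blips(self, kt_timing, single_channel_setup):
        rf = np.ones((1, 5), complex)
        p0 = make_pulse(rf, timing=kt_timing)
        p1 = make_pulse(rf, np.full((4, 3), 17.0), kt_timing)
        assert np.array_equal(b1rms_map(p0, single_channel_setup),
                              b1rms_map(p1, single_channel_setup))


class TestShapeFactors:
    @pytest.mark.parametrize("wave,p1,p2", [
        (np.ones(10), 1.0, 1.0),
        (np.concatenate([np.ones(5), np.full(5, 0.5)]), 0.75, 0.625),
    ])
    def test_examples(self, wave, p1, p2):
        sf = pulse_shape_factors(wave)
        assert sf.p1 == pytest.approx(p1)
        assert sf.p2 == pytest.approx(p2)

    def test_kt_train(self, kt_timing):
        sf = pulse_shape_factors(kt_waveform(kt_timing))
        assert sf.p1 == pytest.approx(5.0 / 7.0, rel=1e-12)
        assert sf.p2 == pytest.approx(5.0 / 7.0, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            pulse_shape_factors(np.array([]))
        with pytest.raises(ValueError):
            pulse_shape_factors(np.full(4, 0.5))   # not unit amplitude
        with pytest.raises(ValueError):
            ShapeFactors(p1=0.9, p2=0.5)           # violates |p1|<=sqrt(p2)


class TestBetaMin:
    def test_fifteen_degrees(self, kt_timing):
        assert kt_beta_min(np.deg2rad(15.0), kt_timing) == pytest.approx(
            0.3460, abs=5e-5)

    def test_linear_in_alpha(self, kt_timing):
        b15 = kt_beta_min(np.deg2rad(15.0), kt_timing)
        b3 = kt_beta_min(np.deg2rad(3.0), kt_timing)
        assert b3 == pytest.approx(b15 / 5.0, rel=1e-12)
        assert b3 == pytest.approx(0.06920, abs=1e-5)
        assert kt_beta_min(0.0, kt_timing) == 0.0

    def test_bloch_oracle(self, kt_timing):
        """Scale a rectangular train on a uniform single-channel setup to
        a 15-degree Bloch flip, evaluate the B1rms definition, and compare
        with the analytic bound to 4 significant figures."""
        from scipy.optimize import brentq

        setup = uniform_setup()

        def flip(v):
            p = make_pulse(np.full((1, 5), v), timing=kt_timing)
            return bloch_simulate(p, setup)[0] - np.deg2rad(15.0)

        v15 = brentq(flip, 0.01, 10.0, xtol=1e-12)
        p = make_pulse(np.full((1, 5), v15), timing=kt_timing)
        beta = b1rms_map(p, setup)[0]
        assert beta == pytest.approx(kt_beta_min(np.deg2rad(15.0),
                                                 kt_timing), rel=5e-4)

    def test_zero_padding_invariance(self, kt_timing):
        """Inserting extra zero-RF gaps changes tau, p1 and p2 but not the
        bound."""
        alpha = np.deg2rad(15.0)
        ref = kt_beta_min(alpha, kt_timing)
        for gap in (300e-6, 1e-3):
            padded = SequenceTiming(blip_duration=gap)
            assert kt_beta_min(alpha, padded) == pytest.approx(ref,
                                                               rel=1e-12)

    def test_zero_flip_waveform_rejected(self, kt_timing):
        with pytest.raises(ValueError):
            beta_min(0.1, ShapeFactors(p1=0.0, p2=0.5), 8e-3, 1.4e-3)


class TestFlipBetaRelation:
    def test_on_resonance_equality(self, kt_timing):
        """For an on-resonance rectangular train without gradients the
        Bloch flip angle equals gamma*p1*sqrt(TR*tau/p2)*beta to <0.1%."""
        setup = uniform_setup()
        sf = pulse_shape_factors(kt_waveform(kt_timing))
        for volts in (0.5, 0.98, 2.0):      # up to ~30 degrees
            p = make_pulse(np.full((1, 5), volts), timing=kt_timing)
            alpha = bloch_simulate(p, setup)[0]
            beta = b1rms_map(p, setup)[0] * 1e-6
            bound = GAMMA * sf.p1 * np.sqrt(
                kt_timing.tr * kt_timing.tau / sf.p2) * beta
            assert alpha == pytest.approx(bound, rel=1e-3)

    def test_inequality_random_pulses(self, kt_timing):
        """With off-resonance and blips the achieved flip angle never
        exceeds the bound (200 random multichannel pulses)."""
        rng = np.random.default_rng(42)
        setup = uniform_setup(n_channels=4, n_voxels=6)
        setup.sensitivities[:] = 0.2 * (
            rng.standard_normal((4, 6)) + 1j * rng.standard_normal((4, 6)))
        setup.delta_b0[:] = rng.uniform(-300, 300, 6)
        sf = pulse_shape_factors(kt_waveform(kt_timing))
        factor = GAMMA * sf.p1 * np.sqrt(kt_timing.tr * kt_timing.tau
                                         / sf.p2)
        for _ in range(200):
            rf = 5 * (rng.standard_normal((4, 5))
                      + 1j * rng.standard_normal((4, 5)))
            blips = rng.uniform(-40, 40, (4, 3))
            p = make_pulse(rf, blips, kt_timing)
            alpha = bloch_simulate(p, setup)
            beta = b1rms_map(p, setup) * 1e-6
            assert np.all(alpha <= factor * beta + 1e-9)


class TestNRMSE:
    def test_trivials(self):
        x = np.array([1.0, 2.0, 3.0])
        assert nrmse(x, x) == 0.0
        assert nrmse(np.zeros(3), 2.0) == pytest.approx(1.0)
        assert nrmse(2.0 * 1.05 * np.ones(4), 2.0) == pytest.approx(0.05)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.ones(3), 0.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    def test_joint_scale_invariance(self, c, target):
        x = np.array([0.5, 1.0, 1.5]) * target
        assert nrmse(c * x, c * target) == pytest.approx(
            nrmse(x, target), rel=1e-9)
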