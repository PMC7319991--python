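"""Spatial-encoding algebra and attenuation kernels of the single-scan sequence."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ufdexsy as u
from ufdexsy.encoding import uf_t1_kernel, uf_t2_kernel

PULSE = u.SweepPulse(duration=15e-3, sweep_width=144e3)


class TestSweepPulse:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.0, 0.0), (7.5e-3, 72e3), (-3.75e-3, -36e3)],
    )
    def test_frequency_is_linear_in_time(self, t, expected):
        assert u.sweep_frequency(PULSE, t) == pytest.approx(expected)

    def test_frequency_antisymmetric(self):
        for t in (1e-3, 3e-3, 7.5e-3):
            assert u.sweep_frequency(PULSE, -t) == -u.sweep_frequency(PULSE, t)

    def test_phase_quadratic_and_even(self):
        # phi = pi * 144e3 * (7.5e-3)^2 / 15e-3
        assert u.sweep_phase(PULSE, 7.5e-3) == pytest.approx(
            math.pi * 144e3 * 7.5e-3**2 / 15e-3
        )
        assert u.sweep_phase(PULSE, 7.5e-3) == pytest.approx(1696.46, rel=1e-4)
        assert u.sweep_phase(PULSE, 0.0) == 0.0
        for t in (2e-3, 5e-3):
            assert u.sweep_phase(PULSE, -t) == u.sweep_phase(PULSE, t)

    def test_time_outside_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            u.sweep_frequency(PULSE, 8e-3)
        with pytest.raises(ValueError, match="window"):
            u.sweep_phase(PULSE, -8e-3)

    def test_pi_pulse_is_half_duration(self, block):
        assert block.sweep_pi.duration == block.sweep_half.duration / 2


class TestPositionMapping:
    def test_encoding_region_bounds(self, block):
        z_min, z_max = u.encoding_region(block)
        assert z_max == pytest.approx(3.3288e-3, rel=1e-4)
        assert z_min == -z_max
        assert z_max - z_min == pytest.approx(6.6576e-3, rel=1e-4)

    def test_region_scales_inversely_with_gradient(self, block):
        double_g = u.default_encoding_block(grad_spatial_diffusion=2 * 0.508)
        assert u.encoding_region(double_g)[1] == pytest.approx(
            u.encoding_region(block)[1] / 2
        )
        double_sw = u.default_encoding_block(sweep_width=2 * 144e3)
        assert u.encoding_region(double_sw)[1] == pytest.approx(
            u.encoding_region(block)[1] * 2
        )

    def test_excitation_instant(self, block):
        assert u.excitation_instant(block, 0.0) == 0.0
        assert u.excitation_instant(block, 1e-3) == pytest.approx(
            2.253e-3, rel=1e-3
        )
        z_min, z_max = u.encoding_region(block)
        # region endpoints map exactly to the sweep endpoints
        assert u.excitation_instant(block, z_max) == pytest.approx(7.5e-3)
        assert u.excitation_instant(block, z_min) == pytest.approx(-7.5e-3)

    def test_position_outside_region_rejected(self, block):
        with pytest.raises(ValueError, match="encoding region"):
            u.excitation_instant(block, 5e-3)

    def test_phase_at_position_even_and_flip_dependent(self, block):
        z = 2e-3
        phi = u.sweep_phase_at_position(block, block.sweep_half, z)
        assert phi == u.sweep_phase_at_position(block, block.sweep_half, -z)
        assert u.sweep_phase_at_position(block, block.sweep_half, 0.0) == 0.0
        # pi/2 and pi pulses imprint different quadratic phases (2x duration)
        phi_pi = u.sweep_phase_at_position(block, block.sweep_pi, z)
        assert phi_pi == pytest.approx(phi / 2)
        assert phi != phi_pi


class TestEchoTimeProfile:
    def test_printed_convention(self, block):
        z_min, z_max = u.encoding_region(block)
        assert u.echo_time_profile(block, z_max) == pytest.approx(0.0, abs=1e-15)
        assert u.echo_time_profile(block, 0.0) == pytest.approx(30e-3)
        assert u.echo_time_profile(block, z_min) == pytest.approx(60e-3)

    def test_prose_convention_halves(self, block):
        z_min, _ = u.encoding_region(block)
        assert u.echo_time_profile(
            block, z_min, t1_prose_convention=True
        ) == pytest.approx(30e-3)

    def test_affine_with_expected_slope(self, block):
        zs = np.linspace(-3e-3, 3e-3, 7)
        t1 = np.array([u.echo_time_profile(block, z) for z in zs])
        slopes = np.diff(t1) / np.diff(zs)
        expected = -2 * block.gamma * block.grad_spatial_diffusion * 15e-3 / (
            math.pi * 144e3
        )
        assert np.allclose(slopes, expected, rtol=1e-12)


class TestAttenuation:
    def test_no_diffusion_no_decay(self, block):
        q = u.AttenuationQuery(diffusion=0.0, amplitude=2.0)
        for z in (-2e-3, 0.0, 2e-3):
            assert u.first_block_attenuation(block, q, z) == 2.0

    @pytest.mark.parametrize(
        "d, expected_amp",
        [(1.9e-9, 2.676e-9), (6.0e-11, 0.53615)],
    )
    def test_first_block_at_centre(self, block, d, expected_amp):
        # t1(0) = 30 ms; exponents 19.74 and 0.623 for the two water pools
        q = u.AttenuationQuery(diffusion=d)
        assert u.first_block_attenuation(block, q, 0.0) == pytest.approx(
            expected_amp, rel=1e-3
        )

    def test_negative_diffusion_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            u.AttenuationQuery(diffusion=-1e-9)

    def test_double_echo_exponent_matches_two_hahn_echoes(self, block):
        # single Hahn echo of duration tE under constant G: gamma^2 G^2 tE^3 D/12;
        # two back-to-back echoes of t1/2 each sum to gamma^2 G^2 t1^3 D / 48
        g = block.gamma * block.grad_spatial_diffusion
        d = 1.9e-9
        t1 = u.echo_time_profile(block, 0.0)
        hahn = 2 * (g**2 * (t1 / 2) ** 3 * d / 12)
        q = u.AttenuationQuery(diffusion=d)
        amp = u.first_block_attenuation(block, q, 0.0)
        assert amp == pytest.approx(math.exp(-hahn), rel=1e-12)

    def test_effective_read_gradient(self, readout):
        assert u.effective_read_gradient(readout) == pytest.approx(
            0.23048, rel=1e-4
        )
        # rectangle of length tau and amplitude G has G_Reff = G
        rect = u.default_cpmg_readout(
            half_echo=4e-3, read_grad_ramp=1e-12, read_grad_total=4e-3
        )
        assert u.effective_read_gradient(rect) == pytest.approx(0.268, rel=1e-6)
        # halving tau doubles G_Reff at fixed area
        halved = u.default_cpmg_readout(half_echo=2e-3)
        assert u.effective_read_gradient(halved) == pytest.approx(
            2 * u.effective_read_gradient(readout)
        )

    def test_cpmg_rates(self, readout):
        q_fast = u.AttenuationQuery(diffusion=1.9e-9, amplitude=1.0)
        assert u.cpmg_attenuation(readout, q_fast, 0.0) == 1.0
        amp = u.cpmg_attenuation(readout, q_fast, 8e-3)
        assert amp == pytest.approx(0.735, rel=1e-3)
        rate = -math.log(amp) / 8e-3
        assert rate == pytest.approx(38.5, rel=1e-2)
        q_slow = u.AttenuationQuery(diffusion=6.0e-11)
        rate_slow = -math.log(u.cpmg_attenuation(readout, q_slow, 8e-3)) / 8e-3
        assert rate_slow == pytest.approx(1.22, rel=1e-2)
        # the slow pool survives the full 32-echo train
        t_end = 32 * readout.echo_spacing
        assert u.cpmg_attenuation(readout, q_slow, t_end) > 0.7

    @given(
        d=st.floats(1e-12, 1e-8),
        scale=st.floats(0.5, 2.0),
    )
    def test_attenuations_bounded_and_monotone_in_d(self, d, scale):
        block = u.default_encoding_block()
        readout = u.default_cpmg_readout()
        q = u.AttenuationQuery(diffusion=d, amplitude=scale)
        q2 = u.AttenuationQuery(diffusion=2 * d, amplitude=scale)
        a1 = u.first_block_attenuation(block, q, 0.0)
        assert 0 < a1 <= scale
        assert u.first_block_attenuation(block, q2, 0.0) < a1
        c1 = u.cpmg_attenuation(readout, q, 16e-3)
        assert 0 < c1 <= scale
        assert u.cpmg_attenuation(readout, q2, 16e-3) < c1
        assert u.cpmg_attenuation(readout, q, 32e-3) < c1


class TestForwardSignal:
    def test_total_weight_at_zero_times(self, block, readout):
        d = np.array([1.9e-9, 6.0e-11])
        w = np.array([[0.76, 0.0], [0.0, 0.24]])
        sig = u.uf_forward_signal(
            block, readout, d, d, w, np.array([0.0]), np.array([0.0]),
            amplitude=3.0,
        )
        assert sig[0, 0] == pytest.approx(3.0 * w.sum())

    def test_slow_component_dominates_large_t1(self, block, readout):
        d = np.array([1.9e-9, 6.0e-11])
        w = np.diag([0.76, 0.24])
        t1 = np.array([0.0, 30e-3, 60e-3])
        t2 = readout.echo_times()
        sig = u.uf_forward_signal(block, readout, d, d, w, t1, t2)
        only_slow = u.uf_forward_signal(
            block, readout, d, d, np.diag([0.0, 0.24]), t1, t2
        )
        # at t1 = 60 ms the free-water term is gone: encapsulated only
        assert sig[2] == pytest.approx(only_slow[2], rel=1e-6)
        assert sig[0, 0] > 2 * sig[2, 0]

    def test_matches_bruteforce_quadruple_loop(self, block, readout):
        rng = np.random.default_rng(42)
        d1 = np.logspace(-11, -9, 8)
        d2 = np.logspace(-11.5, -8.5, 8)
        w = rng.uniform(size=(8, 8))
        t1 = np.linspace(1e-3, 60e-3, 8)
        t2 = readout.echo_spacing * np.arange(1, 9)
        sig = u.uf_forward_signal(block, readout, d1, d2, w, t1, t2)
        g_sd = block.gamma * block.grad_spatial_diffusion
        g_eff = block.gamma * u.effective_read_gradient(readout)
        brute = np.zeros((8, 8))
        for i, a in enumerate(t1):
            for j, b in enumerate(t2):
                for k, da in enumerate(d1):
                    for l, db in enumerate(d2):
                        brute[i, j] += w[k, l] * math.exp(
                            -g_sd**2 * a**3 * da / 48
                        ) * math.exp(-g_eff**2 * readout.half_echo**2 * db * b / 3)
        assert np.allclose(sig, brute, rtol=1e-12, atol=0)

    def test_shape_mismatch_rejected(self, block, readout):
        with pytest.raises(ValueError, match="shape"):
            u.uf_forward_signal(
                block, readout, np.array([1e-9]), np.array([1e-9, 1e-10]),
                np.ones((2, 2)), np.array([0.0]), np.array([0.0]),
            )

    def test_kernel_first_row_is_one_at_zero_time(self, block, readout):
        d = np.logspace(-12, -8, 16)
        assert np.allclose(uf_t1_kernel(block, np.array([0.0]), d), 1.0)
        assert np.allclose(uf_t2_kernel(readout, np.array([0.0]), d), 1.0)
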