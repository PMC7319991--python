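"""Synthetic dataset generation, file format, and preprocessing."""

import math

import numpy as np
import pytest

import ufdexsy as u
from ufdexsy.synthio import exchange_weights


class TestNoiseSpec:
    def test_seed_required_for_finite_snr(self):
        with pytest.raises(ValueError, match="seed"):
            u.NoiseSpec(snr=100.0)
        u.NoiseSpec(snr=math.inf)  # noiseless needs no seed

    def test_noise_sd_matches_snr(self):
        signal = np.ones((48, 32))
        noisy, sd = u.NoiseSpec(snr=100.0, seed=0).apply(signal)
        assert sd == pytest.approx(0.01)
        assert np.std(noisy - signal) == pytest.approx(sd, rel=0.10)


class TestExchangeWeights:
    def test_zero_mixing_time_is_diagonal(self, vesicle_system):
        w = exchange_weights(vesicle_system, 0.0)
        assert np.allclose(np.diag(w), [0.76, 0.24])
        assert w[0, 1] == w[1, 0] == 0.0

    def test_cross_mass_grows_from_zero(self, vesicle_system):
        w = exchange_weights(vesicle_system, 0.05)
        assert w[0, 1] > 0 and w[1, 0] > 0
        assert w.sum() <= 1.0  # relaxation only removes magnetization


class TestGenerateUF:
    def test_deterministic_for_same_seed(self, vesicle_system, block, readout):
        kw = dict(artefacts=True)
        a = u.generate_uf_dataset(vesicle_system, block, readout, 1.0,
                                  u.NoiseSpec(snr=100, seed=7), **kw)
        b = u.generate_uf_dataset(vesicle_system, block, readout, 1.0,
                                  u.NoiseSpec(snr=100, seed=7), **kw)
        assert np.array_equal(a.signal.values, b.signal.values)
        c = u.generate_uf_dataset(vesicle_system, block, readout, 1.0,
                                  u.NoiseSpec(snr=100, seed=8), **kw)
        assert not np.array_equal(a.signal.values, c.signal.values)

    def test_geometry_of_generated_grid(self, vesicle_system, block, readout):
        bundle = u.generate_uf_dataset(
            vesicle_system, block, readout, 1.0, u.NoiseSpec(snr=math.inf)
        )
        g = bundle.signal
        assert g.kind1 == "z" and g.kind2 == "t2"
        # 128 pixels over a 17.5 mm FOV leave ~48 rows in the 6.66 mm region
        assert g.axis1.size == 48
        assert g.axis2.size == readout.n_echoes
        z_min, z_max = u.encoding_region(block)
        assert g.axis1[0] >= z_min and g.axis1[-1] <= z_max

    def test_noiseless_zero_mixing_has_no_cross_mass(
        self, no_exchange_system, block, readout
    ):
        bundle = u.generate_uf_dataset(
            no_exchange_system, block, readout, 0.0, u.NoiseSpec(snr=math.inf)
        )
        w = exchange_weights(no_exchange_system, 0.0)
        assert w[0, 1] == 0.0 and w[1, 0] == 0.0
        # forward signal must then be the sum of the two diagonal components
        data = u.trim_and_map(bundle.signal, block)
        d = no_exchange_system.diffusivities
        direct = u.uf_forward_signal(
            block, readout, d, d, np.diag([0.76, 0.24]),
            data.axis1, data.axis2,
        )
        assert np.allclose(data.values, direct, atol=1e-14)

    def test_artefact_rows_recorded_and_corrupted(
        self, vesicle_system, block, readout
    ):
        clean = u.generate_uf_dataset(
            vesicle_system, block, readout, 1.0, u.NoiseSpec(snr=math.inf)
        )
        dirty = u.generate_uf_dataset(
            vesicle_system, block, readout, 1.0, u.NoiseSpec(snr=math.inf),
            artefacts=True,
        )
        rows = dirty.signal.metadata["artefact_rows"]
        assert len(rows) == 3
        for r in rows:
            assert np.all(
                dirty.signal.values[r] <= 0.5 * clean.signal.values[r] + 1e-15
            )


class TestGenerateConventional:
    def test_b_grid_endpoints(self, vesicle_system, conv_block):
        bundle = u.generate_conventional_dataset(
            vesicle_system, conv_block, u.NoiseSpec(snr=math.inf)
        )
        b = bundle.signal.axis1
        assert b[0] == pytest.approx(
            u.b_value(conv_block, 26.7e-3), rel=1e-12
        )
        assert b[-1] == pytest.approx(1.248e10, rel=1e-3)
        assert bundle.signal.values.shape == (16, 16)

    def test_single_site_is_stejskal_tanner_surface(self, conv_block):
        sys = u.TwoSiteSystem(
            d_free=1e-9, d_enc=1e-9, x_free=1.0, k_ef=0.0, k_fe=0.0
        )
        block = u.default_conventional_block(mixing_time=0.0)
        bundle = u.generate_conventional_dataset(
            sys, block, u.NoiseSpec(snr=math.inf)
        )
        b = bundle.signal.axis1
        expected = np.exp(-np.add.outer(b, b) * 1e-9)
        assert np.allclose(bundle.signal.values, expected, rtol=1e-12)

    def test_reproducible(self, vesicle_system, conv_block):
        a = u.generate_conventional_dataset(
            vesicle_system, conv_block, u.NoiseSpec(snr=50, seed=3)
        )
        b = u.generate_conventional_dataset(
            vesicle_system, conv_block, u.NoiseSpec(snr=50, seed=3)
        )
        assert np.array_equal(a.signal.values, b.signal.values)


class TestEchoesToProfiles:
    def test_constant_record_is_dc_peak(self, readout):
        echoes = np.ones((4, readout.points_per_echo), dtype=complex)
        grid = u.echoes_to_profiles(echoes, readout)
        n = readout.points_per_echo
        profile = grid.values[:, 0]
        assert np.argmax(profile) == n // 2  # centred zero frequency
        assert profile[n // 2] == pytest.approx(n)
        assert np.allclose(np.delete(profile, n // 2), 0.0, atol=1e-9)

    def test_boxcar_object_sinc_width(self, readout):
        # a boxcar profile in z produces echoes whose DFT returns the box
        n = readout.points_per_echo
        box = np.zeros(n)
        box[n // 2 - 8: n // 2 + 8] = 1.0
        record = np.fft.ifft(np.fft.ifftshift(box))
        grid = u.echoes_to_profiles(record[None, :], readout)
        assert np.allclose(grid.values[:, 0], box, atol=1e-12)

    def test_roundtrip_matches_forward_columns(self, block, readout,
                                               vesicle_system):
        # ideal echoes synthesized from the forward model on the imaging
        # pixel grid must Fourier-transform back to the forward columns
        n = readout.points_per_echo
        fov = 2 * math.pi / (readout.gamma * readout.read_grad_amplitude
                             * readout.dwell)
        z_fov = (np.arange(n) - n // 2) * (fov / n)
        z_min, z_max = u.encoding_region(block)
        inside = (z_fov >= z_min) & (z_fov <= z_max)
        t1 = np.array([u.echo_time_profile(block, z) for z in z_fov[inside]])
        order = np.argsort(t1)
        d = vesicle_system.diffusivities
        w = u.exchange_weights(vesicle_system, 1.0)
        sig_sorted = u.uf_forward_signal(
            block, readout, d, d, w, t1[order], readout.echo_times()
        )
        profile = np.zeros((n, readout.n_echoes))
        rows = np.flatnonzero(inside)[order]
        profile[rows] = sig_sorted
        records = np.fft.ifft(np.fft.ifftshift(profile, axes=0), axis=0).T
        grid = u.echoes_to_profiles(records, readout)
        assert np.allclose(grid.values[inside], profile[inside], atol=1e-9)

    def test_wrong_record_length_rejected(self, readout):
        with pytest.raises(ValueError, match="echo records"):
            u.echoes_to_profiles(np.ones((4, 17)), readout)


class TestTrimAndMap:
    def test_rows_preserved_without_artefacts(self, vesicle_system, block,
                                              readout):
        bundle = u.generate_uf_dataset(
            vesicle_system, block, readout, 1.0, u.NoiseSpec(snr=math.inf)
        )
        data = u.trim_and_map(bundle.signal, block)
        assert data.kind1 == "t1"
        assert data.axis1.size == bundle.signal.axis1.size
        assert np.all(np.diff(data.axis1) > 0)

    def test_artefact_rows_dropped(self, vesicle_system, block, readout):
        bundle = u.generate_uf_dataset(
            vesicle_system, block, readout, 1.0,
            u.NoiseSpec(snr=math.inf), artefacts=True,
        )
        data = u.trim_and_map(bundle.signal, block)
        assert data.axis1.size == bundle.signal.axis1.size - 3

    def test_out_of_region_rows_dropped(self, block, readout, vesicle_system):
        bundle = u.generate_uf_dataset(
            vesicle_system, block, readout, 1.0, u.NoiseSpec(snr=math.inf)
        )
        g = bundle.signal
        wide = u.SignalGrid(
            axis1=np.concatenate([[-5e-3], g.axis1, [5e-3]]),
            axis2=g.axis2,
            values=np.vstack([g.values[:1], g.values, g.values[-1:]]),
            kind1="z", kind2="t2", metadata=dict(g.metadata),
        )
        data = u.trim_and_map(wide, block)
        assert data.axis1.size == g.axis1.size

    def test_all_rows_trimmed_is_an_error(self, block, readout):
        grid = u.SignalGrid(
            axis1=np.array([-5e-3, 5e-3]), axis2=np.array([1.0]),
            values=np.ones((2, 1)), kind1="z", kind2="t2",
        )
        with pytest.raises(ValueError, match="trimmed"):
            u.trim_and_map(grid, block)


class TestFileFormat:
    def test_roundtrip_and_byte_identical(self, tmp_path, vesicle_system,
                                          block, readout):
        bundle = u.generate_uf_dataset(
            vesicle_system, block, readout, 1.0, u.NoiseSpec(snr=100, seed=7)
        )
        tsv1, json1 = u.write_dataset(bundle, tmp_path / "a")
        tsv2, json2 = u.write_dataset(bundle, tmp_path / "b")
        assert tsv1.read_bytes() == tsv2.read_bytes()
        assert json1.read_bytes() == json2.read_bytes()
        back = u.read_dataset(tmp_path / "a")
        assert np.allclose(back.signal.values, bundle.signal.values,
                           rtol=1e-11)
        assert np.allclose(back.signal.axis1, bundle.signal.axis1)
        assert back.truth.k_ef == pytest.approx(vesicle_system.k_ef)
        assert back.provenance["seed"] == 7

    def test_regenerated_dataset_serializes_identically(
        self, tmp_path, vesicle_system, conv_block
    ):
        for name in ("x", "y"):
            b = u.generate_conventional_dataset(
                vesicle_system, conv_block, u.NoiseSpec(snr=100, seed=1)
            )
            u.write_dataset(b, tmp_path / name)
        assert (tmp_path / "x.tsv").read_bytes() == \
            (tmp_path / "y.tsv").read_bytes()
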