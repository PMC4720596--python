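"""Tests for k-space containers, Casorati mapping, FFT conventions, and
the despiking pipeline orchestration."""

import numpy as np
import pytest

from kdespike import (DespikeConfig, KSpaceSeries, SpikeModel, add_spikes,
                      background_noise_std, casoratify, despike,
                      despike_grouped, effective_lambda, frame_as_matrix,
                      images_to_kspace, reconstruct_images, uncasoratify)
from kdespike.kspace import default_lambda
from kdespike.refill import central_window_mask
from conftest import complex_randn


class TestEffectiveLambda:
    def test_unit_case(self):
        assert effective_lambda(1, 1, 1, 1) == 1.0

    def test_canonical_max_dim_weight(self):
        # (Nv, Nt) = (16384, 50): weight is kappa / sqrt(Nv)
        assert effective_lambda(128, 128, 50, 5) == pytest.approx(5 / 128.0)
        # frame count dominating the matrix size
        assert effective_lambda(4, 4, 100, 2) == pytest.approx(0.2)
        assert default_lambda((40, 40)) == pytest.approx(1 / np.sqrt(40))

    def test_rejects_nonpositive(self):
        for args in [(0, 1, 1, 1), (1, 1, 1, -2), (1, -1, 1, 1)]:
            with pytest.raises(ValueError):
                effective_lambda(*args)


class TestCasorati:
    def test_constant_frames(self):
        data = np.stack([np.full((2, 2), j, complex) for j in range(3)], axis=2)
        M = casoratify(KSpaceSeries(data))
        assert M.shape == (4, 3)
        for j in range(3):
            np.testing.assert_array_equal(M[:, j], j)

    def test_roundtrip_bit_exact(self, rng):
        data = complex_randn(rng, 5, 7, 4)
        series = KSpaceSeries(data)
        np.testing.assert_array_equal(
            uncasoratify(casoratify(series), data.shape), series.data)

    def test_proportional_frames_have_rank_one(self, lowrank_series):
        s = np.linalg.svd(casoratify(lowrank_series), compute_uv=False)
        assert np.sum(s > 1e-8 * s[0]) == 1

    def test_vectorization_is_column_major(self):
        data = np.arange(6, dtype=complex).reshape(3, 2, 1)
        M = casoratify(KSpaceSeries(data))
        # kx varies fastest
        np.testing.assert_array_equal(M[:, 0], data[:, :, 0].ravel(order="F"))


class TestFrameAsMatrix:
    def test_projection(self, rng):
        data = complex_randn(rng, 4, 6, 3)
        series = KSpaceSeries(data)
        np.testing.assert_array_equal(frame_as_matrix(series, 1), data[:, :, 1])

    def test_out_of_range(self, lowrank_series):
        with pytest.raises(IndexError):
            frame_as_matrix(lowrank_series, 99)

    def test_identical_rows_give_rank_one(self):
        frame = np.tile(np.arange(1, 9, dtype=complex), (8, 1)).T
        series = KSpaceSeries(frame[:, :, None])
        s = np.linalg.svd(frame_as_matrix(series, 0), compute_uv=False)
        assert np.sum(s > 1e-10 * s[0]) == 1


class TestReconstruction:
    def test_delta_at_center_gives_flat_image(self):
        k = np.zeros((16, 16, 1), complex)
        k[8, 8, 0] = 1.0
        img = reconstruct_images(KSpaceSeries(k))
        np.testing.assert_allclose(img, img[0, 0, 0], rtol=1e-12)

    def test_forward_inverse_roundtrip(self, rng):
        images = rng.standard_normal((12, 10, 3)) + 1j * rng.standard_normal(
            (12, 10, 3))
        series = KSpaceSeries(images_to_kspace(images))
        back = np.abs(np.fft.ifft2(np.fft.ifftshift(series.data, axes=(0, 1)),
                                   axes=(0, 1)))
        np.testing.assert_allclose(back, np.abs(images), atol=1e-10)
        np.testing.assert_allclose(reconstruct_images(series),
                                   np.abs(images), atol=1e-10)

    def test_offset_center_roundtrip_magnitude(self, rng):
        images = rng.standard_normal((16, 16, 2))
        center = (5, 11)
        series = KSpaceSeries(images_to_kspace(images, center),
                              center_index=center)
        np.testing.assert_allclose(reconstruct_images(series),
                                   np.abs(images), atol=1e-10)

    def test_parseval(self, rng):
        images = rng.standard_normal((8, 8, 2))
        k = images_to_kspace(images)
        assert np.sum(np.abs(k) ** 2) / 64 == pytest.approx(
            np.sum(np.abs(images) ** 2))


@pytest.fixture(scope="module")
def small_phantom():
    """32x32, 8-frame noisy phantom with injected spikes (seeded)."""
    rng = np.random.default_rng(7)
    base = np.zeros((32, 32))
    base[8:24, 10:22] = 1.0
    base[12:20, 14:18] = 2.0
    scales = 1.0 + 0.3 * np.sin(np.linspace(0, 2 * np.pi, 8, endpoint=False))
    images = base[:, :, None] * scales[None, None, :]
    noisy = images + 0.01 * (rng.standard_normal(images.shape)
                             + 1j * rng.standard_normal(images.shape))
    series = KSpaceSeries(images_to_kspace(noisy))
    corrupted, ledger = add_spikes(
        series, SpikeModel(n_spikes=6, exclusion_radius=10, seed=11))
    return series, corrupted, ledger


class TestDespike:
    def test_spike_free_lowrank_series_has_no_sparse_part(self, lowrank_series):
        out = despike(lowrank_series, DespikeConfig(kappa=3))
        ratio = np.linalg.norm(out.spikes.data) / np.linalg.norm(
            lowrank_series.data)
        assert ratio < 1e-4
        np.testing.assert_allclose(out.clean.data, lowrank_series.data,
                                   atol=1e-4 * np.abs(lowrank_series.data).max())

    def test_injected_spikes_end_up_in_sparse_component(self, small_phantom):
        series, corrupted, ledger = small_phantom
        out = despike(corrupted, DespikeConfig(kappa=3))
        win = central_window_mask((32, 32), corrupted.center_index, 16)
        removed = 0.0
        injected = 0.0
        for rec in ledger:
            for x, y, v in rec.samples:
                if win[x, y]:
                    continue
                injected += abs(v) ** 2
                assert out.spikes.data[x, y, rec.frame] != 0
                removed += abs(corrupted.data[x, y, rec.frame]
                               - out.clean.data[x, y, rec.frame]) ** 2
        assert removed >= 0.9 * injected

    def test_multiframe_L_retains_full_rank(self, small_phantom):
        _, corrupted, _ = small_phantom
        out = despike(corrupted, DespikeConfig(kappa=3))
        assert out.diagnostics.rank_L == corrupted.n_frames

    def test_conservation_within_tol_and_exact_on_refill(self, small_phantom):
        _, corrupted, _ = small_phantom
        cfg = DespikeConfig(kappa=3)
        out = despike(corrupted, cfg)
        total = out.clean.data + out.spikes.data
        rel = np.linalg.norm(total - corrupted.data) / np.linalg.norm(
            corrupted.data)
        assert rel <= cfg.tol
        for j, rep in enumerate(out.diagnostics.refill_reports):
            m = rep.refilled_mask
            np.testing.assert_array_equal(total[:, :, j][m],
                                          corrupted.data[:, :, j][m])

    def test_frame_order_invariance(self, small_phantom):
        _, corrupted, _ = small_phantom
        cfg = DespikeConfig(kappa=3)
        out = despike(corrupted, cfg)
        perm = np.random.default_rng(3).permutation(corrupted.n_frames)
        permuted = KSpaceSeries(corrupted.data[:, :, perm],
                                corrupted.readout_axis,
                                corrupted.center_index)
        out_p = despike(permuted, cfg)
        inv = np.argsort(perm)
        scale = np.linalg.norm(out.clean.data)
        assert np.linalg.norm(out_p.clean.data[:, :, inv]
                              - out.clean.data) / scale < 1e-9

    def test_singleframe_mode_processes_frames_independently(self, small_phantom):
        _, corrupted, _ = small_phantom
        cfg = DespikeConfig(kappa=3, mode="singleframe")
        out = despike(corrupted, cfg)
        assert len(out.diagnostics.rpca) == corrupted.n_frames
        sub = KSpaceSeries(corrupted.data[:, :, :1],
                           corrupted.readout_axis, corrupted.center_index)
        out_one = despike(sub, cfg)
        np.testing.assert_array_equal(out.clean.data[:, :, 0],
                                      out_one.clean.data[:, :, 0])

    def test_stripe_suppression_single_offcenter_spike(self):
        rng = np.random.default_rng(2)
        base = np.zeros((32, 32))
        base[10:22, 10:22] = 1.0
        images = base[:, :, None] * np.linspace(0.8, 1.2, 6)[None, None, :]
        noisy = images + 0.01 * (rng.standard_normal(images.shape)
                                 + 1j * rng.standard_normal(images.shape))
        series = KSpaceSeries(images_to_kspace(noisy))
        corrupted, _ = add_spikes(series, SpikeModel(n_spikes=1, seed=4))
        out = despike(corrupted, DespikeConfig(kappa=3))
        std_before = background_noise_std(reconstruct_images(corrupted))
        std_after = background_noise_std(reconstruct_images(out.clean))
        assert std_after < std_before

    def test_window_larger_than_grid_rejected(self, lowrank_series):
        with pytest.raises(ValueError):
            despike(lowrank_series, DespikeConfig(kappa=3, center_window=64))

    def test_multiframe_needs_two_frames(self, rng):
        series = KSpaceSeries(complex_randn(rng, 16, 16, 1))
        with pytest.raises(ValueError):
            despike(series, DespikeConfig(kappa=3))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DespikeConfig(kappa=0)
        with pytest.raises(ValueError):
            DespikeConfig(kappa=3, center_window=7)
        with pytest.raises(ValueError):
            DespikeConfig(kappa=3, connectivity=6)


class TestDespikeGrouped:
    def test_equals_manual_per_group_calls(self, rng):
        base = np.zeros((24, 24))
        base[6:18, 8:16] = 1.0
        images = np.concatenate([
            2.0 * base[:, :, None] * np.ones((1, 1, 3)),
            base[:, :, None] * np.linspace(0.9, 1.1, 5)[None, None, :],
        ], axis=2)
        noisy = images + 0.01 * (rng.standard_normal(images.shape)
                                 + 1j * rng.standard_normal(images.shape))
        labels = [0.0] * 3 + [1000.0] * 5
        series = KSpaceSeries(images_to_kspace(noisy), frame_labels=labels)
        cfg = DespikeConfig(kappa=5)
        clean, spikes, diags = despike_grouped(series, {0.0: 6, 1000.0: 5}, cfg)
        assert set(diags) == {0.0, 1000.0}
        assert diags[0.0].kappa == 6
        for lab, idx in [(0.0, slice(0, 3)), (1000.0, slice(3, 8))]:
            sub = KSpaceSeries(series.data[:, :, idx],
                               frame_labels=[lab] * (idx.stop - idx.start))
            manual = despike(sub, DespikeConfig(kappa={0.0: 6, 1000.0: 5}[lab]))
            np.testing.assert_array_equal(clean.data[:, :, idx],
                                          manual.clean.data)
            np.testing.assert_array_equal(spikes.data[:, :, idx],
                                          manual.spikes.data)

    def test_requires_labels(self, lowrank_series):
        with pytest.raises(ValueError):
            despike_grouped(lowrank_series, {}, DespikeConfig(kappa=3))
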