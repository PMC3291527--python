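"""Synthetic generators: planted structure, spectra, patch plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robustsc.gabor import GaborParams, gabor_patch
from robustsc.synthetic import (
    ImageStack,
    PatchMatrix,
    concatenate_temporal,
    extract_patches,
    generate_gabor_patch,
    generate_lowrank_sparse,
    generate_pink_noise_images,
    generate_planted_codes,
    normalize_patches,
)
from robustsc.dictionary import init_dictionary


class TestPlantedLowRankSparse:
    def test_exact_additive_decomposition_and_sparsity_count(self):
        pl = generate_lowrank_sparse(40, 60, 4, 0.1, magnitude=2.0, seed=0)
        assert np.array_equal(pl.M, pl.L0 + pl.S0)
        assert np.count_nonzero(pl.S0) == int(0.1 * 40 * 60)
        assert set(np.unique(np.abs(pl.S0[pl.S0 != 0]))) == {2.0}

    def test_planted_rank_matches_svd(self):
        pl = generate_lowrank_sparse(50, 50, 3, 0.1, seed=1)
        s = np.linalg.svd(pl.L0, compute_uv=False)
        assert np.sum(s > 1e-10 * s[0]) == 3

    def test_zero_rank_and_zero_sparsity_limits(self):
        assert not generate_lowrank_sparse(10, 10, 0, 0.1, seed=2).L0.any()
        pl = generate_lowrank_sparse(10, 10, 2, 0.0, seed=3)
        assert not pl.S0.any()
        assert np.array_equal(pl.M, pl.L0)

    def test_rank_exceeding_dimension_rejected(self):
        with pytest.raises(ValueError):
            generate_lowrank_sparse(5, 8, 6, 0.1)

    def test_seeded_determinism(self):
        a = generate_lowrank_sparse(20, 30, 2, 0.05, seed=9)
        b = generate_lowrank_sparse(20, 30, 2, 0.05, seed=9)
        assert np.array_equal(a.M, b.M)


class TestPinkNoiseImages:
    def test_power_law_slope_of_radial_spectrum(self):
        from robustsc.analysis import radial_amplitude_spectrum

        stack = generate_pink_noise_images(200, 64, 1.0, seed=2)
        freq, curve = radial_amplitude_spectrum(stack.pixels, n_bins=32)
        band = (freq > 0.05) & (freq < 0.35)
        slope = np.polyfit(np.log(freq[band]), np.log(curve[band]), 1)[0]
        assert abs(slope + 1.0) < 0.1

    def test_zero_exponent_gives_flat_spectrum(self):
        from robustsc.analysis import radial_amplitude_spectrum

        stack = generate_pink_noise_images(300, 32, 0.0, seed=3)
        freq, curve = radial_amplitude_spectrum(stack.pixels, n_bins=8)
        mid = curve[(freq > 0.05) & (freq < 0.45)]
        assert mid.min() > 0.9 * mid.max()

    def test_count_and_realness(self):
        stack = generate_pink_noise_images(1, 16, 1.0, seed=4)
        assert stack.pixels.shape == (16, 16, 1)
        assert np.isrealobj(stack.pixels)


class TestExtractPatches:
    def test_full_size_patch_is_row_major_flattening(self, rng):
        img = rng.standard_normal((6, 6, 1))
        P = extract_patches(ImageStack(pixels=img), (6, 6), 1, seed=0)
        assert np.array_equal(P.data[:, 0], img[:, :, 0].ravel(order="C"))

    def test_constant_image_gives_constant_columns(self):
        img = np.full((8, 8, 2), 3.0)
        P = extract_patches(ImageStack(pixels=img), (3, 3), 10, seed=1)
        assert np.allclose(P.data, 3.0)

    def test_determinism_and_oversize_rejection(self, rng):
        stack = ImageStack(pixels=rng.standard_normal((10, 10, 3)))
        a = extract_patches(stack, (4, 4), 20, seed=5)
        b = extract_patches(stack, (4, 4), 20, seed=5)
        assert np.array_equal(a.data, b.data)
        with pytest.raises(ValueError):
            extract_patches(stack, (11, 4), 1, seed=0)


class TestNormalizePatches:
    def test_population_convention_and_two_point_column(self):
        P = PatchMatrix(data=np.array([[0.0], [2.0]]), patch_shape=(2, 1))
        out = normalize_patches(P)
        assert np.allclose(out.data[:, 0], [-1.0, 1.0])

    def test_idempotence(self, rng):
        P = PatchMatrix(data=rng.standard_normal((16, 30)), patch_shape=(4, 4))
        once = normalize_patches(P)
        twice = normalize_patches(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_constant_column_dropped(self, rng):
        data = rng.standard_normal((9, 5))
        data[:, 2] = 7.0
        out = normalize_patches(PatchMatrix(data=data, patch_shape=(3, 3)))
        assert out.data.shape[1] == 4
        assert np.allclose(out.data.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(out.data.std(axis=0), 1, atol=1e-6)

    def test_all_rejected_raises(self):
        data = np.ones((4, 3))
        with pytest.raises(ValueError):
            normalize_patches(PatchMatrix(data=data, patch_shape=(2, 2)))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotence_property(self, seed):
        rng = np.random.default_rng(seed)
        P = PatchMatrix(data=rng.standard_normal((8, 5)), patch_shape=(2, 4))
        once = normalize_patches(P)
        assert np.allclose(once.data, normalize_patches(once).data, atol=1e-12)


class TestTemporalConcatenation:
    def test_single_frame_reduces_to_static_normalization(self, rng):
        frame = PatchMatrix(data=rng.standard_normal((16, 7)), patch_shape=(4, 4))
        out = concatenate_temporal([frame], 1)
        assert out.patch_shape == (4, 4, 1)
        assert np.allclose(out.data, normalize_patches(frame).data)

    def test_sixteen_8x8_frames_give_1024_rows(self, rng):
        frames = [
            PatchMatrix(data=rng.standard_normal((64, 5)), patch_shape=(8, 8))
            for _ in range(16)
        ]
        out = concatenate_temporal(frames, 16)
        assert out.data.shape == (1024, 5)
        assert out.patch_shape == (8, 8, 16)

    def test_frame_reordering_permutes_row_blocks(self, rng):
        frames = [
            PatchMatrix(data=rng.standard_normal((9, 4)), patch_shape=(3, 3))
            for _ in range(3)
        ]
        fwd = concatenate_temporal(frames, 3)
        rev = concatenate_temporal(frames[::-1], 3)
        assert np.allclose(fwd.data[0:9], rev.data[18:27])
        assert np.allclose(fwd.data[18:27], rev.data[0:9])

    def test_ragged_frames_rejected(self, rng):
        frames = [
            PatchMatrix(data=rng.standard_normal((9, 4)), patch_shape=(3, 3)),
            PatchMatrix(data=rng.standard_normal((16, 4)), patch_shape=(4, 4)),
        ]
        with pytest.raises(ValueError):
            concatenate_temporal(frames, 2)


class TestPlantedCodes:
    def test_noiseless_residual_and_exact_sparsity(self):
        D = init_dictionary(10, 40, seed=0)
        X, codes = generate_planted_codes(D, k=3, T=25, seed=1)
        assert np.allclose(X.data, D.A @ codes)
        assert np.all(np.count_nonzero(codes, axis=0) == 3)

    def test_k_zero_is_pure_noise_and_k_over_m_rejected(self):
        D = init_dictionary(6, 12, seed=0)
        X, codes = generate_planted_codes(D, k=0, T=5, noise_sigma=1.0, seed=2)
        assert not codes.any()
        assert X.data.any()
        with pytest.raises(ValueError):
            generate_planted_codes(D, k=13, T=5)


class TestGaborPatch:
    def test_zero_frequency_zero_phase_is_pure_envelope(self):
        p = GaborParams(x0=5, y0=5, theta=0.3, f=0.0, phi=0.0,
                        sigma_x=2.0, sigma_y=3.0)
        patch = generate_gabor_patch(p, 12)
        assert patch.max() <= 1.0 + 1e-12
        assert np.all(patch > 0)

    def test_theta_pi_phase_negation_symmetry(self):
        p = GaborParams(x0=4.5, y0=6.0, theta=0.7, f=0.2, phi=1.1,
                        sigma_x=2.0, sigma_y=1.5)
        q = GaborParams(x0=4.5, y0=6.0, theta=0.7 + np.pi, f=0.2, phi=-1.1,
                        sigma_x=2.0, sigma_y=1.5)
        assert np.allclose(generate_gabor_patch(p, 12),
                           generate_gabor_patch(q, 12), atol=1e-12)

    def test_isotropic_envelope_rotation_invariance(self):
        # with sigma_x == sigma_y and f == 0 the patch depends only on the
        # radial distance, so any orientation gives the same envelope
        a = GaborParams(x0=5, y0=5, theta=0.0, f=0.0, phi=0.0,
                        sigma_x=2.0, sigma_y=2.0)
        b = GaborParams(x0=5, y0=5, theta=1.1, f=0.0, phi=0.0,
                        sigma_x=2.0, sigma_y=2.0)
        assert np.allclose(gabor_patch(a, 11), gabor_patch(b, 11), atol=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            GaborParams(x0=0, y0=0, theta=0, f=0.1, phi=0,
                        sigma_x=0.0, sigma_y=1.0)
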