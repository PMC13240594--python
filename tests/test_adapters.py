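"""Adapter stack mathematics: FFT stream, bottleneck geometry, residual
identity, frozen-encoder contract and trainable-parameter accounting."""

import numpy as np
import pytest

from cryofsl.adapters import (AdapterStackConfig, adapter_forward,
                              attach_adapters, build_adapter_stack,
                              count_trainable_params, highpass_fft_filter,
                              prepare_fft_stream)
from cryofsl.autodiff import Tensor, gelu_scalar
from cryofsl.encoder import build_surrogate_encoder, get_encoder_builder

SMALL_DIMS = (16, 32, 48, 64)
SMALL_DEPTHS = (1, 1, 2, 1)


def small_config(**kw):
    kw.setdefault("stage_dims", SMALL_DIMS)
    kw.setdefault("stage_depths", SMALL_DEPTHS)
    kw.setdefault("reduction", 4)
    return AdapterStackConfig(**kw)


def _oracle_highpass(image, cutoff_fraction):
    """Independent oracle: explicit FFT, mask multiply, inverse FFT."""
    h, w = image.shape
    spectrum = np.fft.fftshift(np.fft.fft2(image))
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    fy = (yy - cy) / h
    fx = (xx - cx) / w
    fc = cutoff_fraction * 0.5
    mask = 1.0 - np.exp(-(fy ** 2 + fx ** 2) / (2.0 * fc * fc))
    return np.real(np.fft.ifft2(np.fft.ifftshift(spectrum * mask)))


class TestHighpassFilter:
    def test_constant_image_maps_to_zero(self):
        out = highpass_fft_filter(np.full((32, 32), 5.0), 0.25)
        assert np.abs(out).max() < 1e-8

    def test_matches_direct_fft_oracle_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            img = rng.normal(size=(32, 32))
            ours = highpass_fft_filter(img, 0.25)
            ref = _oracle_highpass(img, 0.25)
            assert np.abs(ours - ref).max() / np.abs(ref).max() < 1e-6

    def test_checkerboard_passes_nearly_unchanged(self):
        yy, xx = np.mgrid[0:64, 0:64]
        checker = ((xx + yy) % 2).astype(float)  # period-2: at Nyquist
        out = highpass_fft_filter(checker, 0.25)
        corr = np.corrcoef(out.ravel(), checker.ravel())[0, 1]
        assert corr > 0.99

    def test_output_mean_is_zero(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(48, 48))
        out = highpass_fft_filter(img, 0.3)
        assert abs(out.sum()) < 1e-6 * img.size

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            highpass_fft_filter(np.full((8, 8), np.nan), 0.25)
        with pytest.raises(ValueError):
            highpass_fft_filter(np.zeros((8, 8)), 1.5)


class TestFftStream:
    def test_shapes_follow_stage_grid(self):
        cfg = small_config()
        shapes = [(32, 32), (16, 16), (8, 8), (4, 4)]
        streams = prepare_fft_stream(np.random.default_rng(0).normal(size=(128, 128)),
                                     cfg, shapes)
        assert [s.shape for s in streams] == shapes

    def test_constant_input_gives_all_zero_streams(self):
        streams = prepare_fft_stream(np.full((64, 64), 3.3), small_config(),
                                     [(16, 16), (8, 8)])
        for s in streams:
            assert np.all(s == 0.0)

    def test_streams_are_standardized(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0  # impulse
        streams = prepare_fft_stream(img, small_config(), [(16, 16), (8, 8)])
        for s in streams:
            assert abs(s.mean()) < 1e-6
            assert s.std() == pytest.approx(1.0, abs=1e-6)

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            prepare_fft_stream(np.zeros((64, 64)), small_config(), [(17, 16)])


class TestAdapterStack:
    def test_default_config_counts_48_unshared_4_shared(self):
        stack = build_adapter_stack(AdapterStackConfig())
        assert stack.n_unshared == 48  # 2 + 6 + 36 + 4
        assert stack.n_shared == 4

    def test_default_bottleneck_dims_floor_of_thirty_second(self):
        assert AdapterStackConfig().bottleneck_dims == (4, 9, 18, 36)

    def test_minimal_single_stage_instance(self):
        cfg = AdapterStackConfig(stage_dims=(32,), stage_depths=(1,), reduction=32)
        stack = build_adapter_stack(cfg)
        assert stack.n_unshared == 1
        assert stack.unshared[(0, 0)][0].data.shape == (1, 1)

    def test_vanishing_bottleneck_rejected_unless_clamped(self):
        with pytest.raises(ValueError, match="bottleneck"):
            AdapterStackConfig(stage_dims=(16, 32), stage_depths=(1, 1),
                               reduction=32)
        cfg = AdapterStackConfig(stage_dims=(16, 32), stage_depths=(1, 1),
                                 reduction=32, clamp_bottleneck=True)
        assert cfg.bottleneck_dims == (1, 1)

    def test_shared_up_projections_start_at_zero(self):
        stack = build_adapter_stack(small_config(), seed=3)
        for W, b in stack.shared_up:
            assert np.all(W.data == 0.0) and np.all(b.data == 0.0)


class TestAdapterForward:
    def test_zero_shared_projection_gives_exact_identity(self):
        cfg = small_config()
        stack = build_adapter_stack(cfg, seed=1)
        rng = np.random.default_rng(2)
        feat = rng.normal(size=(8, 8, 16))
        stream = rng.normal(size=(8, 8))
        out = adapter_forward(feat, stream, stack, stage=0, block=0)
        np.testing.assert_array_equal(out.data, feat)

    def test_shape_preserved_with_random_params(self):
        cfg = AdapterStackConfig(stage_dims=(144,), stage_depths=(1,), reduction=32)
        stack = build_adapter_stack(cfg, seed=0)
        stack.shared_up[0][0].data[:] = 0.01
        feat = np.random.default_rng(0).normal(size=(8, 8, 144))
        out = adapter_forward(feat, np.zeros((8, 8)), stack, 0, 0)
        assert out.data.shape == (8, 8, 144)
        assert np.abs(out.data - feat).max() > 0

    def test_scalar_case_hand_composed(self):
        # 1x1 spatial grid, d=1, all weights 1, biases 0, feat=0, fft=0:
        # shared(GELU(unshared(0 + 0))) = GELU(0) = 0, residual output 0
        cfg = AdapterStackConfig(stage_dims=(1,), stage_depths=(1,), reduction=1)
        stack = build_adapter_stack(cfg, seed=0)
        for pairs in (stack.fft_proj, stack.emb_proj, stack.shared_up):
            pairs[0][0].data[:] = 1.0
            pairs[0][1].data[:] = 0.0
        stack.unshared[(0, 0)][0].data[:] = 1.0
        stack.unshared[(0, 0)][1].data[:] = 0.0
        out = adapter_forward(np.zeros((1, 1, 1)), np.zeros((1, 1)), stack, 0, 0)
        assert out.data[0, 0, 0] == 0.0
        # nonzero scalar input: residual + shared*GELU(unshared*(feat + fft))
        feat, fft = 0.7, -0.2
        out = adapter_forward(np.full((1, 1, 1), feat), np.full((1, 1), fft),
                              stack, 0, 0)
        assert out.data[0, 0, 0] == pytest.approx(feat + gelu_scalar(feat + fft),
                                                  abs=1e-12)

    def test_out_of_range_indices_rejected(self):
        stack = build_adapter_stack(small_config(), seed=0)
        feat = np.zeros((4, 4, 16))
        with pytest.raises(IndexError):
            adapter_forward(feat, np.zeros((4, 4)), stack, stage=9, block=0)
        with pytest.raises(IndexError):
            adapter_forward(feat, np.zeros((4, 4)), stack, stage=0, block=5)

    def test_residual_norm_bounded_by_operator_norms(self):
        cfg = small_config()
        rng = np.random.default_rng(7)
        stack = build_adapter_stack(cfg, seed=7)
        # random weights, zero biases: ||out - in||_F admits a product bound
        for pairs in (stack.fft_proj, stack.emb_proj, stack.shared_up):
            for W, b in pairs:
                W.data = rng.normal(0, 0.3, W.data.shape)
                b.data[:] = 0.0
        for W, b in stack.unshared.values():
            W.data = rng.normal(0, 0.3, W.data.shape)
            b.data[:] = 0.0
        feat = rng.normal(size=(8, 8, 16))
        stream = rng.normal(size=(8, 8))
        out = adapter_forward(feat, stream, stack, 0, 0).data
        sn = lambda W: np.linalg.norm(W.data, 2)
        gelu_lipschitz = 1.13
        bound = sn(stack.shared_up[0][0]) * gelu_lipschitz * sn(stack.unshared[(0, 0)][0]) * (
            sn(stack.emb_proj[0][0]) * np.linalg.norm(feat)
            + sn(stack.fft_proj[0][0]) * np.linalg.norm(stream))
        assert np.linalg.norm(out - feat) <= bound + 1e-9


class TestSurrogateEncoder:
    def test_stage_shape_arithmetic(self):
        enc = build_surrogate_encoder((8, 16, 32, 64), (1, 1, 2, 1), patch_stride=4)
        assert enc.stage_shapes((64, 64)) == [(16, 16), (8, 8), (4, 4), (2, 2)]

    def test_deterministic_under_seed(self):
        img = np.random.default_rng(0).normal(size=(64, 64))
        a = build_surrogate_encoder(seed=5).forward(img)
        b = build_surrogate_encoder(seed=5).forward(img)
        for ta, tb in zip(a, b):
            assert ta.data.tobytes() == tb.data.tobytes()

    def test_frozen_by_default(self):
        enc = build_surrogate_encoder()
        assert enc.frozen
        assert all(not p.requires_grad for p in enc.parameters())

    def test_registry_resolves_surrogate_and_rejects_unknown(self):
        assert get_encoder_builder("surrogate") is build_surrogate_encoder
        with pytest.raises(KeyError, match="unknown encoder"):
            get_encoder_builder("resnet")


class TestAttachAdapters:
    def test_identity_at_init_propagates_through_encoder(self):
        enc = build_surrogate_encoder(SMALL_DIMS, SMALL_DEPTHS, 4, seed=3)
        stack = build_adapter_stack(small_config(), seed=5)
        adapted = attach_adapters(enc, stack)
        img = np.random.default_rng(0).normal(size=(64, 64))
        plain = enc.forward(img)
        wrapped = adapted.forward(img)
        for a, b in zip(plain, wrapped):
            assert np.abs(a.data - b.data).max() < 1e-6

    def test_random_stack_changes_output_and_detach_restores(self):
        enc = build_surrogate_encoder(SMALL_DIMS, SMALL_DEPTHS, 4, seed=3)
        stack = build_adapter_stack(small_config(), seed=5)
        img = np.random.default_rng(1).normal(size=(64, 64))
        cached = [t.data.copy() for t in enc.forward(img)]
        for W, _ in stack.shared_up:
            W.data = np.random.default_rng(9).normal(0, 0.1, W.data.shape)
        adapted = attach_adapters(enc, stack)
        modified = adapted.forward(img)
        assert any(np.abs(a - b.data).max() > 1e-9
                   for a, b in zip(cached, modified))
        restored = adapted.detach().forward(img)
        for a, b in zip(cached, restored):
            np.testing.assert_array_equal(a, b.data)

    def test_dim_mismatch_names_stage(self):
        enc = build_surrogate_encoder((16, 32, 48, 64), SMALL_DEPTHS, 4)
        cfg = AdapterStackConfig(stage_dims=(16, 32, 40, 64),
                                 stage_depths=SMALL_DEPTHS, reduction=4)
        with pytest.raises(ValueError, match="stage 2"):
            attach_adapters(enc, build_adapter_stack(cfg))


class TestParameterCount:
    def test_default_stack_matches_closed_form(self):
        cfg = AdapterStackConfig()
        stack = build_adapter_stack(cfg)
        expected = 0
        for D, depth, d in zip(cfg.stage_dims, cfg.stage_depths,
                               cfg.bottleneck_dims):
            expected += d * (d + 1) * depth    # unshared W + b per block
            expected += D * d + d              # embedding down-projection
            expected += d * D + D              # shared up-projection
            expected += d + d                  # fft projection (1 -> d) + bias
        assert count_trainable_params(stack) == expected

    def test_frozen_encoder_contributes_nothing(self):
        stack = build_adapter_stack(small_config())
        narrow = build_surrogate_encoder(SMALL_DIMS, SMALL_DEPTHS, 4)
        wide = build_surrogate_encoder(tuple(2 * d for d in SMALL_DIMS),
                                       SMALL_DEPTHS, 4)
        assert (count_trainable_params([stack, narrow])
                == count_trainable_params([stack, wide])
                == count_trainable_params(stack))

    def test_zero_stage_config_counts_zero(self):
        cfg = AdapterStackConfig(stage_dims=(), stage_depths=(), reduction=1)
        assert count_trainable_params(build_adapter_stack(cfg)) == 0
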