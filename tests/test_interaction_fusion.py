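"""Gated fusion convexity, attention pooling simplex properties, Z assembly."""

import numpy as np
import pytest

from kanpm._autodiff import Tensor
from kanpm.interaction_fusion import (
    GatedFusion,
    InteractionFusion,
    LinearAttentionPool,
    cross_attention,
    masked_mean,
)
from kanpm.nn import DTYPE


def _t(x):
    return Tensor(np.asarray(x, dtype=DTYPE))


class TestGatedFusion:
    def test_identical_inputs_are_fixed_point(self, rng):
        fuse = GatedFusion(8, np.random.default_rng(0))
        h = _t(rng.standard_normal((3, 8)))
        np.testing.assert_allclose(fuse(h, h).data, h.data, rtol=1e-5)

    def test_zero_gate_weight_gives_elementwise_mean(self, rng):
        fuse = GatedFusion(8, np.random.default_rng(1))
        fuse.gate.weight.data[:] = 0.0
        hd = _t(rng.standard_normal((4, 8)))
        hp = _t(rng.standard_normal((4, 8)))
        np.testing.assert_allclose(fuse(hd, hp).data,
                                   (hd.data + hp.data) / 2, rtol=1e-5)

    def test_output_coordinatewise_between_inputs(self, rng):
        fuse = GatedFusion(16, np.random.default_rng(2))
        for _ in range(100):
            hd = rng.standard_normal((1, 16))
            hp = rng.standard_normal((1, 16))
            out = fuse(_t(hd), _t(hp)).data
            lo = np.minimum(hd, hp) - 1e-5
            hi = np.maximum(hd, hp) + 1e-5
            assert (out >= lo).all() and (out <= hi).all()

    def test_width_mismatch_rejected(self, rng):
        fuse = GatedFusion(8, np.random.default_rng(3))
        with pytest.raises(ValueError, match="mismatch"):
            fuse(_t(np.zeros((2, 8))), _t(np.zeros((2, 6))))


class TestLinearAttentionPool:
    def test_single_token_identity(self, rng):
        pool = LinearAttentionPool(8, 4, np.random.default_rng(4))
        f = rng.standard_normal((2, 1, 8))
        np.testing.assert_allclose(pool(_t(f)).data, f[:, 0], rtol=1e-5)

    def test_identical_tokens_identity(self, rng):
        pool = LinearAttentionPool(8, 4, np.random.default_rng(5))
        tok = rng.standard_normal((1, 1, 8))
        f = np.repeat(tok, 5, axis=1)
        np.testing.assert_allclose(pool(_t(f)).data, tok[:, 0], rtol=1e-5)

    def test_weights_form_masked_simplex(self, rng):
        pool = LinearAttentionPool(8, 4, np.random.default_rng(6))
        f = rng.standard_normal((3, 7, 8))
        mask = np.ones((3, 7), dtype=bool)
        mask[0, 4:] = False
        alpha = pool.weights(f.astype(DTYPE), mask)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, rtol=1e-5)
        assert (alpha[0, 4:] < 1e-12).all()
        assert (alpha >= 0).all()

    def test_pooled_output_permutation_invariant(self, rng):
        pool = LinearAttentionPool(6, 3, np.random.default_rng(7))
        f = rng.standard_normal((1, 9, 6)).astype(DTYPE)
        mask = rng.random((1, 9)) < 0.7
        mask[0, 0] = True
        base = pool(_t(f), mask).data
        for _ in range(5):
            perm = rng.permutation(9)
            out = pool(_t(f[:, perm]), mask[:, perm]).data
            np.testing.assert_allclose(out, base, rtol=1e-4, atol=1e-6)

    def test_all_masked_rejected(self, rng):
        pool = LinearAttentionPool(4, 2, np.random.default_rng(8))
        with pytest.raises(ValueError, match="mask"):
            pool(_t(np.zeros((1, 3, 4))), np.zeros((1, 3), dtype=bool))


class TestCrossAttention:
    def test_identical_vectors_identity(self, rng):
        pool = LinearAttentionPool(8, 4, np.random.default_rng(9))
        a = _t(rng.standard_normal((2, 8)))
        np.testing.assert_allclose(cross_attention(a, a, pool).data, a.data,
                                   rtol=1e-5)

    def test_output_in_segment_between_inputs(self, rng):
        pool = LinearAttentionPool(8, 4, np.random.default_rng(10))
        ad_ = rng.standard_normal((1, 8))
        at_ = rng.standard_normal((1, 8))
        out = cross_attention(_t(ad_), _t(at_), pool).data
        lo = np.minimum(ad_, at_) - 1e-5
        hi = np.maximum(ad_, at_) + 1e-5
        assert (out >= lo).all() and (out <= hi).all()

    def test_deterministic_repeated_eval(self, rng):
        pool = LinearAttentionPool(8, 4, np.random.default_rng(11))
        a = _t(rng.standard_normal((2, 8)))
        b = _t(rng.standard_normal((2, 8)))
        np.testing.assert_array_equal(cross_attention(a, b, pool).data,
                                      cross_attention(a, b, pool).data)


class TestAssembleJoint:
    def _inputs(self, rng, dim=8):
        hd = _t(rng.standard_normal((2, dim)))
        hp = _t(rng.standard_normal((2, dim)))
        fs = _t(rng.standard_normal((2, 5, dim)))
        ft = _t(rng.standard_normal((2, 7, dim)))
        ms = np.ones((2, 5), dtype=bool)
        mt = np.ones((2, 7), dtype=bool)
        return dict(h_d=hd, h_p=hp, f_s=fs, mask_s=ms, f_t=ft, mask_t=mt)

    def test_full_model_width_is_four_blocks(self, rng):
        fusion = InteractionFusion(8, 8, 4, np.random.default_rng(12))
        z = fusion(**self._inputs(rng))
        assert z.shape == (2, 32)
        assert fusion.z_dim == 32

    def test_without_sequence_single_block(self, rng):
        fusion = InteractionFusion(8, 8, 4, np.random.default_rng(13),
                                   use_sequence=False)
        z = fusion(**{**self._inputs(rng), "f_s": None, "mask_s": None,
                      "f_t": None, "mask_t": None})
        assert z.shape == (2, 8)

    def test_without_graph_three_blocks(self, rng):
        fusion = InteractionFusion(8, 8, 4, np.random.default_rng(14),
                                   use_graph=False)
        z = fusion(**{**self._inputs(rng), "h_d": None, "h_p": None})
        assert z.shape == (2, 24)

    def test_without_linear_attention_uses_masked_means(self, rng):
        fusion = InteractionFusion(8, 8, 4, np.random.default_rng(15),
                                   use_linear_attention=False)
        inputs = self._inputs(rng)
        z = fusion(**inputs)
        assert z.shape == (2, 24)
        mm = masked_mean(inputs["f_s"], inputs["mask_s"]).data
        np.testing.assert_allclose(z.data[:, 8:16], mm, rtol=1e-5)

    def test_without_gated_fusion_linear_reduction(self, rng):
        fusion = InteractionFusion(8, 8, 4, np.random.default_rng(16),
                                   use_gated_fusion=False)
        z = fusion(**self._inputs(rng))
        assert z.shape == (2, 32)

    def test_block_order_is_stable(self, rng):
        fusion = InteractionFusion(8, 8, 4, np.random.default_rng(17))
        inputs = self._inputs(rng)
        z = fusion(**inputs).data
        a_g = fusion.gated(inputs["h_d"], inputs["h_p"]).data
        np.testing.assert_allclose(z[:, :8], a_g, rtol=1e-6)
        swapped = fusion(**{**inputs, "h_d": inputs["h_p"],
                            "h_p": inputs["h_d"]}).data
        assert not np.allclose(z[:, :8], swapped[:, :8])

    def test_all_blocks_off_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            InteractionFusion(8, 8, 4, np.random.default_rng(18),
                              use_graph=False, use_sequence=False)
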