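"""Global branch: token bookkeeping, reduction/aggregation, conditioning,
spatial projection, and frozen-backbone behaviour."""

import numpy as np
import pytest

from busseg import autodiff as ad
from busseg.global_branch import GlobalBranch, ToyViT
from busseg.layers import parameter_checksum


@pytest.fixture(scope="module")
def backbone():
    return ToyViT(width=32, n_layers=2, n_heads=4, seed=3)


@pytest.fixture()
def branch(backbone, rng):
    return GlobalBranch(backbone, layer_ids=(1, 2), reduced_width=16,
                        cond_width=16, out_channels=16, rng=rng, n_upsample=3)


def test_token_count_352_side(backbone):
    images = np.zeros((1, 3, 352, 352), dtype=np.float32)
    stack = backbone.tokens(images, (1,))
    assert 352 // 16 == 22
    assert stack.n_tokens == 1 + 22 * 22 == 485


def test_token_count_96_side(backbone):
    stack = backbone.tokens(np.zeros((1, 3, 96, 96), dtype=np.float32), (1,))
    assert stack.n_tokens == 1 + (96 // 16) ** 2 == 37


@pytest.mark.parametrize("side", [96, 160, 352])
def test_token_bookkeeping_all_sides(backbone, side):
    stack = backbone.tokens(np.zeros((1, 3, side, side), dtype=np.float32), (2,))
    assert stack.n_tokens - 1 == (side // 16) ** 2


def test_frozen_backbone_deterministic(backbone, rng):
    images = rng.random((2, 3, 96, 96)).astype(np.float32)
    s1 = backbone.tokens(images, (1, 2))
    s2 = backbone.tokens(images, (1, 2))
    for j in (1, 2):
        np.testing.assert_array_equal(s1.layers[j], s2.layers[j])


def test_reduce_and_aggregate_matches_matmul_sum(branch, backbone, rng):
    images = rng.random((2, 3, 96, 96)).astype(np.float32)
    stack = backbone.tokens(images, branch.layer_ids)
    reduced = branch.reduce_and_aggregate(stack)
    expected = np.zeros_like(reduced.values.data)
    for red, j in zip(branch.reducers, branch.layer_ids):
        expected = expected + (stack.layers[j][:, 1:, :] @ red.weight.data
                               + red.bias.data)
    np.testing.assert_allclose(reduced.values.data, expected, rtol=1e-5, atol=1e-6)
    assert reduced.values.shape == (2, 36, 16)  # class token removed


def test_zero_reducers_give_zero_tokens(branch, backbone, rng):
    for red in branch.reducers:
        red.weight.data[:] = 0.0
        red.bias.data[:] = 0.0
    stack = backbone.tokens(rng.random((1, 3, 96, 96)).astype(np.float32),
                            branch.layer_ids)
    reduced = branch.reduce_and_aggregate(stack)
    assert np.all(reduced.values.data == 0.0)


def test_conditioning_identity_at_init(branch, backbone, rng):
    """Freshly built conditioning maps give mul-vector 1 and add-vector 0."""
    stack = backbone.tokens(rng.random((2, 3, 96, 96)).astype(np.float32),
                            branch.layer_ids)
    tokens = branch.reduce_and_aggregate(stack)
    cond = branch.condition_tokens(tokens, ad.Tensor(rng.standard_normal((2, 16))
                                                     .astype(np.float32)))
    np.testing.assert_array_equal(cond.values.data, tokens.values.data)
    assert cond.conditioned


def test_conditioning_matches_per_channel_affine(branch, backbone, rng):
    branch.w_mul.weight.data = rng.standard_normal(branch.w_mul.weight.shape).astype(np.float32)
    branch.w_add.weight.data = rng.standard_normal(branch.w_add.weight.shape).astype(np.float32)
    ec = rng.standard_normal((2, 16)).astype(np.float32)
    stack = backbone.tokens(rng.random((2, 3, 96, 96)).astype(np.float32),
                            branch.layer_ids)
    tokens = branch.reduce_and_aggregate(stack)
    cond = branch.condition_tokens(tokens, ad.Tensor(ec))
    mul = ec @ branch.w_mul.weight.data + branch.w_mul.bias.data
    add = ec @ branch.w_add.weight.data + branch.w_add.bias.data
    expected = mul[:, None, :] * tokens.values.data + add[:, None, :]
    np.testing.assert_allclose(cond.values.data, expected, rtol=1e-5, atol=1e-6)


def test_double_conditioning_rejected(branch, backbone, rng):
    stack = backbone.tokens(rng.random((1, 3, 96, 96)).astype(np.float32),
                            branch.layer_ids)
    tokens = branch.reduce_and_aggregate(stack)
    ec = ad.Tensor(np.zeros((1, 16), dtype=np.float32))
    cond = branch.condition_tokens(tokens, ec)
    with pytest.raises(RuntimeError, match="conditioned"):
        branch.condition_tokens(cond, ec)


def test_tokens_to_map_shape_and_grid(branch, backbone, rng):
    stack = backbone.tokens(rng.random((2, 3, 96, 96)).astype(np.float32),
                            branch.layer_ids)
    tokens = branch.reduce_and_aggregate(stack)
    fmap = branch.tokens_to_map(tokens)
    # 36 tokens -> 6x6 grid -> 3 stride-2 transposed convs -> 48x48
    assert fmap.shape == (2, 16, 48, 48)


def test_non_square_token_count_rejected(branch):
    from busseg.global_branch import ReducedTokens
    bad = ReducedTokens(values=ad.Tensor(np.zeros((1, 35, 16), dtype=np.float32)))
    with pytest.raises(ValueError, match="square"):
        branch.tokens_to_map(bad)


def test_full_forward_shape_and_sfa_identity(branch, backbone, rng):
    images = rng.random((2, 3, 96, 96)).astype(np.float32)
    ec = ad.Tensor(rng.standard_normal((2, 16)).astype(np.float32))
    out_with = branch(images, ec, use_sfa=True)
    out_without = branch(images, ec, use_sfa=False)
    assert out_with.shape == (2, 16, 48, 48)
    # SFA and conditioning start as exact identities
    np.testing.assert_array_equal(out_with.data, out_without.data)


def test_aggregation_linear_in_each_layer(branch, rng):
    """Superposition: reducing (Z + Z') equals reducing Z plus reducing Z'."""
    from busseg.global_branch import TokenStack

    def stack_of(z1, z2):
        return TokenStack(layers={1: z1, 2: z2}, layer_ids=(1, 2),
                          n_tokens=z1.shape[1], width=z1.shape[2])

    za = rng.standard_normal((1, 10, 32)).astype(np.float32)
    zb = rng.standard_normal((1, 10, 32)).astype(np.float32)
    zc = rng.standard_normal((1, 10, 32)).astype(np.float32)
    out_sum = branch.reduce_and_aggregate(stack_of(za + zb, zc)).values.data
    out_a = branch.reduce_and_aggregate(stack_of(za, zc)).values.data
    out_b = branch.reduce_and_aggregate(stack_of(zb, np.zeros_like(zc))).values.data
    bias_only = branch.reduce_and_aggregate(
        stack_of(np.zeros_like(za), np.zeros_like(zc))).values.data
    np.testing.assert_allclose(out_sum, out_a + out_b - bias_only,
                               rtol=1e-4, atol=1e-5)


def test_training_step_leaves_backbone_untouched(tiny_model_config, encoder,
                                                 tiny_samples):
    """After one optimization step only trainable parts change; the frozen
    encoder stack and the text encoder are bit-identical."""
    from busseg.io_utils import to_model_input
    from busseg.layers import AdamW
    from busseg.model import build_model, segmentation_loss
    from busseg.text_embedding import encode_batch

    model = build_model(tiny_model_config, seed=0)
    bb = model.global_branch.backbone
    before = [a.copy() for a in (bb._wpe, bb._cls)]
    enc_before = encoder._proj.copy()
    x = to_model_input(np.stack([s.image for s in tiny_samples[:2]]))
    y = np.stack([s.mask for s in tiny_samples[:2]])[:, None].astype(np.float32)
    ec = encode_batch(["a small lesion"] * 2, encoder)
    el = encode_batch(["breast lesion"] * 2, encoder)
    opt = AdamW(model.trainable_parameters(), lr=1e-3)
    loss = segmentation_loss(model.forward(x, ec, el), y)
    model.zero_grad()
    loss.backward()
    opt.step()
    np.testing.assert_array_equal(bb._wpe, before[0])
    np.testing.assert_array_equal(bb._cls, before[1])
    np.testing.assert_array_equal(encoder._proj, enc_before)
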