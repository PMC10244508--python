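"""Assembled network: decoder wiring, ablation lattice, checkpoints."""

import numpy as np
import pytest

from acpseg import (ModelConfig, ACPTransUNet, build_variant, count_parameters,
                    tokens_to_grid, save_checkpoint, load_checkpoint, VARIANTS)
from acpseg.attention import cpat_param_count
from acpseg.model import DecoderBlock
from acpseg.nn import Tensor

rng = np.random.default_rng(21)


def test_tokens_to_grid_round_trip():
    from acpseg.encoder import sequentialize
    f = rng.normal(size=(2, 5, 4, 4))
    tokens, grid = sequentialize(Tensor(f), 1)
    assert np.allclose(tokens_to_grid(tokens, grid).data, f)


def test_tokens_to_grid_shapes_and_errors():
    z = Tensor(rng.normal(size=(1, 256, 8)))
    assert tokens_to_grid(z, (16, 16)).shape == (1, 8, 16, 16)
    assert tokens_to_grid(Tensor(rng.normal(size=(1, 1, 8))), (1, 1)).shape \
        == (1, 8, 1, 1)
    with pytest.raises(ValueError, match="grid"):
        tokens_to_grid(z, None)
    with pytest.raises(ValueError, match="tile"):
        tokens_to_grid(z, (3, 5))


def test_decoder_block_doubles_spatial_size():
    blk = DecoderBlock(8, 4, 6, "cpat", 4, "batch").initialize(
        np.random.default_rng(1))
    blk.eval()
    x = Tensor(rng.normal(size=(1, 8, 4, 4)))
    skip = Tensor(rng.normal(size=(1, 4, 8, 8)))
    assert blk(x, skip).shape == (1, 6, 8, 8)
    with pytest.raises(ValueError, match="spatial"):
        blk(x, Tensor(rng.normal(size=(1, 4, 6, 6))))
    with pytest.raises(ValueError, match="skip"):
        blk(x, None)


def test_decoder_attention_none_is_plain_block():
    blk = DecoderBlock(4, 0, 4, "none", 4, "batch").initialize(
        np.random.default_rng(2))
    blk.eval()
    from acpseg.nn import Identity
    assert isinstance(blk.attention, Identity)


def test_zero_weight_cpat_scales_conv_output_by_quarter():
    """With all CPAT weights zero both gates are sigmoid(0) = 0.5, so the
    block output is 0.25 x the conv-path output."""
    blk = DecoderBlock(4, 0, 4, "cpat", 4, "batch").initialize(
        np.random.default_rng(3))
    for _, p in blk.attention.named_parameters():
        p.data[...] = 0.0
    blk.eval()
    x = Tensor(rng.normal(size=(1, 4, 4, 4)))
    up = x.upsample_bilinear(2)
    conv_out = blk.conv(up).data
    assert np.allclose(blk(x).data, 0.25 * conv_out, rtol=1e-12)


def test_forward_preserves_input_size_64(tiny_model):
    out = tiny_model.predict(rng.random((2, 64, 64)))
    assert out.logits.shape == (2, 2, 64, 64)
    assert out.prob.shape == (2, 64, 64)
    assert out.mask.dtype == np.uint8
    assert np.all((out.prob >= 0) & (out.prob <= 1))
    assert np.array_equal(out.mask, (out.prob >= 0.5).astype(np.uint8))


def test_batch_permutation_permutes_outputs(tiny_model):
    x = rng.random((3, 64, 64))
    out = tiny_model.predict(x)
    out_r = tiny_model.predict(x[::-1])
    assert np.allclose(out.logits[::-1], out_r.logits, atol=1e-10)


@pytest.mark.parametrize("name,use_aspp,att", [
    ("transunet", False, "none"),
    ("transunet+aspp", True, "none"),
    ("transunet+aspp+c", True, "channel"),
    ("transunet+aspp+p", True, "pixel"),
    ("transunet+aspp+cpat", True, "cpat"),
    ("transunet+cpat", False, "cpat"),
])
def test_build_variant_table(name, use_aspp, att):
    cfg = build_variant(name, ModelConfig.tiny())
    assert cfg.use_aspp is use_aspp
    assert cfg.decoder_attention == att


def test_acp_is_alias_for_full_model():
    assert build_variant("acp", ModelConfig.tiny()) == \
        build_variant("transunet+aspp+cpat", ModelConfig.tiny())


def test_unknown_variant_lists_choices():
    with pytest.raises(ValueError, match="transunet\\+aspp"):
        build_variant("resnet")


def test_ablation_parameter_lattice():
    """Each added module strictly increases the count; removing CPAT
    restores the baseline count exactly (closed-form block total)."""
    base = ModelConfig.tiny()
    counts = {}
    for name in ("transunet", "transunet+aspp", "transunet+aspp+cpat"):
        counts[name] = count_parameters(ACPTransUNet(build_variant(name, base)))
    assert counts["transunet"] < counts["transunet+aspp"] \
        < counts["transunet+aspp+cpat"]
    cpat_total = sum(cpat_param_count(c, base.attention_reduction)
                     for c in base.decoder_widths)
    assert counts["transunet+aspp+cpat"] - counts["transunet+aspp"] == cpat_total


def test_parameter_count_invariant_under_weights():
    cfg = ModelConfig.tiny()
    m1 = ACPTransUNet(cfg)
    m2 = ACPTransUNet(cfg).initialize(np.random.default_rng(0))
    assert count_parameters(m1) == count_parameters(m2)


def test_zero_layer_transformer_count_decomposition():
    """Transformer layers account exactly for the difference between a
    0-layer and an n-layer build."""
    cfg0 = ModelConfig.tiny(encoder=__import__("acpseg").EncoderConfig.tiny(n_layers=0))
    cfg2 = ModelConfig.tiny()
    from acpseg.encoder import TransformerLayer
    per_layer = count_parameters(TransformerLayer(64, 4, 128))
    delta = count_parameters(ACPTransUNet(cfg2)) - count_parameters(ACPTransUNet(cfg0))
    assert delta == 2 * per_layer


def test_checkpoint_round_trip_bitwise(tmp_path, tiny_model):
    x = rng.random((1, 64, 64))
    before = tiny_model.predict(x).logits
    save_checkpoint(tiny_model, tmp_path / "ck.npz", extra={"note": "test"})
    restored = load_checkpoint(tmp_path / "ck.npz")
    restored.eval()
    after = restored.predict(x).logits
    assert np.array_equal(before, after)


def test_gradient_reaches_every_parameter_group(phantom_bench):
    """One backward pass touches every trainable tensor (no dead branches)."""
    from acpseg.train import segmentation_loss
    pairs, _ = phantom_bench
    model = ACPTransUNet(ModelConfig.tiny()).initialize(np.random.default_rng(13))
    x = Tensor(np.stack([p[1].pixels for p in pairs[:2]])[:, None])
    y = np.stack([p[2].labels for p in pairs[:2]])
    loss = segmentation_loss(model.forward_logits(x), y)
    loss.backward()
    dead = [n for n, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert dead == []
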