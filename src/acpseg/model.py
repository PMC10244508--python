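"""Full segmentation network and the ablation-variant factory.

The network is a U-shaped hybrid: the encoder of :mod:`acpseg.encoder`
produces transformer tokens plus three CNN skip maps; the tokens are
reshaped back onto the 1/16 grid and a cascaded decoder up-samples x2 four
times, concatenating the 1/8, 1/4 and 1/2 skips, with one attention block
(CPAT by default) after the conv pair of every decoder stage. A 1x1 head
emits two-class logits at full resolution.

Ablation variants toggle exactly one ingredient at a time: the ASPP block
in the encoder and the decoder attention kind (none / channel / pixel /
cpat), mirroring the "fix two, change one" grid.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn import (Module, Sequential, Identity, Conv2d, BatchNorm2d, GroupNorm,
                 ReLU, Tensor, concat)
from .encoder import EncoderConfig, HybridEncoder, unflatten
from .attention import ChannelAttention, PixelAttention, CPAT

__all__ = ["ModelConfig", "SegmentationOutput", "ACPTransUNet", "tokens_to_grid",
           "build_variant", "count_parameters", "VARIANTS",
           "save_checkpoint", "load_checkpoint"]

ATTENTION_KINDS = ("none", "channel", "pixel", "cpat")

VARIANTS = ("transunet", "transunet+aspp", "transunet+aspp+c", "transunet+aspp+p",
            "transunet+aspp+cpat", "transunet+cpat", "acp")


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture + ablation switches for one model build."""

    encoder: EncoderConfig = dataclasses.field(default_factory=EncoderConfig)
    use_aspp: bool = True
    decoder_attention: str = "cpat"
    decoder_widths: tuple[int, int, int, int] = (256, 128, 64, 16)
    head_width: int = 512
    n_classes: int = 2
    input_size: tuple[int, int] = (512, 512)
    attention_reduction: int = 16

    def __post_init__(self):
        if self.decoder_attention not in ATTENTION_KINDS:
            raise ValueError(f"decoder_attention must be one of {ATTENTION_KINDS}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.decoder_widths) != 4:
            raise ValueError("decoder has four stages; give four widths")

    @staticmethod
    def tiny(**overrides) -> "ModelConfig":
        """CPU-scale configuration: 64x64 input, D=64, two transformer layers."""
        base = dict(encoder=EncoderConfig.tiny(), decoder_widths=(32, 16, 16, 8),
                    head_width=64, input_size=(64, 64), attention_reduction=4)
        base.update(overrides)
        return ModelConfig(**base)


@dataclasses.dataclass
class SegmentationOutput:
    """Logits, foreground probability and the thresholded binary mask."""

    logits: np.ndarray          # (B, n_classes, H, W)
    prob: np.ndarray            # (B, H, W) foreground probability
    mask: np.ndarray            # (B, H, W) uint8, prob >= 0.5

    def __post_init__(self):
        if not np.all(np.isfinite(self.logits)):
            raise FloatingPointError("non-finite logits")


def tokens_to_grid(z: Tensor, grid_shape: tuple[int, int]) -> Tensor:
    """Reshape B x N x D tokens to a B x D x gh x gw feature map."""
    if grid_shape is None:
        raise ValueError("grid_shape is required to unflatten tokens")
    B, N, D = z.shape
    gh, gw = grid_shape
    if N != gh * gw:
        raise ValueError(f"{N} tokens do not tile a {gh}x{gw} grid")
    return unflatten(z, grid_shape, 1, D)


def _norm(channels: int, kind: str) -> Module:
    if kind == "batch":
        return BatchNorm2d(channels)
    return GroupNorm(min(8, channels), channels)


def _attention_block(kind: str, channels: int, reduction: int) -> Module:
    if kind == "none":
        return Identity()
    if kind == "channel":
        return _GateOnly(ChannelAttention(channels, reduction=reduction))
    if kind == "pixel":
        return _GateOnly(PixelAttention(channels))
    return CPAT(channels, reduction=reduction)


class _GateOnly(Module):
    """Wrap a map-producing attention module as gate(F) * F."""

    def __init__(self, att: Module):
        super().__init__()
        self.att = att

    def forward(self, f: Tensor) -> Tensor:
        return self.att(f) * f


class DecoderBlock(Module):
    """x2 bilinear upsample -> concat skip -> two 3x3 convs -> attention."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, attention: str,
                 reduction: int, norm: str):
        super().__init__()
        self.skip_ch = skip_ch
        c = in_ch + skip_ch
        self.conv = Sequential(
            Conv2d(c, out_ch, 3, padding=1), _norm(out_ch, norm), ReLU(),
            Conv2d(out_ch, out_ch, 3, padding=1), _norm(out_ch, norm), ReLU())
        self.attention = _attention_block(attention, out_ch, reduction)

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        x = x.upsample_bilinear(2)
        if (skip is None) != (self.skip_ch == 0):
            raise ValueError("skip presence must match block configuration")
        if skip is not None:
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(f"skip spatial size {skip.shape[2:]} does not "
                                 f"match upsampled size {x.shape[2:]}")
            x = concat([x, skip], axis=1)
        return self.attention(self.conv(x))


class ACPTransUNet(Module):
    """The assembled encoder-decoder network."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        enc = cfg.encoder
        self.encoder = HybridEncoder(enc, cfg.input_size, use_aspp=cfg.use_aspp)
        D = enc.hidden_dim
        self.conv_more = Sequential(Conv2d(D, cfg.head_width, 3, padding=1),
                                    _norm(cfg.head_width, enc.norm), ReLU())
        skip_chs = [enc.stem_widths[2], enc.stem_widths[1], enc.stem_widths[0], 0]
        widths = cfg.decoder_widths
        ins = [cfg.head_width] + list(widths[:-1])
        blocks = [DecoderBlock(i, s, o, cfg.decoder_attention,
                               cfg.attention_reduction, enc.norm)
                  for i, s, o in zip(ins, skip_chs, widths)]
        for k, b in enumerate(blocks):
            setattr(self, f"dec{k}", b)
        self.blocks = blocks
        self.head = Conv2d(widths[-1], cfg.n_classes, 1)

    def forward_logits(self, x: Tensor) -> Tensor:
        z, skips = self.encoder(x)
        f = tokens_to_grid(z, self.encoder.grid_shape)
        f = self.conv_more(f)
        feed = [skips[2], skips[1], skips[0], None]  # 1/8, 1/4, 1/2, then none
        for block, skip in zip(self.blocks, feed):
            f = block(f, skip)
        return self.head(f)

    def forward(self, x: Tensor) -> SegmentationOutput:
        logits = self.forward_logits(x)
        prob = logits.softmax(axis=1).data[:, 1]
        return SegmentationOutput(logits=logits.data, prob=prob,
                                  mask=(prob >= 0.5).astype(np.uint8))

    def predict(self, images: np.ndarray) -> SegmentationOutput:
        """Inference on a (B, H, W) or (H, W) float array in [0, 1]."""
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        self.eval()
        return self.forward(Tensor(arr[:, None]))


def build_variant(name: str, base: ModelConfig | None = None) -> ModelConfig:
    """Config for one ablation row; `acp` is the full model (+ASPP, +CPAT)."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {list(VARIANTS)}")
    base = base if base is not None else ModelConfig()
    table = {
        "transunet": (False, "none"),
        "transunet+aspp": (True, "none"),
        "transunet+aspp+c": (True, "channel"),
        "transunet+aspp+p": (True, "pixel"),
        "transunet+aspp+cpat": (True, "cpat"),
        "transunet+cpat": (False, "cpat"),
        "acp": (True, "cpat"),
    }
    use_aspp, att = table[name]
    return dataclasses.replace(base, use_aspp=use_aspp, decoder_attention=att)


def count_parameters(model: Module) -> int:
    """Exact trainable-parameter total."""
    return sum(p.size for p in model.parameters() if p.requires_grad)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: ACPTransUNet, path, extra: dict | None = None) -> None:
    """Serialise weights (npz) with a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    cfg = dataclasses.asdict(model.cfg)
    sidecar = {"model_config": cfg}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path) -> ACPTransUNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = sidecar["model_config"]
    cfg_d["encoder"] = EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in cfg_d["encoder"].items()})
    for key in ("decoder_widths", "input_size"):
        cfg_d[key] = tuple(cfg_d[key])
    model = ACPTransUNet(ModelConfig(**cfg_d))
    with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model


def load_pretrained_backbone(model: ACPTransUNet, path,
                             name_map: dict[str, str]) -> list[str]:
    """Optional hook: copy tensors from an external npz archive into the
    encoder by explicit name mapping (ours -> theirs). Grayscale inputs are
    matched to RGB stems by averaging the first conv over its input axis.
    Returns the parameter names actually loaded; entries missing from the
    archive are skipped. Untested against any published checkpoint file.
    """
    with np.load(Path(path)) as z:
        params = dict(model.named_parameters())
        loaded = []
        for ours, theirs in name_map.items():
            if theirs not in z.files or ours not in params:
                continue
            src = z[theirs]
            dst = params[ours]
            if dst.data.shape != src.shape:
                if (dst.data.ndim == 4 and src.ndim == 4
                        and dst.data.shape[1] == 1 and src.shape[1] == 3):
                    src = src.mean(axis=1, keepdims=True)
                else:
                    continue
            dst.data[...] = src
            loaded.append(ours)
    return loaded
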