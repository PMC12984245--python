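"""Dual-input cortex/vessel segmentation network.

A shared ResNet-style trunk serves two modalities:

* RGB images enter through a ResNet-C style stem (three 3x3 convolutions);
* 25-band hyperspectral cubes first pass an HSI stem of three *valid* 3x3
  convolutions (25 -> 16 -> 8 -> 3 channels) whose output is shaped exactly
  like an RGB image and is fed to the same RGB stem, so the whole trunk is
  weight-shared between modalities.

The encoder stacks 14 residual blocks in three stages; downsampling uses the
ResNet-D shortcut (2x2 average pool + 1x1 convolution). The decoder mirrors
the stages with nearest-neighbour x2 upsampling, a linear-projection skip
add from the matching encoder stage, and two 3x3 conv + BN + leaky ReLU
blocks. Two 1x1-convolution heads with a sigmoid produce per-pixel cortex
and vessel probabilities at the input resolution. A projection head
(global average pool + two linear layers, embedding dim 256, L2-normalised)
supports contrastive pre-training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (BatchNorm2d, Conv2d, LeakyReLU, Linear, Module, Parameter,
                 Sequential, Tensor)

#: spatial downsampling factor of the trunk (stem /2, two stage strides /2)
DOWN_FACTOR = 8

#: total one-sided spatial shrink of three valid 3x3 convolutions
HSI_STEM_MARGIN = 3


@dataclass
class NetworkConfig:
    base_channels: int = 32
    stage_blocks: tuple = (4, 4, 6)
    embedding_dim: int = 256
    hsi_in_bands: int = 25
    leaky_slope: float = 0.01

    def __post_init__(self):
        if len(self.stage_blocks) != 3:
            raise ValueError("stage_blocks must have three entries")
        if any(b < 1 for b in self.stage_blocks):
            raise ValueError("each stage needs at least one block")
        if self.base_channels < 1 or self.embedding_dim < 1:
            raise ValueError("channel counts must be positive")


@dataclass
class NetOutput:
    cortex_prob: Tensor
    vessel_prob: Tensor

    def numpy(self):
        return (self.cortex_prob.data.copy(), self.vessel_prob.data.copy())


def _conv_bn_act(in_ch, out_ch, kernel, stride, padding, slope):
    return Sequential(
        Conv2d(in_ch, out_ch, kernel, stride=stride, padding=padding,
               bias=False),
        BatchNorm2d(out_ch),
        LeakyReLU(slope),
    )


class ResidualBlock(Module):
    """ResNet-B basic block: two 3x3 convs; ResNet-D downsampling shortcut."""

    def __init__(self, in_ch, out_ch, stride=1, slope=0.01):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                            bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, padding=1, bias=False)
        self.bn2 = BatchNorm2d(out_ch)
        self.act = LeakyReLU(slope)
        self.stride = stride
        if stride != 1 or in_ch != out_ch:
            self.short_conv = Conv2d(in_ch, out_ch, 1, bias=False)
            self.short_bn = BatchNorm2d(out_ch)
        else:
            self.short_conv = None
            self.short_bn = None

    def forward(self, x):
        out = self.act(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        if self.short_conv is not None:
            s = x.avg_pool2x2() if self.stride == 2 else x
            s = self.short_bn(self.short_conv(s))
        else:
            s = x
        return self.act(out + s)


class DecoderStage(Module):
    """x2 nearest upsample, optional projection-skip add, two conv blocks."""

    def __init__(self, in_ch, skip_ch, out_ch, slope=0.01):
        super().__init__()
        self.proj = (Conv2d(skip_ch, in_ch, 1, bias=False)
                     if skip_ch else None)
        self.block1 = _conv_bn_act(in_ch, out_ch, 3, 1, 1, slope)
        self.block2 = _conv_bn_act(out_ch, out_ch, 3, 1, 1, slope)

    def forward(self, x, skip=None):
        x = x.upsample2x()
        if self.proj is not None and skip is not None:
            x = x + self.proj(skip)
        return self.block2(self.block1(x))


class CortexNet(Module):
    """Dual-modality segmentation network with a shared trunk."""

    def __init__(self, config: NetworkConfig | None = None):
        super().__init__()
        cfg = config or NetworkConfig()
        self.config = cfg
        c = cfg.base_channels
        s = cfg.leaky_slope

        # HSI stem: three valid 3x3 convolutions, 25 -> 16 -> 8 -> 3
        self.hsi_stem = Sequential(
            Conv2d(cfg.hsi_in_bands, 16, 3, padding=0, bias=False),
            BatchNorm2d(16), LeakyReLU(s),
            Conv2d(16, 8, 3, padding=0, bias=False),
            BatchNorm2d(8), LeakyReLU(s),
            Conv2d(8, 3, 3, padding=0, bias=False),
            BatchNorm2d(3), LeakyReLU(s),
        )

        # RGB stem (ResNet-C: three 3x3 convs, the first strided)
        self.rgb_stem = Sequential(
            _conv_bn_act(3, c // 2 or 1, 3, 2, 1, s),
            _conv_bn_act(c // 2 or 1, c // 2 or 1, 3, 1, 1, s),
            _conv_bn_act(c // 2 or 1, c, 3, 1, 1, s),
        )

        n1, n2, n3 = cfg.stage_blocks
        self.encoder = [
            Sequential(*[ResidualBlock(c, c, 1, s) for _ in range(n1)]),
            Sequential(ResidualBlock(c, 2 * c, 2, s),
                       *[ResidualBlock(2 * c, 2 * c, 1, s)
                         for _ in range(n2 - 1)]),
            Sequential(ResidualBlock(2 * c, 4 * c, 2, s),
                       *[ResidualBlock(4 * c, 4 * c, 1, s)
                         for _ in range(n3 - 1)]),
        ]

        self.decoder = [
            DecoderStage(4 * c, 2 * c, 2 * c, s),   # 1/8 -> 1/4, skip stage 2
            DecoderStage(2 * c, c, c, s),           # 1/4 -> 1/2, skip stage 1
            DecoderStage(c, 0, c, s),               # 1/2 -> 1/1, no skip
        ]

        # dual head: two 1x1 convolutions with BN between, sigmoid output
        self.head = Sequential(
            Conv2d(c, c, 1, bias=False), BatchNorm2d(c), LeakyReLU(s),
            Conv2d(c, 2, 1, bias=True),
        )

        self.projection = Sequential(
            Linear(4 * c, cfg.embedding_dim), LeakyReLU(s),
            Linear(cfg.embedding_dim, cfg.embedding_dim),
        )

    # ------------------------------------------------------------- plumbing
    @staticmethod
    def _to_tensor(image) -> Tensor:
        if not isinstance(image, Tensor):
            image = Tensor(np.asarray(image, dtype=np.float32))
        if image.ndim == 3:
            image = image.reshape(1, *image.shape)
        if image.ndim != 4:
            raise ValueError("expected (C, H, W) or (N, C, H, W) input")
        return image

    @staticmethod
    def _pad_to_multiple(x: Tensor, factor: int):
        h, w = x.shape[-2:]
        h8 = -(-h // factor) * factor
        w8 = -(-w // factor) * factor
        if (h8, w8) == (h, w):
            return x, (h, w)
        pad = max(h8 - h, w8 - w)
        mode = "reflect" if pad < min(h, w) else "edge"
        x = x.pad2d(pad, mode=mode)
        # crop so the origin matches the unpadded input; the extra rows and
        # columns extend only past the bottom/right edge
        return x.crop2d(pad, pad, h8, w8), (h, w)

    def hsi_stem_forward(self, cube) -> Tensor:
        x = self._to_tensor(cube)
        if x.shape[1] != self.config.hsi_in_bands:
            raise ValueError(
                f"expected {self.config.hsi_in_bands} bands, got {x.shape[1]}")
        # reflect-pad so the three valid convolutions return the input size
        x = x.pad2d(HSI_STEM_MARGIN, mode="reflect")
        return self.hsi_stem(x)

    def _encode(self, x: Tensor):
        f0 = self.rgb_stem(x)
        f1 = self.encoder[0](f0)
        f2 = self.encoder[1](f1)
        f3 = self.encoder[2](f2)
        return f1, f2, f3

    # -------------------------------------------------------------- forward
    def forward(self, image, modality: str) -> NetOutput:
        if modality not in ("rgb", "hsi"):
            raise ValueError("modality must be 'rgb' or 'hsi'")
        x = self._to_tensor(image)
        expected = 3 if modality == "rgb" else self.config.hsi_in_bands
        if x.shape[1] != expected:
            raise ValueError(
                f"{modality} input needs {expected} channels, got {x.shape[1]}")
        if modality == "hsi":
            x = self.hsi_stem_forward(x)
        x, (h, w) = self._pad_to_multiple(x, DOWN_FACTOR)
        f1, f2, f3 = self._encode(x)
        d = self.decoder[0](f3, f2)
        d = self.decoder[1](d, f1)
        d = self.decoder[2](d)
        logits = self.head(d).crop2d(0, 0, h, w)
        probs = logits.sigmoid()
        return NetOutput(cortex_prob=probs[:, 0:1], vessel_prob=probs[:, 1:2])

    def project_embedding(self, image_batch, modality: str = "rgb") -> Tensor:
        """Unit-norm contrastive embeddings of a batch of patches."""
        x = self._to_tensor(image_batch)
        if modality == "hsi":
            x = self.hsi_stem_forward(x)
        x, _ = self._pad_to_multiple(x, DOWN_FACTOR)
        _, _, f3 = self._encode(x)
        pooled = f3.mean(axis=(2, 3))          # global average pool -> (N, 4c)
        emb = self.projection(pooled)
        norm = ((emb * emb).sum(axis=1, keepdims=True) + 1e-12).sqrt()
        return emb / norm


# ------------------------------------------------------------- checkpointing
WEIGHT_GROUPS = ("hsi_stem", "rgb_stem", "encoder", "decoder", "head",
                 "projection")

#: the weight-shared trunk (everything except the HSI stem's adapter convs)
TRUNK_GROUPS = ("rgb_stem", "encoder", "decoder", "head")


def save_checkpoint(model: CortexNet, path) -> None:
    """Write all weight groups to a single ``.npz`` archive."""
    np.savez(path, **model.state_dict())


def load_checkpoint(model: CortexNet, path, groups=None) -> list:
    """Load named weight groups (default: all) from an ``.npz`` archive.

    Returns the list of loaded keys. Loading only ``TRUNK_GROUPS`` transfers
    the shared trunk, e.g. from an RGB-trained model into an HSI model.
    """
    groups = tuple(groups) if groups is not None else WEIGHT_GROUPS
    unknown = set(groups) - set(WEIGHT_GROUPS)
    if unknown:
        raise ValueError(f"unknown weight groups: {sorted(unknown)}")
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files
                 if k.split(".", 1)[0] in groups}
    expected = [k for k, _ in list(model.named_parameters())
                + list(model.named_buffers())
                if k.split(".", 1)[0] in groups]
    missing = sorted(set(expected) - set(state))
    if missing:
        raise KeyError(f"checkpoint missing keys: {missing[:5]}...")
    model.load_state_dict(state, strict=False)
    return sorted(state)


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))
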