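"""Dual-head U-Net generator and conditional PatchGAN discriminators.

The generator follows the canonical conditional-translation U-Net recipe:
stride-2 4x4 convolutions down, transposed convolutions up, batch
normalization except on the outermost and innermost layers, LeakyReLU(0.2)
in the encoder and ReLU in the decoders, tanh output.  One encoder is
shared; two structurally identical decoders (bone head, iodine head)
consume the same bottleneck and skip tensors but share no parameters.

The stochastic input z is realized either as dropout in the first three
decoder blocks (default) or as an explicit Gaussian noise channel
concatenated to the input image; both are selectable, or noise can be
switched off entirely for deterministic inference.

Each discriminator sees the conditioning image concatenated with a real or
generated candidate along the channel axis and emits a grid of patch
logits (70x70 receptive field with the default three stride-2 layers).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

NOISE_KINDS = ("dropout", "channel", "off")


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    depth: int = 8                 # down/up levels; input dims must divide 2^depth
    base_width: int = 64
    dropout: float = 0.5
    noise_kind: str = "dropout"
    heads: int = 2                 # 2 = dual (bone + iodine), 1 = single-head baseline

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.noise_kind not in NOISE_KINDS:
            raise ValueError(f"noise_kind must be one of {NOISE_KINDS}")
        if self.heads not in (1, 2):
            raise ValueError("heads must be 1 or 2")

    @property
    def in_channels(self) -> int:
        return 2 if self.noise_kind == "channel" else 1

    def widths(self) -> list[int]:
        return [self.base_width * min(2 ** i, 8) for i in range(self.depth)]


@dataclasses.dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 2           # condition + candidate
    n_strided: int = 3             # stride-2 layers
    base_width: int = 64

    def layer_stack(self) -> list[tuple[int, int]]:
        """(kernel, stride) list: n stride-2 layers then two stride-1 layers."""
        return [(4, 2)] * self.n_strided + [(4, 1), (4, 1)]


def receptive_field(spec_or_layers) -> int:
    """Receptive field of one output logit, by the standard recursion."""
    layers = (spec_or_layers.layer_stack()
              if isinstance(spec_or_layers, DiscriminatorSpec) else spec_or_layers)
    rf, jump = 1, 1
    for k, s in layers:
        rf += (k - 1) * jump
        jump *= s
    return rf


class _EncoderBlock(nn.Module):
    def __init__(self, cin, cout, rng, norm: bool):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 4, 2, 1, rng)
        self.bn = nn.BatchNorm2d(cout) if norm else None

    def forward(self, x):
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return y.leaky_relu(0.2)


class _DecoderBlock(nn.Module):
    def __init__(self, cin, cout, rng, norm: bool, drop: float):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, cout, 4, 2, 1, rng)
        self.bn = nn.BatchNorm2d(cout) if norm else None
        self.drop = drop

    def forward(self, x, noise_rng, noise_active: bool):
        y = self.up(x)
        if self.bn is not None:
            y = self.bn(y)
        y = ad.dropout(y, self.drop, noise_rng, noise_active)
        return y.relu()


class _Decoder(nn.Module):
    """One U-Net decoding head with skip connections from the shared encoder."""

    def __init__(self, spec: GeneratorSpec, rng):
        super().__init__()
        w = spec.widths()
        depth = spec.depth
        self.blocks = []
        for i in range(depth - 2, -1, -1):
            cin = w[i + 1] if i == depth - 2 else w[i + 1] * 2
            drop = spec.dropout if (spec.noise_kind == "dropout"
                                    and (depth - 2 - i) < 3) else 0.0
            blk = _DecoderBlock(cin, w[i], rng, norm=True, drop=drop)
            self.blocks.append(blk)
            setattr(self, f"up{i}", blk)
        self.out = nn.ConvTranspose2d(w[0] * 2, 1, 4, 2, 1, rng)

    def forward(self, feats: list[Tensor], noise_rng, noise_active: bool):
        x = feats[-1]
        depth = len(feats)
        for j, blk in enumerate(self.blocks):
            level = depth - 2 - j
            x = blk(x, noise_rng, noise_active)
            x = ad.concat([x, feats[level]], axis=1)
        return self.out(x).tanh()


class DualHeadGenerator(nn.Module):
    """Shared encoder; bone and iodine decoding heads with private parameters."""

    def __init__(self, spec: GeneratorSpec, init_seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(init_seed)
        w = spec.widths()
        self.enc_blocks = []
        for i in range(spec.depth):
            cin = spec.in_channels if i == 0 else w[i - 1]
            norm = 0 < i < spec.depth - 1   # no BN on outermost or bottleneck
            blk = _EncoderBlock(cin, w[i], rng, norm)
            self.enc_blocks.append(blk)
            setattr(self, f"enc{i}", blk)
        self.dec_b = _Decoder(spec, rng)
        self.dec_c = _Decoder(spec, rng) if spec.heads == 2 else None

    # -- parameter partitions (for wiring probes and separate optimizers)
    def encoder_parameters(self):
        return [p for blk in self.enc_blocks for p in blk.parameters()]

    def head_parameters(self, head: str):
        dec = {"bone": self.dec_b, "iodine": self.dec_c}[head]
        return [] if dec is None else dec.parameters()

    def forward(self, conv_image: Tensor, noise_rng=None, noise_active: bool = False):
        """(conv, z) -> (bone_pred, iodine_pred); iodine_pred None for single head."""
        h, wd = conv_image.shape[2], conv_image.shape[3]
        div = 2 ** self.spec.depth
        if h % div or wd % div:
            raise ValueError(f"input spatial dims must be divisible by {div}")
        x = conv_image
        if self.spec.noise_kind == "channel":
            if noise_active and noise_rng is not None:
                z = noise_rng.standard_normal(
                    (x.shape[0], 1, h, wd)).astype(x.dtype)
            else:
                z = np.zeros((x.shape[0], 1, h, wd), dtype=x.dtype)
            x = ad.concat([x, Tensor(z)], axis=1)
        feats = []
        for blk in self.enc_blocks:
            x = blk(x)
            feats.append(x)
        noise_on = noise_active and self.spec.noise_kind == "dropout"
        if noise_rng is None:
            noise_on = False
        bone = self.dec_b(feats, noise_rng, noise_on)
        iodine = self.dec_c(feats, noise_rng, noise_on) if self.dec_c else None
        return bone, iodine


class PatchDiscriminator(nn.Module):
    """Conditional PatchGAN: judges (condition, candidate) channel pairs patch-wise."""

    def __init__(self, spec: DiscriminatorSpec, init_seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(init_seed)
        w = spec.base_width
        chans = [spec.in_channels] + [w * min(2 ** i, 8) for i in range(spec.n_strided + 1)]
        self.layers = []
        for i in range(spec.n_strided):
            blk = _DiscBlock(chans[i], chans[i + 1], 2, rng, norm=i > 0)
            self.layers.append(blk)
            setattr(self, f"d{i}", blk)
        blk = _DiscBlock(chans[spec.n_strided], chans[spec.n_strided + 1], 1, rng, norm=True)
        self.layers.append(blk)
        setattr(self, f"d{spec.n_strided}", blk)
        self.head = nn.Conv2d(chans[spec.n_strided + 1], 1, 4, 1, 1, rng)

    def forward(self, condition: Tensor, candidate: Tensor) -> Tensor:
        if condition.shape != candidate.shape:
            raise ValueError("condition and candidate must share a shape")
        x = ad.concat([condition, candidate], axis=1)
        for blk in self.layers:
            x = blk(x)
        return self.head(x)


class _DiscBlock(nn.Module):
    def __init__(self, cin, cout, stride, rng, norm: bool):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 4, stride, 1, rng)
        self.bn = nn.BatchNorm2d(cout) if norm else None

    def forward(self, x):
        y = self.conv(x)
        if self.bn is not None:
            y = self.bn(y)
        return y.leaky_relu(0.2)


def build_generator(spec: GeneratorSpec, init_seed: int = 0) -> DualHeadGenerator:
    """Deterministically initialized generator; see GeneratorSpec for knobs."""
    return DualHeadGenerator(spec, init_seed)


def build_discriminator(spec: DiscriminatorSpec, init_seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, init_seed)
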