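"""Generator, conditional patch discriminator, and the learnable RF layer.

The generator is a U-Net: a first (stride-1) convolution, four stride-2
skip-connected encoder/decoder block pairs, and a final transposed
convolution with tanh, so a [C, H, W] stack of receptive-field signal
images maps to a [3, H, W] frame in [-1, 1]. The discriminator is a
five-layer convolutional PatchGAN with batch normalization and leaky ReLU
(slope 0.2) that scores overlapping patches of the candidate frame
concatenated with its conditioning RFS images.

Channel widths and strides follow the standard conditional
image-to-image-translation plan (encoder widths base*{2,4,8,8}, kernel 4,
stride 2); the discriminator uses strides 2,2,2,1,1 so a 96x96 input yields
a 10x10 patch grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import (
    Tensor, concat, Module, Conv2d, ConvTranspose2d, BatchNorm2d,
    LeakyReLU, ReLU, Tanh, Sequential,
)
from .rf_transport import PerturbationMask

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "UNetGenerator",
    "PatchDiscriminator", "LearnableRFLayer", "learned_rf_forward",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 15          # lags x ROIs
    out_channels: int = 3
    base_width: int = 64
    n_skip_blocks: int = 4
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "GeneratorConfig":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 18          # 3 + RFS channels
    base_width: int = 64
    n_layers: int = 5
    leaky_slope: float = 0.2
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "DiscriminatorConfig":
        return cls(**json.loads(s))


class UNetGenerator(Module):
    """Spatial-size-preserving U-Net with 4 skip blocks; output in [-1, 1]."""

    def __init__(self, cfg: GeneratorConfig):
        if cfg.n_skip_blocks != 4:
            raise ValueError("the architecture is defined with 4 skip blocks")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        b = cfg.base_width
        widths = [b, 2 * b, 4 * b, 8 * b, 8 * b]   # stem + 4 encoder outputs
        self.stem = Conv2d(cfg.in_channels, b, 3, stride=1, padding=1, rng=rng)
        self.enc = []
        for i in range(4):
            self.enc.append(Sequential(
                Conv2d(widths[i], widths[i + 1], 4, stride=2, padding=1, rng=rng),
                BatchNorm2d(widths[i + 1], rng=rng),
                LeakyReLU(0.2),
            ))
        # decoder block i upsamples and is followed by concat with encoder skip
        dec_in = [widths[4], widths[4] + widths[3], 2 * widths[2], 2 * widths[1]]
        dec_out = [widths[3], widths[2], widths[1], widths[0]]
        self.dec = []
        for i in range(4):
            self.dec.append(Sequential(
                ConvTranspose2d(dec_in[i], dec_out[i], 4, stride=2, padding=1, rng=rng),
                BatchNorm2d(dec_out[i], rng=rng),
                ReLU(),
            ))
        self.head = ConvTranspose2d(2 * b, cfg.out_channels, 3, stride=1, padding=1, rng=rng)
        self.act = Tanh()
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        x = Tensor.as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("spatial dims must be divisible by 16")
        e0 = self.stem(x).leaky_relu(0.2)
        skips = [e0]
        h = e0
        for blk in self.enc:
            h = blk(h)
            skips.append(h)
        # bottleneck is skips[-1]; decode with skip concatenation
        for i, blk in enumerate(self.dec):
            h = blk(h)
            h = concat([h, skips[3 - i]], axis=1)
        return self.act(self.head(h))


class PatchDiscriminator(Module):
    """Five convolutional layers scoring real/fake per patch, conditioned on
    the RFS images concatenated channelwise with the candidate frame."""

    STRIDES = (2, 2, 2, 1, 1)

    def __init__(self, cfg: DiscriminatorConfig):
        if cfg.n_layers != 5:
            raise ValueError("the architecture is defined with 5 layers")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        b = cfg.base_width
        widths = [cfg.in_channels, b, 2 * b, 4 * b, 8 * b, 1]
        layers: list[Module] = []
        for i, s in enumerate(self.STRIDES):
            layers.append(Conv2d(widths[i], widths[i + 1], 4, stride=s, padding=1, rng=rng))
            if 0 < i < 4:    # no norm on the first layer, none on the logits
                layers.append(BatchNorm2d(widths[i + 1], rng=rng))
            if i < 4:
                layers.append(LeakyReLU(cfg.leaky_slope))
        self.net = Sequential(*layers)
        self.training = True

    def forward(self, candidate: Tensor, condition: Tensor) -> Tensor:
        candidate = Tensor.as_tensor(candidate)
        condition = Tensor.as_tensor(condition)
        if candidate.ndim == 3:
            candidate = candidate.reshape(1, *candidate.shape)
        if condition.ndim == 3:
            condition = condition.reshape(1, *condition.shape)
        if candidate.shape[0] != condition.shape[0] or candidate.shape[2:] != condition.shape[2:]:
            raise ValueError("candidate and condition shapes are inconsistent")
        if candidate.shape[1] + condition.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} total channels, got "
                f"{candidate.shape[1] + condition.shape[1]}")
        logits = self.net(concat([candidate, condition], axis=1))
        if logits.shape[2] < 2 or logits.shape[3] < 2:
            raise ValueError("input too small for a patch (non-scalar) output grid")
        return logits


def learned_rf_forward(weights: np.ndarray | Tensor, mask: PerturbationMask,
                       responses: np.ndarray | Tensor) -> Tensor:
    """Transport with learnable per-voxel weights V (masked to each voxel's
    RF pixel): image = (delta/M * V) . responses. At V = 1 this equals the
    fixed point transport exactly. Differentiable in both V and responses.

    weights: [V] (the masked entries); responses: [V] or [N, V].
    Returns [H, W] or [N, H, W].
    """
    w = weights if isinstance(weights, Tensor) else Tensor(weights)
    r = responses if isinstance(responses, Tensor) else Tensor(responses)
    if w.shape != (mask.n_voxels,):
        raise ValueError("weights must have one entry per voxel")
    single = r.ndim == 1
    if single:
        r = r.reshape(1, -1)
    if r.shape[1] != mask.n_voxels:
        raise ValueError("responses do not match mask voxel count")
    contrib = r * (w * Tensor(mask.normalizer))          # [N, V]
    # scatter-add voxel contributions to their pixels via a 0/1 matrix
    scatter = Tensor(mask.to_sparse().toarray())          # [H*W, V]
    img = contrib @ scatter.transpose(1, 0)               # [N, H*W]
    img = img.reshape(r.shape[0], mask.canvas.height, mask.canvas.width)
    return img.reshape(mask.canvas.height, mask.canvas.width) if single else img


class LearnableRFLayer(Module):
    """Per-ROI learnable perturbation of the fixed RF transport.

    Holds one weight per voxel (the masked entries of V), initialized to 1 so
    the layer reproduces the fixed transport exactly before training. Applies
    the same weights to every lag channel of its ROI.
    """

    def __init__(self, mask: PerturbationMask):
        self.mask = mask
        self.v = Tensor(np.ones(mask.n_voxels), requires_grad=True)
        # dense scatter kept as a constant array; memory ~ pixels x voxels
        self._scatter = mask.to_sparse().toarray()

    def forward(self, responses: Tensor | np.ndarray) -> Tensor:
        """responses [N, L, V] (L lag channels) -> images [N, L, H, W]."""
        r = responses if isinstance(responses, Tensor) else Tensor(responses)
        if r.ndim == 2:
            r = r.reshape(r.shape[0], 1, r.shape[1])
        n, l, v = r.shape
        if v != self.mask.n_voxels:
            raise ValueError("responses do not match mask voxel count")
        contrib = r * (self.v * Tensor(self.mask.normalizer)).reshape(1, 1, v)
        img = contrib.reshape(n * l, v) @ Tensor(self._scatter.T)
        return img.reshape(n, l, self.mask.canvas.height, self.mask.canvas.width)


def save_checkpoint(path, generator: UNetGenerator,
                    discriminator: PatchDiscriminator | None = None,
                    extra: dict | None = None):
    """Single-file checkpoint with configs embedded."""
    arrays = {f"gen.{k}": v for k, v in generator.state_arrays().items()}
    meta = {"generator_config": asdict(generator.cfg)}
    if discriminator is not None:
        arrays.update({f"disc.{k}": v for k, v in discriminator.state_arrays().items()})
        meta["discriminator_config"] = asdict(discriminator.cfg)
    if extra:
        meta["extra"] = extra
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[UNetGenerator, PatchDiscriminator | None, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        gen = UNetGenerator(GeneratorConfig(**meta["generator_config"]))
        gen.load_state_arrays(
            {k[len("gen."):]: data[k] for k in data.files if k.startswith("gen.")})
        disc = None
        if "discriminator_config" in meta:
            disc = PatchDiscriminator(DiscriminatorConfig(**meta["discriminator_config"]))
            disc.load_state_arrays(
                {k[len("disc."):]: data[k] for k in data.files if k.startswith("disc.")})
    return gen, disc, meta.get("extra", {})
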