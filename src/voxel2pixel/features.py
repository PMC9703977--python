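"""Pluggable perceptual feature extractors.

Both the feature loss used in training and the evaluation metrics compare
images in the activation space of a convolutional network. The extractor is
pluggable: any object with ``__call__(images, layer) -> Tensor`` and a
``layers`` attribute works. The extractor shipped here is a fixed-seed
random-weight convolutional network — random convolutional features are a
well-established perceptual basis and require no downloaded weights; swap in
a pretrained network (e.g. VGG/AlexNet/C3D activations exported to .npz)
for absolute comparability with published scores.

Two standard instances mirror the usual evaluation pair: a single-frame
extractor (``alexnet_like``) and a wider one standing in for a
spatiotemporal clip network (``c3d_like``), each exposing the canonical
pool2 / pool5 / fc6 layers.
"""

from __future__ import annotations

import zlib

import numpy as np

from .autodiff import Tensor

__all__ = ["RandomConvFeatureExtractor", "default_extractors", "avg_pool2"]


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling via reshape (spatial dims must be even)."""
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


class RandomConvFeatureExtractor:
    """Frozen random-weight conv net with named layers pool2, pool5, fc6.

    Deterministic per (name, seed); parameters never train. Images are
    [N, 3, H, W] with H = W divisible by 16, values in [-1, 1].
    """

    layers = ("pool2", "pool5", "fc6")

    def __init__(self, name: str = "alexnet_like", seed: int = 0,
                 width: int = 8, fc_dim: int = 64):
        self.name = name
        self.seed = seed
        self.width = width
        self.fc_dim = fc_dim
        rng = np.random.default_rng([seed, zlib.crc32(name.encode()) % (2**31)])
        w = width
        self._convs = []
        chans = [3, w, 2 * w, 4 * w, 4 * w]
        for i in range(4):
            k = rng.normal(0.0, np.sqrt(2.0 / (chans[i] * 9)), (chans[i + 1], chans[i], 3, 3))
            self._convs.append((Tensor(k), Tensor(np.zeros(chans[i + 1]))))
        self._fc_cache: dict[int, Tensor] = {}
        self._fc_seed = rng.integers(0, 2**31)

    def _fc_weight(self, in_dim: int) -> Tensor:
        if in_dim not in self._fc_cache:
            rng = np.random.default_rng([self._fc_seed, in_dim])
            self._fc_cache[in_dim] = Tensor(
                rng.normal(0.0, np.sqrt(1.0 / in_dim), (in_dim, self.fc_dim)))
        return self._fc_cache[in_dim]

    def __call__(self, images: Tensor | np.ndarray, layer: str = "pool5") -> Tensor:
        """Differentiable features, flattened to [N, D]."""
        if layer not in self.layers:
            raise ValueError(f"unknown layer {layer!r}; choose from {self.layers}")
        x = images if isinstance(images, Tensor) else Tensor(images)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        h = x
        for i, (kw, kb) in enumerate(self._convs):
            h = h.conv2d(kw, kb, stride=1, padding=1).leaky_relu(0.1)
            h = avg_pool2(h)
            if i == 1 and layer == "pool2":
                return h.reshape(h.shape[0], -1)
        flat = h.reshape(h.shape[0], -1)
        if layer == "pool5":
            return flat
        return (flat @ self._fc_weight(flat.shape[1])).relu()

    def features(self, images: np.ndarray, layer: str = "pool5") -> np.ndarray:
        """Non-differentiable convenience wrapper returning numpy [N, D]."""
        return self(images, layer).data


def default_extractors(seed: int = 0) -> dict[str, RandomConvFeatureExtractor]:
    """The evaluation pair: a frame extractor and a clip-network stand-in."""
    return {
        "alexnet_like": RandomConvFeatureExtractor("alexnet_like", seed=seed, width=8),
        "c3d_like": RandomConvFeatureExtractor("c3d_like", seed=seed + 1, width=12),
    }
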