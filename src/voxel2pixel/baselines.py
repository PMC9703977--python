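"""Comparison decoders: identification, voxel-input GAN, and fully connected.

Baseline 1 is an identification decoder in the spirit of encoding-model
inversion: fit a (ridge) linear encoding model from stimulus features to
voxel responses on the training set, forward-pass every training stimulus to
get predicted voxel patterns, correlate each test voxel pattern with all
predictions, and reconstruct as the pixelwise mean of the top-k
best-matching training frames.

Baseline 2 keeps the exact generator/discriminator and losses of the main
model but feeds raw z-scored lag-stacked voxels through a learned linear
layer reshaped onto the generator's input grid — no receptive-field
topography.

Baseline 3 replaces all convolutional layers with fully connected ones; it
is a control expected to produce noise-like output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, Module, Linear, Sequential, LeakyReLU, Tanh, concat
from .networks import (
    GeneratorConfig, DiscriminatorConfig, UNetGenerator, PatchDiscriminator,
)
from .rf_transport import Canvas

__all__ = [
    "EncodingModel", "IdentificationResult", "baseline1_reconstruct",
    "LinearFrontend", "baseline2_build", "FCGenerator", "FCDiscriminator",
    "baseline3_build",
]


@dataclass
class EncodingModel:
    """Ridge-regularized linear map from stimulus features to voxel vectors."""

    coef: np.ndarray        # [n_features + 1, n_voxels]; last row is intercept
    ridge_lambda: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        return features @ self.coef[:-1] + self.coef[-1]


def fit_encoding_model(features: np.ndarray, responses: np.ndarray,
                       ridge_lambda: float = 1.0) -> EncodingModel:
    """Closed-form ridge fit (intercept unpenalized via centering)."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(responses, dtype=float)
    xm, ym = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - xm, y - ym
    a = xc.T @ xc + ridge_lambda * np.eye(x.shape[1])
    w = np.linalg.solve(a, xc.T @ yc)
    intercept = ym - xm @ w
    return EncodingModel(np.vstack([w, intercept]), ridge_lambda)


@dataclass
class IdentificationResult:
    correlations: np.ndarray    # [n_test, n_train]
    top_k_indices: np.ndarray   # [n_test, k], descending correlation
    reconstructions: np.ndarray  # [n_test, H, W, 3] (or input frame shape)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation of every row of a with every row of b -> [len(a), len(b)]."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(az, axis=1, keepdims=True)
    bn = np.linalg.norm(bz, axis=1, keepdims=True)
    an[an == 0] = 1.0
    bn[bn == 0] = 1.0
    return (az / an) @ (bz / bn).T


def baseline1_reconstruct(train_stimuli: np.ndarray, train_responses: np.ndarray,
                          test_responses: np.ndarray, feature_extractor,
                          k: int = 10, ridge_lambda: float = 1.0,
                          feature_layer: str = "pool5") -> IdentificationResult:
    """Identification decoder: encode, forward-pass, correlate, average top-k.

    Ties in the correlation ranking break toward the lower training index.
    """
    n_train = len(train_stimuli)
    if k > n_train:
        raise ValueError(f"k={k} exceeds the {n_train} training items")
    if train_responses.shape[1] != test_responses.shape[1]:
        raise ValueError("train and test voxel dimensions differ")
    feats = feature_extractor.features(_to_nchw(train_stimuli), layer=feature_layer)
    model = fit_encoding_model(feats, train_responses, ridge_lambda)
    pred_train = model.predict(feats)                    # [n_train, V]
    corr = _rowwise_pearson(test_responses, pred_train)  # [n_test, n_train]
    # stable argsort on -corr => ties toward lower index
    order = np.argsort(-corr, axis=1, kind="stable")[:, :k]
    recon = train_stimuli[order].mean(axis=1)
    return IdentificationResult(corr, order, recon)


def _to_nchw(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 4 and frames.shape[-1] in (1, 3):
        return frames.transpose(0, 3, 1, 2)
    return frames


class LinearFrontend(Module):
    """Learned linear map from a flat voxel vector to the generator grid."""

    def __init__(self, voxel_dim: int, n_channels: int, canvas: Canvas,
                 rng: np.random.Generator | None = None):
        self.voxel_dim = voxel_dim
        self.n_channels = n_channels
        self.canvas = canvas
        self.linear = Linear(voxel_dim, n_channels * canvas.n_pixels, rng=rng)

    def forward(self, x) -> Tensor:
        x = Tensor.as_tensor(x)
        if x.ndim == 1:
            x = x.reshape(1, -1)
        if x.shape[1] != self.voxel_dim:
            raise ValueError(f"expected {self.voxel_dim} voxels, got {x.shape[1]}")
        out = self.linear(x)
        return out.reshape(x.shape[0], self.n_channels,
                           self.canvas.height, self.canvas.width)


@dataclass
class Baseline2Model:
    frontend: LinearFrontend
    generator: UNetGenerator
    discriminator: PatchDiscriminator

    def forward(self, voxels: np.ndarray | Tensor) -> Tensor:
        return self.generator(self.frontend(voxels))


def baseline2_build(voxel_dim: int, canvas: Canvas, n_channels: int = 15,
                    base_width: int = 64, seed: int = 0) -> Baseline2Model:
    """Voxel-input variant: same nets and losses, linear layer in front."""
    rng = np.random.default_rng([seed, 2])
    frontend = LinearFrontend(voxel_dim, n_channels, canvas, rng=rng)
    gen = UNetGenerator(GeneratorConfig(in_channels=n_channels,
                                        base_width=base_width, seed=seed))
    disc = PatchDiscriminator(DiscriminatorConfig(in_channels=3 + n_channels,
                                                  base_width=base_width, seed=seed))
    return Baseline2Model(frontend, gen, disc)


class FCGenerator(Module):
    """All-dense generator control; parameter count dwarfs the conv model."""

    def __init__(self, voxel_dim: int, canvas: Canvas, hidden: int = 256,
                 seed: int = 0):
        rng = np.random.default_rng([seed, 3])
        self.voxel_dim = voxel_dim
        self.canvas = canvas
        self.net = Sequential(
            Linear(voxel_dim, hidden, rng=rng), LeakyReLU(0.2),
            Linear(hidden, hidden, rng=rng), LeakyReLU(0.2),
            Linear(hidden, 3 * canvas.n_pixels, rng=rng), Tanh(),
        )

    def forward(self, x) -> Tensor:
        x = Tensor.as_tensor(x)
        if x.ndim == 1:
            x = x.reshape(1, -1)
        out = self.net(x)
        return out.reshape(x.shape[0], 3, self.canvas.height, self.canvas.width)


class FCDiscriminator(Module):
    """Dense discriminator over (candidate frame, raw voxel condition)."""

    def __init__(self, voxel_dim: int, canvas: Canvas, hidden: int = 128,
                 seed: int = 0):
        rng = np.random.default_rng([seed, 4])
        in_dim = 3 * canvas.n_pixels + voxel_dim
        self.canvas = canvas
        self.net = Sequential(
            Linear(in_dim, hidden, rng=rng), LeakyReLU(0.2),
            Linear(hidden, hidden, rng=rng), LeakyReLU(0.2),
            Linear(hidden, 1, rng=rng),
        )

    def forward(self, candidate: Tensor, condition: Tensor) -> Tensor:
        candidate = Tensor.as_tensor(candidate)
        condition = Tensor.as_tensor(condition)
        flat = candidate.reshape(candidate.shape[0], -1)
        return self.net(concat([flat, condition.reshape(condition.shape[0], -1)], axis=1))


@dataclass
class Baseline3Model:
    generator: FCGenerator
    discriminator: FCDiscriminator

    def forward(self, voxels: np.ndarray | Tensor) -> Tensor:
        return self.generator(voxels)


def baseline3_build(voxel_dim: int, canvas: Canvas, hidden: int = 256,
                    seed: int = 0) -> Baseline3Model:
    return Baseline3Model(FCGenerator(voxel_dim, canvas, hidden, seed),
                          FCDiscriminator(voxel_dim, canvas, max(64, hidden // 2), seed))
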