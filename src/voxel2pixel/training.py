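"""Composite loss, reconstruction history buffer, and the adversarial loop.

The generator minimizes a weighted sum of three terms: an L1 pixel loss
(weight 1), a perceptual feature loss — the Euclidean distance between
extractor features of target and reconstruction (weight 100) — and an
adversarial term, the binary cross-entropy of the discriminator's patch
logits against the "real" label (weight 1). The discriminator minimizes
BCE(real -> 1) + BCE(fake -> 0), where fakes are drawn through a capacity-50
history buffer: once full, each incoming reconstruction is swapped with a
stored past one with probability 0.5, so the discriminator keeps seeing the
generator's old mistakes.

Optimization is Adam with learning rate 2e-4 and beta1 = 0.5; the
discriminator and generator are updated alternately once per batch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, Adam, Module, bce_with_logits
from .networks import UNetGenerator, PatchDiscriminator

logger = logging.getLogger(__name__)

__all__ = [
    "LossComponents", "HistoryBuffer", "OptimConfig", "ArrayPairs",
    "generator_loss", "discriminator_loss", "buffer_step", "fit", "FitResult",
]

DEFAULT_WEIGHTS = (1.0, 100.0, 1.0)   # (L1, feature, adversarial)


@dataclass(frozen=True)
class LossComponents:
    l1: float
    feature: float
    adversarial: float
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    @property
    def total(self) -> float:
        w = self.weights
        parts = (self.l1, self.feature, self.adversarial)
        return float(sum(wi * p for wi, p in zip(w, parts) if not math.isnan(p)))


def _feature_distance(extractor, recon: Tensor, target: Tensor) -> Tensor:
    """Per-item Euclidean distance between features, RMS-normalized over the
    feature dimension so the weight of 100 acts on an O(1) quantity."""
    fr = extractor(recon)
    ft = extractor(target)
    if not np.isfinite(fr.data).all() or not np.isfinite(ft.data).all():
        raise ValueError("feature extractor produced non-finite values")
    d2 = ((fr - ft) ** 2).mean(axis=1)
    return d2.sqrt_safe().mean()


def generator_loss(recon: Tensor, target: Tensor | np.ndarray,
                   disc_logits: Tensor | None, feature_extractor=None,
                   weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                   ) -> tuple[Tensor, LossComponents]:
    """Weighted generator objective; disabled terms are passed as None.

    The adversarial term scores the reconstruction's logits against the
    "real" label — the inverse of the discriminator's objective.
    Returns (scalar loss Tensor for backprop, numeric components).
    """
    target = Tensor.as_tensor(target)
    if recon.shape != target.shape:
        raise ValueError("reconstruction and target shapes differ")
    w_l1, w_feat, w_adv = weights
    l1 = (recon - target).abs().mean()
    loss = w_l1 * l1
    l1_val = l1.item()
    feat_val = float("nan")
    if feature_extractor is not None:
        feat = _feature_distance(feature_extractor, recon, target)
        loss = loss + w_feat * feat
        feat_val = feat.item()
    adv_val = float("nan")
    if disc_logits is not None:
        adv = bce_with_logits(disc_logits, 1.0)
        loss = loss + w_adv * adv
        adv_val = adv.item()
    return loss, LossComponents(l1_val, feat_val, adv_val, weights)


def discriminator_loss(real_logits: Tensor, fake_logits: Tensor) -> Tensor:
    """BCE(real -> 1) + BCE(fake -> 0), each averaged over the patch grid."""
    if not np.isfinite(real_logits.data).all() or not np.isfinite(fake_logits.data).all():
        raise ValueError("non-finite discriminator logits")
    return bce_with_logits(real_logits, 1.0) + bce_with_logits(fake_logits, 0.0)


class HistoryBuffer:
    """Replay store of past reconstructions for discriminator training."""

    def __init__(self, capacity: int = 50, swap_probability: float = 0.5,
                 seed: int | None = None):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.swap_probability = swap_probability
        self._rng = np.random.default_rng(seed)
        self._store: list[np.ndarray] = []

    def __len__(self) -> int:
        return len(self._store)

    def step(self, batch: np.ndarray) -> np.ndarray:
        """Route a batch of reconstructions toward the discriminator.

        While filling, items pass through unswapped and are stored; once at
        capacity each item is, with probability ``swap_probability``,
        exchanged for a uniformly drawn stored item (which it replaces).
        """
        out = np.array(batch, copy=True)
        for i in range(out.shape[0]):
            if len(self._store) < self.capacity:
                self._store.append(out[i].copy())
                continue
            if self._rng.random() < self.swap_probability:
                j = int(self._rng.integers(self.capacity))
                out[i], self._store[j] = self._store[j].copy(), out[i].copy()
        return out


def buffer_step(buffer: HistoryBuffer, batch_of_recons: np.ndarray) -> np.ndarray:
    return buffer.step(batch_of_recons)


@dataclass(frozen=True)
class OptimConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.5
    batch_size: int = 16
    epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class ArrayPairs:
    """In-memory dataset of (network input, target frame) pairs.

    ``inputs`` is [N, ...] — RFS image stacks for the main model, or raw
    responses when a trainable frontend maps them to images — and
    ``targets`` is [N, 3, H, W] in [-1, 1].
    """

    def __init__(self, inputs: np.ndarray, targets: np.ndarray):
        self.inputs = np.asarray(inputs, dtype=float)
        self.targets = np.asarray(targets, dtype=float)
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets must have equal length")

    def __len__(self) -> int:
        return len(self.inputs)


@dataclass
class FitResult:
    generator: UNetGenerator
    discriminator: PatchDiscriminator | None
    frontend: Module | None
    loss_log: pd.DataFrame


def fit(dataset: ArrayPairs, generator: UNetGenerator,
        discriminator: PatchDiscriminator | None, optim: OptimConfig,
        feature_extractor=None, *, use_adv: bool = True, use_feat: bool = True,
        frontend: Module | None = None,
        loss_weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
        log_path=None) -> FitResult:
    """Alternating adversarial training, seeded end to end on CPU.

    ``frontend`` (optional) differentiably maps raw dataset inputs to the
    generator's image grid — the learnable-RF input layer, or a linear layer
    for the voxel baseline — and trains jointly with the generator. With
    ``use_adv=False`` the discriminator is never touched; with
    ``use_feat=False`` the perceptual term is dropped. Disabled components
    are logged as NaN.
    """
    if use_adv and discriminator is None:
        raise ValueError("use_adv=True requires a discriminator")
    if use_feat and feature_extractor is None:
        raise ValueError("use_feat=True requires a feature extractor")
    rng = np.random.default_rng([optim.seed, 0x5eed])
    buffer = HistoryBuffer(seed=int(rng.integers(2**31)))
    gen_params = generator.parameters() + (frontend.parameters() if frontend else [])
    opt_g = Adam(gen_params, lr=optim.learning_rate, beta1=optim.beta1)
    opt_d = (Adam(discriminator.parameters(), lr=optim.learning_rate, beta1=optim.beta1)
             if use_adv else None)
    rows = []
    step = 0
    n = len(dataset)
    for epoch in range(optim.epochs):
        order = rng.permutation(n)
        for start in range(0, n, optim.batch_size):
            idx = order[start:start + optim.batch_size]
            if len(idx) < 2:
                continue    # batch norm needs more than one sample
            x_raw = dataset.inputs[idx]
            y = Tensor(dataset.targets[idx])
            cond = frontend(x_raw) if frontend is not None else Tensor(x_raw)
            recon = generator(cond)
            d_loss_val = float("nan")
            if use_adv:
                cond_d = Tensor(cond.data.copy())    # condition detached for D
                fake = Tensor(buffer.step(recon.data))
                discriminator.zero_grad()
                d_loss = discriminator_loss(discriminator(y, cond_d),
                                            discriminator(fake, cond_d))
                d_loss.backward()
                opt_d.step()
                d_loss_val = d_loss.item()
            logits = discriminator(recon, Tensor(cond.data.copy())) if use_adv else None
            loss, comps = generator_loss(
                recon, y, logits,
                feature_extractor if use_feat else None,
                weights=loss_weights)
            if not np.isfinite(loss.data).all():
                raise RuntimeError(
                    f"training diverged at epoch {epoch} step {step}: "
                    f"loss components {comps}")
            opt_g.zero_grad()
            if use_adv:
                discriminator.zero_grad()    # G step must not update D
            loss.backward()
            opt_g.step()
            rows.append({"step": step, "epoch": epoch, "l1": comps.l1,
                         "feature": comps.feature, "adv": comps.adversarial,
                         "total": comps.total, "d_loss": d_loss_val})
            step += 1
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return FitResult(generator, discriminator if use_adv else None, frontend, log)
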