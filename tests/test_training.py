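"""Loss composition, history buffer semantics, and the training loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxel2pixel.autodiff import Tensor
from voxel2pixel.features import RandomConvFeatureExtractor
from voxel2pixel.networks import (
    GeneratorConfig, DiscriminatorConfig, UNetGenerator, PatchDiscriminator,
)
from voxel2pixel.training import (
    LossComponents, HistoryBuffer, OptimConfig, ArrayPairs,
    generator_loss, discriminator_loss, fit,
)

RNG = np.random.default_rng(21)


class TestGeneratorLoss:
    def test_perfect_reconstruction_at_zero_logits(self):
        img = Tensor(RNG.uniform(-1, 1, (2, 3, 16, 16)))
        fx = RandomConvFeatureExtractor("loss_features", seed=0)
        loss, comps = generator_loss(img, Tensor(img.data.copy()),
                                     Tensor(np.zeros((2, 1, 2, 2))), fx)
        assert comps.l1 == 0.0
        assert comps.feature == 0.0
        assert comps.adversarial == pytest.approx(math.log(2), rel=1e-12)
        assert comps.total == pytest.approx(math.log(2), rel=1e-12)
        assert loss.item() == pytest.approx(comps.total, rel=1e-12)

    def test_weighted_total_arithmetic(self):
        comps = LossComponents(l1=0.2, feature=0.01, adversarial=0.7)
        assert comps.total == pytest.approx(0.2 + 100 * 0.01 + 0.7)

    def test_l1_homogeneity(self):
        target = Tensor(RNG.uniform(-0.5, 0.5, (1, 3, 16, 16)))
        gap = RNG.uniform(-0.1, 0.1, target.shape)
        _, c1 = generator_loss(Tensor(target.data + gap), target, None, None)
        _, c2 = generator_loss(Tensor(target.data + 2 * gap), target, None, None)
        assert c2.l1 == pytest.approx(2 * c1.l1, rel=1e-12)

    def test_total_recomputable_from_components(self):
        img = Tensor(RNG.uniform(-1, 1, (2, 3, 16, 16)))
        tgt = Tensor(RNG.uniform(-1, 1, (2, 3, 16, 16)))
        fx = RandomConvFeatureExtractor("loss_features", seed=0)
        loss, c = generator_loss(img, tgt, Tensor(RNG.normal(size=(2, 1, 2, 2))), fx)
        assert loss.item() == pytest.approx(1 * c.l1 + 100 * c.feature
                                            + 1 * c.adversarial, rel=1e-10)


class TestDiscriminatorLoss:
    def test_zero_logits_give_two_ln_two(self):
        z = Tensor(np.zeros((2, 1, 3, 3)))
        assert discriminator_loss(z, z).item() == pytest.approx(2 * math.log(2))

    def test_perfect_discriminator_limit(self):
        big = Tensor(np.full((1, 1, 2, 2), 40.0))
        assert discriminator_loss(big, -big).item() < 1e-12

    def test_matches_elementwise_oracle(self):
        real = RNG.normal(size=(2, 1, 3, 3))
        fake = RNG.normal(size=(2, 1, 3, 3))

        def bce(z, t):
            return np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - t * z)

        expected = bce(real, 1.0) + bce(fake, 0.0)
        got = discriminator_loss(Tensor(real), Tensor(fake)).item()
        assert got == pytest.approx(expected, rel=1e-12)


class TestHistoryBuffer:
    def test_fills_then_holds_at_capacity(self):
        buf = HistoryBuffer(capacity=50, seed=0)
        batch = RNG.normal(size=(10, 2, 2))
        for i in range(5):
            out = buf.step(batch + i)
            np.testing.assert_array_equal(out, batch + i)  # pass-through while filling
        assert len(buf) == 50
        for _ in range(20):
            buf.step(batch)
            assert len(buf) == 50

    def test_swap_fraction_near_half(self):
        buf = HistoryBuffer(capacity=50, swap_probability=0.5, seed=123)
        fill = np.full((50, 1), -1.0)
        buf.step(fill)
        n, swapped = 10_000, 0
        for i in range(n):
            out = buf.step(np.array([[float(i)]]))
            if out[0, 0] != float(i):
                swapped += 1
        assert 0.48 <= swapped / n <= 0.52

    def test_zero_probability_never_swaps(self):
        buf = HistoryBuffer(capacity=5, swap_probability=0.0, seed=0)
        buf.step(RNG.normal(size=(5, 2)))
        batch = RNG.normal(size=(7, 2))
        np.testing.assert_array_equal(buf.step(batch), batch)

    def test_deterministic_given_seed(self):
        outs = []
        for _ in range(2):
            buf = HistoryBuffer(capacity=5, seed=99)
            buf.step(np.arange(5.0).reshape(5, 1))
            outs.append(np.concatenate(
                [buf.step(np.array([[float(10 + i)]])) for i in range(20)]))
        np.testing.assert_array_equal(outs[0], outs[1])

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(1, 12), min_size=1, max_size=15),
           st.integers(0, 2**31 - 1))
    def test_never_exceeds_capacity(self, batch_sizes, seed):
        buf = HistoryBuffer(capacity=50, seed=seed)
        rng = np.random.default_rng(seed)
        for b in batch_sizes:
            buf.step(rng.normal(size=(b, 2)))
            assert len(buf) <= 50


def tiny_pairs(n=24, size=32, channels=3, seed=0):  # 32: smallest patch-valid size
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, channels, size, size))
    y = np.tanh(x[:, :3] + 0.1 * rng.normal(size=(n, 3, size, size)))
    return ArrayPairs(x, y)


def tiny_models(channels=3, bw=4, seed=0):
    gen = UNetGenerator(GeneratorConfig(in_channels=channels, base_width=bw, seed=seed))
    disc = PatchDiscriminator(DiscriminatorConfig(in_channels=3 + channels,
                                                  base_width=bw, seed=seed))
    return gen, disc


class TestFit:
    def test_loss_decreases_and_composition_holds(self):
        pairs = tiny_pairs()
        gen, disc = tiny_models()
        fx = RandomConvFeatureExtractor("loss_features", seed=0)
        res = fit(pairs, gen, disc, OptimConfig(batch_size=8, epochs=6, seed=0), fx)
        log = res.loss_log
        assert log.total.iloc[-1] < log[log.epoch == 0].total.mean()
        recomputed = log.l1 + 100 * log.feature + log.adv
        np.testing.assert_allclose(log.total, recomputed, rtol=1e-9)

    def test_same_seed_identical_loss_logs(self):
        logs = []
        for _ in range(2):
            pairs = tiny_pairs()
            gen, disc = tiny_models()
            fx = RandomConvFeatureExtractor("loss_features", seed=0)
            res = fit(pairs, gen, disc, OptimConfig(batch_size=8, epochs=2, seed=5), fx)
            logs.append(res.loss_log)
        np.testing.assert_array_equal(logs[0].total.values, logs[1].total.values)

    def test_ablation_wiring(self):
        pairs = tiny_pairs()
        fx = RandomConvFeatureExtractor("loss_features", seed=0)
        gen, disc = tiny_models()
        no_feat = fit(pairs, gen, disc, OptimConfig(batch_size=8, epochs=1, seed=0),
                      None, use_feat=False)
        assert no_feat.loss_log.feature.isna().all()
        assert no_feat.loss_log.adv.notna().all()
        gen, _ = tiny_models()
        no_adv = fit(pairs, gen, None, OptimConfig(batch_size=8, epochs=1, seed=0),
                     fx, use_adv=False)
        assert no_adv.loss_log.adv.isna().all()
        assert no_adv.loss_log.d_loss.isna().all()
        assert no_adv.loss_log.feature.notna().all()
        assert no_adv.discriminator is None

    def test_l1_only_approaches_least_absolute_deviation(self):
        """With feature and adversarial terms off, fit is plain L1 regression;
        on a constant-target problem the generator approaches the target."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(16, 3, 16, 16))
        y = np.full((16, 3, 16, 16), 0.25)
        pairs = ArrayPairs(x, y)
        gen, _ = tiny_models()
        res = fit(pairs, gen, None, OptimConfig(learning_rate=2e-3, batch_size=8,
                                                epochs=40, seed=0),
                  None, use_adv=False, use_feat=False)
        assert res.loss_log.l1.iloc[-1] < 0.25 * res.loss_log.l1.iloc[0]

    def test_missing_discriminator_rejected(self):
        with pytest.raises(ValueError, match="discriminator"):
            fit(tiny_pairs(), tiny_models()[0], None, OptimConfig(epochs=1),
                None, use_adv=True, use_feat=False)
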