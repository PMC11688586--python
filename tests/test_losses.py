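"""Loss terms against hand-computed oracles and their algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echogan.losses import (
    FeatureExtractor,
    LossRecord,
    LossWeights,
    adversarial_term,
    cycle_term,
    discriminator_term,
    l1_term,
    lpips_distance,
    perceptual_term,
    real_label,
    total_generator_loss,
)
from echogan.nn import Tensor


def _const(v, shape=(1, 1, 3, 3)):
    return np.full(shape, v, dtype=np.float64)


identity = lambda x: x


def shift(c):
    return lambda x: x + c


class TestLpipsDistance:
    def test_identical_inputs_give_zero(self, tiny_fx, rng):
        x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
        assert float(lpips_distance(tiny_fx, x, x).data) == pytest.approx(0.0)

    def test_degenerate_one_pixel_oracle(self):
        """Channel normalization maps +a -> +1 and -b -> -1; d = (1-(-1))^2 = 4."""
        fx = FeatureExtractor.identity()
        d = lpips_distance(fx, _const(0.7, (1, 1, 1, 1)), _const(-0.4, (1, 1, 1, 1)))
        assert float(d.data) == pytest.approx(4.0, rel=1e-6)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetric_nonnegative_premetric(self, tiny_fx, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=(1, 1, 16, 16)).astype(np.float32)
        y = r.normal(size=(1, 1, 16, 16)).astype(np.float32)
        dxy = float(lpips_distance(tiny_fx, x, y).data)
        dyx = float(lpips_distance(tiny_fx, y, x).data)
        assert dxy == pytest.approx(dyx, rel=1e-5)
        assert dxy >= 0.0

    def test_shape_mismatch_rejected(self, tiny_fx):
        with pytest.raises(ValueError, match="shape"):
            lpips_distance(tiny_fx, np.zeros((1, 1, 8, 8)), np.zeros((1, 1, 4, 4)))


class TestPerceptualTerm:
    def test_identity_generators_on_equal_domains(self, tiny_fx, rng):
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        val = perceptual_term(x, x, identity, identity, tiny_fx)
        assert float(val.data) == pytest.approx(0.0)

    def test_degenerate_oracle_sums_both_directions(self):
        fx = FeatureExtractor.identity()
        L = _const(0.5, (1, 1, 1, 1))
        H = _const(-0.2, (1, 1, 1, 1))
        assert float(
            perceptual_term(L, H, identity, identity, fx).data
        ) == pytest.approx(8.0, rel=1e-6)


class TestGeneratorLossTerms:
    @pytest.mark.parametrize(
        "value,expected", [(1.0, 0.0), (0.0, 2.0), (0.5, 0.5)]
    )
    def test_adversarial_constant_maps(self, value, expected):
        s = _const(value)
        assert float(adversarial_term(s, s).data) == pytest.approx(expected)

    def test_cycle_inverse_pair_is_zero(self, rng):
        x = Tensor(rng.normal(size=(1, 1, 4, 4)))
        val = cycle_term(x, x, shift(-0.3), shift(0.3))
        assert float(val.data) == pytest.approx(0.0)

    def test_cycle_stub_oracle(self):
        """Two +0.1 shifts move a zero image by 0.2 per direction -> 0.4."""
        z = Tensor(np.zeros((1, 1, 4, 4)))
        val = cycle_term(z, z, shift(0.1), shift(0.1))
        assert float(val.data) == pytest.approx(0.4)

    def test_l1_constant_offset(self):
        L = Tensor(np.zeros((1, 1, 4, 4)))
        H = Tensor(_const(0.2, (1, 1, 4, 4)))
        assert float(l1_term(L, H, identity, identity).data) == pytest.approx(0.4)

    def test_l1_stub_and_single_direction_flag(self):
        L = Tensor(np.zeros((1, 1, 4, 4)))
        H = Tensor(_const(0.2, (1, 1, 4, 4)))
        both = l1_term(L, H, identity, shift(0.2))
        assert float(both.data) == pytest.approx(0.2)
        one = l1_term(L, H, identity, shift(0.2), both_directions=False)
        assert float(one.data) == pytest.approx(0.0)

    def test_total_weighted_sum_oracle(self):
        w = LossWeights()
        assert float(total_generator_loss(1, 1, 1, 1, w).data) == pytest.approx(23.0)
        assert float(total_generator_loss(2, 0, 0, 0, w).data) == pytest.approx(2.0)
        assert float(total_generator_loss(0, 0, 0, 0, w).data) == pytest.approx(0.0)

    def test_total_is_linear_in_weights(self, rng):
        c = rng.uniform(0, 2, 4)
        w1 = LossWeights(1.0, 2.0, 3.0, 4.0)
        w2 = LossWeights(5.0, 1.0, 0.5, 2.0)
        w_sum = LossWeights(6.0, 3.0, 3.5, 6.0)
        t1 = float(total_generator_loss(*c, w1).data)
        t2 = float(total_generator_loss(*c, w2).data)
        ts = float(total_generator_loss(*c, w_sum).data)
        assert ts == pytest.approx(t1 + t2, rel=1e-12)

    def test_nonfinite_component_named(self):
        with pytest.raises(ValueError, match="cycle"):
            total_generator_loss(0.0, np.nan, 0.0, 0.0, LossWeights())


class TestDiscriminatorSide:
    @pytest.mark.parametrize(
        "means,expected",
        [((0.5, 0.3), 1.0), ((0.95, 0.92), 0.9), ((0.9, 0.9), 0.9),
         ((0.95, 0.5), 0.9), ((0.5, 0.95), 0.9)],
    )
    def test_label_smoothing_rule(self, means, expected):
        assert real_label(*means) == expected

    def test_discriminator_term_oracles(self):
        assert float(
            discriminator_term(_const(0.9), _const(0.0), 0.9).data
        ) == pytest.approx(0.0)
        assert float(
            discriminator_term(_const(0.0), _const(1.0), 1.0).data
        ) == pytest.approx(2.0)
        assert float(
            discriminator_term(_const(0.8), _const(0.1), 0.9).data
        ) == pytest.approx(0.02)

    def test_empty_score_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discriminator_term(np.zeros((0,)), np.zeros((0,)), 1.0)


class TestLossRecord:
    def test_total_must_recombine(self):
        w = LossWeights()
        good = LossRecord(1, 1, 1, 1, 23.0, 0.1, 0.1)
        good.validate(w)
        bad = LossRecord(1, 1, 1, 1, 24.0, 0.1, 0.1)
        with pytest.raises(ValueError, match="recombine"):
            bad.validate(w)


class TestFeatureExtractor:
    def test_requires_a_stage(self):
        with pytest.raises(ValueError, match="stage"):
            FeatureExtractor([])

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError, match="non-negative"):
            FeatureExtractor([lambda x: x], layer_weights=[-1.0])

    def test_random_conv_is_seed_reproducible(self, rng):
        a = FeatureExtractor.random_conv(seed=5, n_stages=2, base_channels=4)
        b = FeatureExtractor.random_conv(seed=5, n_stages=2, base_channels=4)
        x = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        fa = a.features(Tensor(x))
        fb = b.features(Tensor(x))
        for ta, tb in zip(fa, fb):
            assert np.array_equal(ta.data, tb.data)
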