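"""Training losses: perceptual feature distance, adversarial, cycle, paired L1,
the weighted aggregate generator objective, and the label-smoothed
discriminator objective.

The perceptual distance follows the learned-perceptual-image-patch-similarity
construction: images are passed through a frozen convolutional feature
extractor; at every stage the feature vectors are unit-normalized across
channels at each spatial location, squared differences are weighted per stage,
summed over channels and averaged over space; stage contributions are summed.
The default backbone is a seeded random convolutional stack — random deep
features are a serviceable perceptual substrate and make the package fully
self-contained; a pretrained stack can be plugged in through the same
interface.

All mean-squared and L1 reductions are means over batch, channels and space,
so the loss weights are scale-free in batch size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .nn import Module, Parameter, Tensor, as_tensor, conv2d, relu

__all__ = [
    "FeatureExtractor",
    "LossWeights",
    "LossRecord",
    "lpips_distance",
    "perceptual_term",
    "adversarial_term",
    "cycle_term",
    "l1_term",
    "total_generator_loss",
    "real_label",
    "discriminator_term",
]


class _RandomConvStage(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        k = 3
        scale = np.sqrt(2.0 / (in_ch * k * k))  # He init for stable feature scale
        self.weight = Parameter(rng.normal(0.0, scale, (out_ch, in_ch, k, k)))
        self.weight.requires_grad = False

    def forward(self, x):
        return relu(conv2d(x, self.weight, None, stride=2, padding=1))


class FeatureExtractor:
    """Ordered frozen feature stages with per-stage weights w_i."""

    def __init__(
        self,
        stages: Sequence[Callable],
        layer_weights: Sequence[float] | None = None,
        frozen: bool = True,
    ):
        if len(stages) < 1:
            raise ValueError("FeatureExtractor needs at least one stage")
        self.stages = list(stages)
        w = np.ones(len(stages)) if layer_weights is None else np.asarray(
            layer_weights, dtype=float
        )
        if len(w) != len(stages):
            raise ValueError("layer_weights length must match number of stages")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("layer_weights must be finite and non-negative")
        self.layer_weights = w
        self.frozen = frozen

    def features(self, x: Tensor) -> list[Tensor]:
        out = []
        h = as_tensor(x)
        for stage in self.stages:
            h = stage(h)
            out.append(h)
        return out

    def state(self) -> dict[str, np.ndarray]:
        s: dict[str, np.ndarray] = {}
        for i, stage in enumerate(self.stages):
            if isinstance(stage, Module):
                s.update(stage.named_state(prefix=f"stage{i}."))
        return s

    @classmethod
    def random_conv(
        cls,
        seed: int = 0,
        n_stages: int = 5,
        in_channels: int = 1,
        base_channels: int = 16,
        max_channels: int = 64,
    ) -> "FeatureExtractor":
        """Seeded random convolutional stack (no download required)."""
        rng = np.random.default_rng(seed)
        stages = []
        prev = in_channels
        for i in range(n_stages):
            ch = min(base_channels * 2**i, max_channels)
            stages.append(_RandomConvStage(prev, ch, rng))
            prev = ch
        return cls(stages)

    @classmethod
    def identity(cls) -> "FeatureExtractor":
        """Single identity stage; the degenerate analytic reference."""
        return cls([lambda x: x], layer_weights=[1.0])


@dataclass(frozen=True)
class LossWeights:
    lambda_adv: float = 1.0
    lambda_cycle: float = 10.0
    lambda_l1: float = 2.0
    lambda_per: float = 10.0

    def validate(self) -> None:
        for name in ("lambda_adv", "lambda_cycle", "lambda_l1", "lambda_per"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LossRecord:
    adv: float
    cycle: float
    l1: float
    perceptual: float
    total: float
    disc_H: float
    disc_L: float

    def validate(self, weights: "LossWeights") -> None:
        vals = [self.adv, self.cycle, self.l1, self.perceptual, self.total,
                self.disc_H, self.disc_L]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite loss record: {self}")
        expected = (
            weights.lambda_adv * self.adv
            + weights.lambda_cycle * self.cycle
            + weights.lambda_l1 * self.l1
            + weights.lambda_per * self.perceptual
        )
        if abs(expected - self.total) > 1e-6 * max(1.0, abs(expected)):
            raise ValueError(
                f"total {self.total} does not recombine from components ({expected})"
            )


def _mse(a: Tensor, b) -> Tensor:
    d = a - b
    return (d * d).mean()


def _mae(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).abs().mean()


def lpips_distance(fx: FeatureExtractor, X, Y, eps: float = 1e-10) -> Tensor:
    """Stage-summed, channel-normalized squared feature distance."""
    X, Y = as_tensor(X), as_tensor(Y)
    if X.shape != Y.shape:
        raise ValueError(f"lpips_distance: shape mismatch {X.shape} vs {Y.shape}")
    total = None
    for w, (fx_x, fx_y) in zip(
        fx.layer_weights, zip(fx.features(X), fx.features(Y))
    ):
        nx = _channel_normalize(fx_x, eps)
        ny = _channel_normalize(fx_y, eps)
        d = nx - ny
        # sum over channels, mean over batch and space
        stage = (d * d).sum(axis=1).mean() * float(w)
        total = stage if total is None else total + stage
    return total


def _channel_normalize(f: Tensor, eps: float) -> Tensor:
    norm = ((f * f).sum(axis=1, keepdims=True) + eps) ** 0.5
    return f / norm


def perceptual_term(L, H, G_L, G_H, fx: FeatureExtractor) -> Tensor:
    """d(H, G_H(L)) + d(L, G_L(H)) — both translation directions."""
    H_prime = G_H(L)
    L_prime = G_L(H)
    return lpips_distance(fx, H, H_prime) + lpips_distance(fx, L, L_prime)


def adversarial_term(scores_fake_H, scores_fake_L) -> Tensor:
    """MSE of each fake-score map against an all-ones target, summed."""
    sh, sl = as_tensor(scores_fake_H), as_tensor(scores_fake_L)
    if sh.data.size == 0 or sl.data.size == 0:
        raise ValueError("adversarial_term: empty score map")
    return _mse(sh, 1.0) + _mse(sl, 1.0)


def cycle_term(L, H, G_L, G_H) -> Tensor:
    """|G_L(G_H(L)) - L| + |G_H(G_L(H)) - H| (means)."""
    L, H = as_tensor(L), as_tensor(H)
    return _mae(G_L(G_H(L)), L) + _mae(G_H(G_L(H)), H)


def l1_term(L, H, G_L, G_H, both_directions: bool = True) -> Tensor:
    """Paired L1: |G_H(L) - H| (+ |G_L(H) - L| by default)."""
    L, H = as_tensor(L), as_tensor(H)
    out = _mae(G_H(L), H)
    if both_directions:
        out = out + _mae(G_L(H), L)
    return out


def total_generator_loss(adv, cycle, l1, perceptual, weights: LossWeights):
    weights.validate()
    for name, term in (
        ("adv", adv),
        ("cycle", cycle),
        ("l1", l1),
        ("perceptual", perceptual),
    ):
        val = term.data if isinstance(term, Tensor) else term
        if not np.all(np.isfinite(val)):
            raise ValueError(f"total_generator_loss: non-finite {name} term")
    return (
        weights.lambda_adv * as_tensor(adv)
        + weights.lambda_cycle * as_tensor(cycle)
        + weights.lambda_l1 * as_tensor(l1)
        + weights.lambda_per * as_tensor(perceptual)
    )


def real_label(
    mean_real_score: float,
    mean_fake_score: float,
    threshold: float = 0.9,
    smooth: float = 0.9,
) -> float:
    """Conditional label smoothing for the discriminator's real target.

    When both batch-mean scores are strictly below ``threshold`` the
    discriminator is not yet overconfident and the hard label 1.0 is kept;
    otherwise the smoothed label is used."""
    if not (np.isfinite(mean_real_score) and np.isfinite(mean_fake_score)):
        raise ValueError("real_label: non-finite score means")
    if mean_real_score < threshold and mean_fake_score < threshold:
        return 1.0
    return smooth


def discriminator_term(real_scores, fake_scores, label: float) -> Tensor:
    """MSE(real, label) + MSE(fake, 0) for one discriminator."""
    r, f = as_tensor(real_scores), as_tensor(fake_scores)
    if r.data.size == 0 or f.data.size == 0:
        raise ValueError("discriminator_term: empty score map")
    return _mse(r, float(label)) + _mse(f, 0.0)
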