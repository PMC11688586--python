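"""Generator and discriminator architectures.

The generator is an encoder–decoder UNet: strided 4-wide convolutions with
instance normalization and leaky ReLU on the way down (channel widths doubling
from ``base_channels``, capped at 8x base), transposed convolutions with
instance normalization and ReLU plus skip concatenations on the way up,
dropout on the configured deep decoder stages, and a tanh head that scales the
output to [-1, 1].  Two generators (roles ``G_H``: low→high, ``G_L``:
high→low) share the architecture but never the parameters, and likewise the
two discriminators (``D_H``, ``D_L``).

The discriminator is a patch critic: all convolutions are spectrally
normalized (largest singular value divided out, keeping each layer
1-Lipschitz) and the output is a spatial score map — 30x30 for a 256-pixel
input under the default stack — judging the realism of overlapping patches
rather than the whole image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Conv2d,
    ConvTranspose2d,
    Dropout,
    InstanceNorm2d,
    Module,
    SpectralConv2d,
    concat,
    leaky_relu,
    relu,
    spectral_sigma,
    tanh,
)

log = logging.getLogger(__name__)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "generator_forward",
    "spectral_normalize",
]


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int = 1
    base_channels: int = 64
    depth: int = 8
    dropout_rate: float = 0.5
    dropout_stages: tuple[int, ...] = (0, 1, 2)  # decoder stages, 0 = innermost
    # alternative placement: dropout after the deepest encoder stages instead
    encoder_dropout: bool = False

    def validate(self) -> None:
        if self.in_channels < 1:
            raise ValueError(f"in_channels must be >= 1: {self.in_channels}")
        if self.base_channels < 1:
            raise ValueError(f"base_channels must be >= 1: {self.base_channels}")
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2: {self.depth}")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1]: {self.dropout_rate}")


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 1
    base_channels: int = 64
    n_strided_layers: int = 3
    kernel_size: int = 4
    leaky_slope: float = 0.2

    def validate(self) -> None:
        if self.in_channels < 1 or self.base_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.n_strided_layers < 1:
            raise ValueError(
                f"n_strided_layers must be >= 1: {self.n_strided_layers}"
            )


class Generator(Module):
    """UNet translator between the low- and high-quality image domains."""

    def __init__(
        self,
        spec: GeneratorSpec,
        seed: int | None = None,
        role_tag: str = "G_H",
    ):
        super().__init__()
        spec.validate()
        self.spec = spec
        self.role_tag = role_tag
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            None if seed is None else seed + 1
        )
        b, d, cap = spec.base_channels, spec.depth, 8 * spec.base_channels

        enc_out = [min(b * 2**i, cap) for i in range(d)]
        self.enc_convs: list[Conv2d] = []
        self.enc_norms: list[InstanceNorm2d | None] = []
        self.enc_drops: list[Dropout | None] = []
        for i, ch in enumerate(enc_out):
            prev = spec.in_channels if i == 0 else enc_out[i - 1]
            conv = Conv2d(prev, ch, 4, stride=2, padding=1, rng=rng)
            # no normalization on the first stage or the bottleneck (1x1 maps)
            norm = InstanceNorm2d(ch) if 0 < i < d - 1 else None
            # encoder-dropout placement mirrors the decoder stage indices,
            # counted from the deepest stage
            drop = (
                Dropout(spec.dropout_rate, rng=self._dropout_rng)
                if spec.encoder_dropout and (d - 1 - i) in spec.dropout_stages
                else None
            )
            setattr(self, f"enc{i}", conv)
            if norm is not None:
                setattr(self, f"enc_norm{i}", norm)
            if drop is not None:
                setattr(self, f"enc_drop{i}", drop)
            self.enc_convs.append(conv)
            self.enc_norms.append(norm)
            self.enc_drops.append(drop)

        dec_out = [min(b * 2 ** (d - 2 - j), cap) for j in range(d - 1)]
        self.dec_convs: list[ConvTranspose2d] = []
        self.dec_norms: list[InstanceNorm2d] = []
        self.dec_drops: list[Dropout | None] = []
        prev = enc_out[-1]
        for j, ch in enumerate(dec_out):
            conv = ConvTranspose2d(prev, ch, 4, stride=2, padding=1, rng=rng)
            norm = InstanceNorm2d(ch)
            drop = (
                Dropout(spec.dropout_rate, rng=self._dropout_rng)
                if j in spec.dropout_stages and not spec.encoder_dropout
                else None
            )
            setattr(self, f"dec{j}", conv)
            setattr(self, f"dec_norm{j}", norm)
            if drop is not None:
                setattr(self, f"dec_drop{j}", drop)
            self.dec_convs.append(conv)
            self.dec_norms.append(norm)
            self.dec_drops.append(drop)
            prev = ch + enc_out[d - 2 - j]
        self.head = ConvTranspose2d(prev, spec.in_channels, 4, stride=2, padding=1, rng=rng)

    def forward(self, x):
        data = x.data if hasattr(x, "data") else np.asarray(x)
        if data.ndim != 4 or data.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"{self.role_tag}: expected (N, {self.spec.in_channels}, H, W) "
                f"input, got shape {data.shape}"
            )
        div = 2**self.spec.depth
        if data.shape[2] % div or data.shape[3] % div:
            raise ValueError(
                f"{self.role_tag}: spatial size {data.shape[2:]} must be "
                f"divisible by 2^depth = {div}"
            )
        skips = []
        h = x
        for conv, norm, drop in zip(self.enc_convs, self.enc_norms, self.enc_drops):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            if drop is not None:
                h = drop(h)
            h = leaky_relu(h, 0.2)
            skips.append(h)
        for j, (conv, norm, drop) in enumerate(
            zip(self.dec_convs, self.dec_norms, self.dec_drops)
        ):
            h = norm(conv(h))
            if drop is not None:
                h = drop(h)
            h = relu(h)
            h = concat([h, skips[self.spec.depth - 2 - j]], axis=1)
        return tanh(self.head(h))


class Discriminator(Module):
    """Spectrally normalized patch critic emitting a spatial score map."""

    def __init__(
        self,
        spec: DiscriminatorSpec,
        seed: int | None = None,
        role_tag: str = "D_H",
    ):
        super().__init__()
        spec.validate()
        self.spec = spec
        self.role_tag = role_tag
        rng = np.random.default_rng(seed)
        b, k, cap = spec.base_channels, spec.kernel_size, 8 * spec.base_channels
        channels = [min(b * 2**i, cap) for i in range(spec.n_strided_layers)]
        channels.append(min(b * 2**spec.n_strided_layers, cap))
        strides = [2] * spec.n_strided_layers + [1]
        self.convs: list[SpectralConv2d] = []
        prev = spec.in_channels
        for i, (ch, s) in enumerate(zip(channels, strides)):
            conv = SpectralConv2d(prev, ch, k, stride=s, padding=1, rng=rng)
            setattr(self, f"conv{i}", conv)
            self.convs.append(conv)
            prev = ch
        self.score = SpectralConv2d(prev, 1, k, stride=1, padding=1, rng=rng)

    def forward(self, x):
        h = x
        for conv in self.convs:
            h = leaky_relu(conv(h), self.spec.leaky_slope)
        return self.score(h)


def build_generator(
    spec: GeneratorSpec, seed: int | None = None, role_tag: str = "G_H"
) -> Generator:
    return Generator(spec, seed=seed, role_tag=role_tag)


def build_discriminator(
    spec: DiscriminatorSpec, seed: int | None = None, role_tag: str = "D_H"
) -> Discriminator:
    return Discriminator(spec, seed=seed, role_tag=role_tag)


def generator_forward(g: Generator, batch):
    """Apply ``g`` to a batch in [-1, 1]; shape- and range-preserving."""
    return g(batch)


def spectral_normalize(weight: np.ndarray, n_power_iterations: int = 20) -> np.ndarray:
    """Divide ``weight`` by its largest singular value (power iteration).

    Higher-rank weights (e.g. conv kernels) are treated as their
    (out_channels, -1) matrix view.  At >= 20 iterations the result's largest
    singular value is within 1e-3 of unity for non-degenerate inputs.
    All-zero weights are returned unchanged (sigma undefined) with a warning.
    """
    if n_power_iterations < 1:
        raise ValueError("n_power_iterations must be >= 1")
    weight = np.asarray(weight, dtype=np.float64)
    if weight.size == 0:
        raise ValueError("spectral_normalize: empty weight")
    wmat = weight.reshape(weight.shape[0], -1)
    norm = np.linalg.norm(wmat)
    if norm == 0.0:
        log.warning("spectral_normalize: all-zero weight left unnormalized")
        return weight
    rng = np.random.default_rng(0)
    u = rng.normal(size=wmat.shape[0])
    u /= np.linalg.norm(u)
    v = rng.normal(size=wmat.shape[1])
    v /= np.linalg.norm(v)
    sigma, _, _ = spectral_sigma(wmat, u, v, n_power_iterations, converge_tol=1e-8)
    return (weight / sigma).reshape(weight.shape)
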