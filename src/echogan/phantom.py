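"""Synthetic speckle phantoms: paired low/high-quality B-mode-like images.

A phantom is a piecewise-elliptical echogenicity map (background tissue plus
elliptical inclusions of differing reflectivity) multiplied by unit-mean
multiplicative speckle — the first-order statistical model of a B-mode image.
Speckle is gamma-distributed with shape equal to the number of incoherently
averaged "looks"; variance of the field is 1/looks.

The low-quality member of a pair is produced from the high-quality member by
a fixed degradation chain that emulates a low-end portable probe: a smooth
random warp (the two images of a real pair are acquired at different times,
so they are anatomically but not pixel-wise aligned), Gaussian point-spread
blur, resolution reduction, dynamic-range (gamma) compression, and
re-speckling with fewer looks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as _ellipse

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "ImagePair",
    "echogenicity_map",
    "render_phantom",
    "apply_speckle",
    "degrade",
    "make_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and statistics of the clean (high-quality) phantom."""

    side_length: int = 256
    n_inclusions: int = 6
    background_echogenicity: float = 0.35
    inclusion_echogenicity_range: tuple[float, float] = (0.05, 0.9)
    inclusion_axis_range: tuple[int, int] = (8, 48)
    speckle_looks_high: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        s = self.side_length
        if s < 32 or (s & (s - 1)) != 0:
            raise ValueError(f"side_length must be a power of two >= 32: {s}")
        if self.n_inclusions < 0:
            raise ValueError(f"n_inclusions must be >= 0: {self.n_inclusions}")
        for name in ("background_echogenicity",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]: {v}")
        lo, hi = self.inclusion_echogenicity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(
                f"inclusion_echogenicity_range must be an ordered pair in [0, 1]: {(lo, hi)}"
            )
        a, b = self.inclusion_axis_range
        if not (1 <= a <= b) or b >= s // 2:
            raise ValueError(
                f"inclusion_axis_range must fit inside the image: {(a, b)} vs side {s}"
            )
        if self.speckle_looks_high <= 0:
            raise ValueError(
                f"speckle_looks_high must be positive: {self.speckle_looks_high}"
            )


@dataclass(frozen=True)
class DegradationSpec:
    """Parameters of the high→low quality degradation chain."""

    psf_sigma: float = 2.0
    downsample_factor: int = 2
    speckle_looks_low: float = 2.0
    contrast_gamma: float = 1.5
    warp_amplitude: float = 1.0
    warp_scale: float = 8.0
    seed: int = 0

    def validate(self, side_length: int | None = None) -> None:
        if self.psf_sigma < 0:
            raise ValueError(f"psf_sigma must be >= 0: {self.psf_sigma}")
        if self.downsample_factor < 1:
            raise ValueError(
                f"downsample_factor must be >= 1: {self.downsample_factor}"
            )
        if side_length is not None and side_length % self.downsample_factor != 0:
            raise ValueError(
                f"downsample_factor {self.downsample_factor} does not divide "
                f"side length {side_length}"
            )
        if self.speckle_looks_low <= 0:
            raise ValueError(
                f"speckle_looks_low must be positive: {self.speckle_looks_low}"
            )
        if self.contrast_gamma <= 0:
            raise ValueError(f"contrast_gamma must be positive: {self.contrast_gamma}")
        if self.warp_amplitude < 0:
            raise ValueError(f"warp_amplitude must be >= 0: {self.warp_amplitude}")
        if self.warp_scale <= 0:
            raise ValueError(f"warp_scale must be positive: {self.warp_scale}")


@dataclass
class ImagePair:
    """One low/high-quality pair sharing an identifier.

    ``registered`` records whether the two members are pixel-aligned (true only
    when the degradation used no warp)."""

    identifier: str
    low: np.ndarray
    high: np.ndarray
    registered: bool

    def __post_init__(self):
        if self.low.shape != self.high.shape:
            raise ValueError(
                f"pair {self.identifier}: low {self.low.shape} != high {self.high.shape}"
            )
        for name in ("low", "high"):
            img = getattr(self, name)
            if img.min() < 0.0 or img.max() > 1.0:
                raise ValueError(f"pair {self.identifier}: {name} outside [0, 1]")


def echogenicity_map(spec: PhantomSpec) -> np.ndarray:
    """The noiseless tissue-reflectivity map underlying a phantom."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.side_length
    img = np.full((s, s), spec.background_echogenicity, dtype=np.float32)
    lo_e, hi_e = spec.inclusion_echogenicity_range
    a_min, a_max = spec.inclusion_axis_range
    for _ in range(spec.n_inclusions):
        ax1 = rng.uniform(a_min, a_max)
        ax2 = rng.uniform(a_min, a_max)
        margin = max(ax1, ax2)
        r = rng.uniform(margin, s - margin)
        c = rng.uniform(margin, s - margin)
        theta = rng.uniform(0.0, np.pi)
        echo = rng.uniform(lo_e, hi_e)
        rr, cc = _ellipse(r, c, ax1, ax2, shape=(s, s), rotation=theta)
        img[rr, cc] = echo
    return img


def render_phantom(spec: PhantomSpec) -> np.ndarray:
    """Echogenicity map times unit-mean speckle, clipped to [0, 1]."""
    emap = echogenicity_map(spec)
    # Distinct stream from the geometry stream so the same seed never reuses draws.
    speckle_seed = np.random.SeedSequence([spec.seed, 0x5EED]).generate_state(1)[0]
    return apply_speckle(emap, spec.speckle_looks_high, int(speckle_seed))


def apply_speckle(image: np.ndarray, looks: float, seed: int) -> np.ndarray:
    """Multiply by a gamma(shape=looks, mean=1) field; clip to [0, 1]."""
    if looks <= 0:
        raise ValueError(f"looks must be positive: {looks}")
    image = np.asarray(image)
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("apply_speckle: image must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    speckle = rng.gamma(shape=looks, scale=1.0 / looks, size=image.shape)
    return np.clip(image * speckle, 0.0, 1.0).astype(np.float32)


def _smooth_warp(shape: tuple, amplitude: float, scale: float, rng) -> np.ndarray:
    """Coarse random displacement field, Gaussian-smoothed, peak |d| = amplitude."""
    disp = rng.normal(size=(2, *shape))
    disp = np.stack([ndimage.gaussian_filter(d, sigma=scale) for d in disp])
    peak = np.abs(disp).max()
    if peak > 0:
        disp *= amplitude / peak
    return disp


def degrade(high: np.ndarray, dspec: DegradationSpec) -> np.ndarray:
    """Run the warp → blur → resample → contrast → speckle chain."""
    high = np.asarray(high, dtype=np.float64)
    if high.min() < 0.0 or high.max() > 1.0:
        raise ValueError("degrade: input must lie in [0, 1]")
    s = high.shape[0]
    dspec.validate(side_length=s)
    rng = np.random.default_rng(dspec.seed)
    img = high

    if dspec.warp_amplitude > 0:
        disp = _smooth_warp(img.shape, dspec.warp_amplitude, dspec.warp_scale, rng)
        rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(np.float64)
        img = ndimage.map_coordinates(
            img, [rows + disp[0], cols + disp[1]], order=1, mode="reflect"
        )

    if dspec.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=dspec.psf_sigma)

    f = dspec.downsample_factor
    if f > 1:
        h, w = img.shape
        small = img.reshape(h // f, f, w // f, f).mean(axis=(1, 3))
        img = np.repeat(np.repeat(small, f, axis=0), f, axis=1)

    if dspec.contrast_gamma != 1.0:
        img = np.clip(img, 0.0, 1.0) ** dspec.contrast_gamma

    img = np.clip(img, 0.0, 1.0)
    speckle_seed = int(rng.integers(0, 2**31 - 1))
    return apply_speckle(img, dspec.speckle_looks_low, speckle_seed)


def make_dataset(
    n_pairs: int, pspec: PhantomSpec, dspec: DegradationSpec, seed: int
) -> list[ImagePair]:
    """Generate ``n_pairs`` pairs with per-pair seeds spawned from ``seed``."""
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1: {n_pairs}")
    pspec.validate()
    dspec.validate(side_length=pspec.side_length)
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_pairs)
    pairs = []
    for i in range(n_pairs):
        p_i = replace(pspec, seed=int(seeds[2 * i]))
        d_i = replace(dspec, seed=int(seeds[2 * i + 1]))
        high = render_phantom(p_i)
        low = degrade(high, d_i)
        pairs.append(
            ImagePair(
                identifier=f"pair_{i:05d}",
                low=low,
                high=high,
                registered=dspec.warp_amplitude == 0,
            )
        )
    return pairs
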