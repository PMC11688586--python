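"""Full-reference image-quality metrics (SSI, LNCC, PSNR, perceptual distance)
and the paired one-sided significance comparison.

All metrics operate on images mapped to the unit interval with MAX_I = 1, so
PSNR is invariant to the bit depth of the source files.  SSI is windowed by
default (11x11 Gaussian, sigma 1.5, the standard formulation); the single
whole-image-moment form is kept as ``global`` mode.  LNCC is the mean over
patch centers of the local Pearson correlation between the two images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.metrics import structural_similarity as _skimage_ssim

from .losses import FeatureExtractor, lpips_distance

__all__ = [
    "MetricConfig",
    "MetricReport",
    "ssi",
    "lncc",
    "psnr",
    "lpips_metric",
    "evaluate_dataset",
    "wilcoxon_one_sided",
    "METRIC_ORIENTATION",
]

PSNR_CAP_DB = 100.0

#: direction of improvement per metric column (+1 higher better, -1 lower better)
METRIC_ORIENTATION = {"ssi": +1, "lncc": +1, "psnr": +1, "lpips": -1}


@dataclass(frozen=True)
class MetricConfig:
    ssi_mode: str = "windowed"  # or "global"
    window_side: int = 11
    window_sigma: float = 1.5
    lncc_window: int = 9
    data_range: float = 1.0
    epsilon: float = 1e-8

    def validate(self) -> None:
        if self.ssi_mode not in ("windowed", "global"):
            raise ValueError(f"ssi_mode must be windowed|global: {self.ssi_mode}")
        for name in ("window_side", "lncc_window"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3: {w}")
        if self.data_range <= 0:
            raise ValueError(f"data_range must be positive: {self.data_range}")


@dataclass
class MetricReport:
    """Per-pair metric table plus aggregate means."""

    per_pair: pd.DataFrame  # columns: identifier, ssi, lncc, psnr, lpips
    means: dict[str, float]
    n: int
    psnr_capped: bool = False

    @classmethod
    def from_table(cls, per_pair: pd.DataFrame) -> "MetricReport":
        capped = bool(np.isinf(per_pair["psnr"]).any())
        if capped:
            warnings.warn(
                f"infinite PSNR capped at {PSNR_CAP_DB} dB in the aggregate mean"
            )
        psnr_col = per_pair["psnr"].replace(np.inf, PSNR_CAP_DB)
        means = {
            "ssi": float(per_pair["ssi"].mean()),
            "lncc": float(per_pair["lncc"].mean()),
            "psnr": float(psnr_col.mean()),
            "lpips": float(per_pair["lpips"].mean()),
        }
        return cls(per_pair=per_pair, means=means, n=len(per_pair), psnr_capped=capped)


def _check_pair(H: np.ndarray, H_prime: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H = np.asarray(H, dtype=np.float64)
    H_prime = np.asarray(H_prime, dtype=np.float64)
    if H.shape != H_prime.shape:
        raise ValueError(f"shape mismatch: {H.shape} vs {H_prime.shape}")
    return H, H_prime


def ssi(H, H_prime, cfg: MetricConfig = MetricConfig()) -> float:
    """Structural similarity between ``H`` and ``H_prime``."""
    cfg.validate()
    H, H_prime = _check_pair(H, H_prime)
    c1 = (0.01 * cfg.data_range) ** 2
    c2 = (0.03 * cfg.data_range) ** 2
    if cfg.ssi_mode == "global":
        mu_x, mu_y = H.mean(), H_prime.mean()
        var_x, var_y = H.var(), H_prime.var()
        cov = ((H - mu_x) * (H_prime - mu_y)).mean()
        return float(
            (2 * mu_x * mu_y + c1)
            * (2 * cov + c2)
            / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
        )
    return float(
        _skimage_ssim(
            H,
            H_prime,
            data_range=cfg.data_range,
            gaussian_weights=True,
            sigma=cfg.window_sigma,
            win_size=cfg.window_side,
            use_sample_covariance=False,
        )
    )


def lncc(H, H_prime, cfg: MetricConfig = MetricConfig()) -> float:
    """Mean local Pearson correlation over sliding windows, clipped to [-1, 1]."""
    cfg.validate()
    H, H_prime = _check_pair(H, H_prime)
    w = cfg.lncc_window
    uf = lambda a: ndimage.uniform_filter(a, size=w, mode="reflect")
    mx, my = uf(H), uf(H_prime)
    cov = uf(H * H_prime) - mx * my
    var_x = np.maximum(uf(H * H) - mx * mx, 0.0)
    var_y = np.maximum(uf(H_prime * H_prime) - my * my, 0.0)
    ncc = cov / (np.sqrt(var_x) * np.sqrt(var_y) + cfg.epsilon)
    return float(np.clip(ncc, -1.0, 1.0).mean())


def psnr(H, H_prime, cfg: MetricConfig = MetricConfig()) -> float:
    """10 log10(MAX_I^2 / MSE) in dB; +inf for identical images."""
    cfg.validate()
    H, H_prime = _check_pair(H, H_prime)
    mse = float(np.mean((H - H_prime) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(cfg.data_range**2 / mse))


def lpips_metric(H, H_prime, fx: FeatureExtractor) -> float:
    """Perceptual distance on a single [0, 1] pair (lower is better)."""
    H, H_prime = _check_pair(H, H_prime)
    x = (H * 2.0 - 1.0)[None, None].astype(np.float32)
    y = (H_prime * 2.0 - 1.0)[None, None].astype(np.float32)
    return float(lpips_distance(fx, x, y).data)


def evaluate_dataset(
    pairs,
    enhancer: Callable | None = None,
    cfg: MetricConfig = MetricConfig(),
    fx: FeatureExtractor | None = None,
) -> MetricReport:
    """Score (enhanced low vs high) for every pair.

    ``enhancer`` maps a [0, 1] image to a [0, 1] image; ``None`` is the
    identity, which reproduces the unenhanced reference-low baseline."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_dataset: empty pair list")
    cfg.validate()
    fx = fx or FeatureExtractor.random_conv(seed=0)
    rows = []
    for pair in pairs:
        out = pair.low if enhancer is None else enhancer(pair.low)
        rows.append(
            {
                "identifier": pair.identifier,
                "ssi": ssi(pair.high, out, cfg),
                "lncc": lncc(pair.high, out, cfg),
                "psnr": psnr(pair.high, out, cfg),
                "lpips": lpips_metric(pair.high, out, fx),
            }
        )
    return MetricReport.from_table(pd.DataFrame(rows))


def wilcoxon_one_sided(
    scores_a, scores_b, higher_better: bool = True
) -> float:
    """P-value that model a beats model b on paired per-image scores.

    Exact signed-rank distribution for small samples (scipy switches to the
    normal approximation for larger n or ties).  Returns NaN with a warning
    when every paired difference is zero (the statistic is undefined)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("wilcoxon_one_sided: inputs must be equal-length 1-D")
    if len(a) < 5:
        raise ValueError("wilcoxon_one_sided: need at least 5 pairs")
    d = a - b if higher_better else b - a
    if np.all(d == 0):
        warnings.warn("wilcoxon_one_sided: all differences zero, p undefined")
        return float("nan")
    res = stats.wilcoxon(d, alternative="greater")
    return float(res.pvalue)
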