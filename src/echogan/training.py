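"""Training orchestration: data split, learning-rate schedule, alternating
generator/discriminator optimization, checkpointing, and inference-time
enhancement.

One training step updates both generators jointly on the aggregate objective
(adversarial + cycle + paired-L1 + perceptual, each weighted by its lambda),
then updates each discriminator on its own least-squares objective with the
conditional label-smoothing rule evaluated from that step's score means.
Discriminators score detached fakes, so neither update leaks into the other's
parameters; the perceptual backbone is frozen throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import (
    FeatureExtractor,
    LossRecord,
    LossWeights,
    adversarial_term,
    discriminator_term,
    l1_term,
    lpips_distance,
    real_label,
    total_generator_loss,
)
from .metrics import MetricConfig, evaluate_dataset
from .models import (
    Discriminator,
    DiscriminatorSpec,
    Generator,
    GeneratorSpec,
    build_discriminator,
    build_generator,
)
from .nn import Adam, GradScaler, Tensor
from .phantom import ImagePair

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "TrainingHistory",
    "CycleGanModels",
    "split_dataset",
    "lr_at_epoch",
    "train_step",
    "fit",
    "enhance",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    batch_size: int = 4
    lr_initial: float = 3e-4
    beta1: float = 0.9
    beta2: float = 0.999
    lr_gamma: float = 0.5
    lr_step: int = 100
    loss_weights: LossWeights = field(default_factory=LossWeights)
    mixed_precision: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1: {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1: {self.batch_size}")
        if not 0.0 < self.lr_gamma <= 1.0:
            raise ValueError(f"lr_gamma must be in (0, 1]: {self.lr_gamma}")
        if self.lr_step < 1:
            raise ValueError(f"lr_step must be >= 1: {self.lr_step}")
        self.loss_weights.validate()


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    val_fraction: float = 0.10
    test_fraction: float = 0.20
    seed: int = 0

    def validate(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1: {total}")


@dataclass
class TrainingHistory:
    """Per-epoch mean losses, validation metric means, and the lr trace."""

    rows: list[dict] = field(default_factory=list)

    def append(self, row: dict) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


@dataclass
class CycleGanModels:
    g_h: Generator
    g_l: Generator
    d_h: Discriminator
    d_l: Discriminator

    @classmethod
    def build(
        cls, gspec: GeneratorSpec, dspec: DiscriminatorSpec, seed: int = 0
    ) -> "CycleGanModels":
        seeds = np.random.SeedSequence(seed).generate_state(4)
        return cls(
            g_h=build_generator(gspec, seed=int(seeds[0]), role_tag="G_H"),
            g_l=build_generator(gspec, seed=int(seeds[1]), role_tag="G_L"),
            d_h=build_discriminator(dspec, seed=int(seeds[2]), role_tag="D_H"),
            d_l=build_discriminator(dspec, seed=int(seeds[3]), role_tag="D_L"),
        )

    def train(self):
        for m in (self.g_h, self.g_l, self.d_h, self.d_l):
            m.train()

    def eval(self):
        for m in (self.g_h, self.g_l, self.d_h, self.d_l):
            m.eval()


def split_dataset(
    pairs: list[ImagePair], spec: SplitSpec = SplitSpec()
) -> tuple[list[ImagePair], list[ImagePair], list[ImagePair]]:
    """Disjoint, exhaustive train/val/test partition; floor sizes for val and
    test, remainder to train; deterministic shuffle under the split seed."""
    spec.validate()
    pairs = list(pairs)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need at least 3 pairs to split: {n}")
    n_val = math.floor(spec.val_fraction * n)
    n_test = math.floor(spec.test_fraction * n)
    n_train = n - n_val - n_test
    order = np.random.default_rng(spec.seed).permutation(n)
    shuffled = [pairs[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step decay: lr_initial * gamma^floor(epoch / step)."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0: {epoch}")
    return cfg.lr_initial * cfg.lr_gamma ** (epoch // cfg.lr_step)


def _to_net(batch: np.ndarray) -> Tensor:
    """[0,1] (N,H,W) stack -> [-1,1] (N,1,H,W) tensor."""
    return Tensor((batch[:, None] * 2.0 - 1.0).astype(np.float32))


def _from_net(out: np.ndarray) -> np.ndarray:
    return np.clip((out[:, 0] + 1.0) / 2.0, 0.0, 1.0)


def train_step(
    batch_low: Tensor,
    batch_high: Tensor,
    models: CycleGanModels,
    opt_g: Adam,
    opt_d_h: Adam,
    opt_d_l: Adam,
    fx: FeatureExtractor,
    weights: LossWeights,
    scaler: GradScaler | None = None,
    label_rule: str = "per_discriminator",
) -> LossRecord:
    """One generator update followed by one update per discriminator.

    ``batch_low``/``batch_high`` are (N,1,H,W) tensors in [-1,1].
    ``label_rule`` selects whose score means drive label smoothing:
    ``per_discriminator`` (each from its own batch) or ``d_h_only`` (the
    high-quality discriminator's means are applied to both)."""
    if label_rule not in ("per_discriminator", "d_h_only"):
        raise ValueError(f"unknown label_rule: {label_rule}")
    scaler = scaler or GradScaler(enabled=False)
    g_h, g_l, d_h, d_l = models.g_h, models.g_l, models.d_h, models.d_l

    # -- generator update (both generators jointly) -----------------------
    fake_h = g_h(batch_low)
    fake_l = g_l(batch_high)
    scores_fake_h = d_h(fake_h)
    scores_fake_l = d_l(fake_l)
    adv = adversarial_term(scores_fake_h, scores_fake_l)
    rec_l = g_l(fake_h)
    rec_h = g_h(fake_l)
    cycle = (rec_l - batch_low).abs().mean() + (rec_h - batch_high).abs().mean()
    l1 = (fake_h - batch_high).abs().mean() + (fake_l - batch_low).abs().mean()
    perceptual = lpips_distance(fx, batch_high, fake_h) + lpips_distance(
        fx, batch_low, fake_l
    )
    total = total_generator_loss(adv, cycle, l1, perceptual, weights)
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite generator loss; step aborted")
    gen_params = g_h.parameters() + g_l.parameters()
    for m in (g_h, g_l, d_h, d_l):
        m.zero_grad()
    scaler.scale_loss(total).backward()
    scaler.unscale(gen_params)
    if any(w > 0 for w in (weights.lambda_adv, weights.lambda_cycle,
                           weights.lambda_l1, weights.lambda_per)):
        opt_g.step()

    # -- discriminator updates on detached fakes --------------------------
    disc_losses = {}
    shared_label = None
    for tag, disc, opt, real, fake in (
        ("disc_H", d_h, opt_d_h, batch_high, fake_h),
        ("disc_L", d_l, opt_d_l, batch_low, fake_l),
    ):
        fake_det = Tensor(fake.data.copy())
        scores_real = disc(real.detach())
        scores_fake = disc(fake_det)
        label = real_label(
            float(scores_real.data.mean()), float(scores_fake.data.mean())
        )
        if label_rule == "d_h_only":
            if tag == "disc_H":
                shared_label = label
            else:
                label = shared_label
        loss_d = discriminator_term(scores_real, scores_fake, label)
        if not np.isfinite(loss_d.data):
            raise FloatingPointError(f"non-finite {tag} loss; step aborted")
        disc.zero_grad()
        scaler.scale_loss(loss_d).backward()
        scaler.unscale(disc.parameters())
        opt.step()
        disc_losses[tag] = float(loss_d.data)

    record = LossRecord(
        adv=float(adv.data),
        cycle=float(cycle.data),
        l1=float(l1.data),
        perceptual=float(perceptual.data),
        total=float(total.data),
        disc_H=disc_losses["disc_H"],
        disc_L=disc_losses["disc_L"],
    )
    record.validate(weights)
    return record


def fit(
    cfg: TrainConfig,
    train_pairs: list[ImagePair],
    val_pairs: list[ImagePair],
    out_dir: str | Path,
    gspec: GeneratorSpec = GeneratorSpec(),
    dspec: DiscriminatorSpec = DiscriminatorSpec(),
    fx: FeatureExtractor | None = None,
    metric_cfg: MetricConfig = MetricConfig(),
) -> tuple[Path, TrainingHistory]:
    """Full training loop; returns (best checkpoint path, history)."""
    cfg.validate()
    if not train_pairs:
        raise ValueError("fit: empty training set")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx = fx or FeatureExtractor.random_conv(seed=cfg.seed)
    models = CycleGanModels.build(gspec, dspec, seed=cfg.seed)
    betas = (cfg.beta1, cfg.beta2)
    opt_g = Adam(models.g_h.parameters() + models.g_l.parameters(),
                 lr=cfg.lr_initial, betas=betas)
    opt_d_h = Adam(models.d_h.parameters(), lr=cfg.lr_initial, betas=betas)
    opt_d_l = Adam(models.d_l.parameters(), lr=cfg.lr_initial, betas=betas)
    scaler = GradScaler(enabled=cfg.mixed_precision)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)

    history = TrainingHistory()
    log_rows = []
    best_psnr = -np.inf
    best_path = out_dir / "checkpoint_best.npz"
    latest_path = out_dir / "checkpoint_latest.npz"

    lows = np.stack([p.low for p in train_pairs])
    highs = np.stack([p.high for p in train_pairs])
    n = len(train_pairs)

    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(cfg, epoch)
        for opt in (opt_g, opt_d_h, opt_d_l):
            opt.lr = lr
        models.train()
        order = shuffle_rng.permutation(n)
        epoch_records = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            rec = train_step(
                _to_net(lows[idx]),
                _to_net(highs[idx]),
                models,
                opt_g,
                opt_d_h,
                opt_d_l,
                fx,
                cfg.loss_weights,
                scaler,
            )
            log_rows.append(
                {"epoch": epoch, "iter": start // cfg.batch_size, "lr": lr,
                 **asdict(rec)}
            )
            epoch_records.append(rec)

        row = {
            "epoch": epoch,
            "lr": lr,
            **{
                k: float(np.mean([getattr(r, k) for r in epoch_records]))
                for k in ("adv", "cycle", "l1", "perceptual", "total",
                          "disc_H", "disc_L")
            },
        }
        if val_pairs:
            models.eval()
            report = evaluate_dataset(
                val_pairs, _make_enhancer(models.g_h), metric_cfg, fx
            )
            row.update({f"val_{k}": v for k, v in report.means.items()})
            if report.means["psnr"] > best_psnr:
                best_psnr = report.means["psnr"]
                save_checkpoint(best_path, models, gspec, dspec, cfg, epoch,
                                opt_g, opt_d_h, opt_d_l)
        history.append(row)
        save_checkpoint(latest_path, models, gspec, dspec, cfg, epoch,
                        opt_g, opt_d_h, opt_d_l)

    if not val_pairs or not best_path.exists():
        best_path = latest_path
    pd.DataFrame(log_rows).to_csv(out_dir / "training_log.csv", index=False)
    history.to_frame().to_csv(out_dir / "history.csv", index=False)
    return best_path, history


def _make_enhancer(g_h: Generator):
    def enhancer(low: np.ndarray) -> np.ndarray:
        out = g_h(_to_net(low[None]))
        return _from_net(out.data)[0]

    return enhancer


def save_checkpoint(
    path: str | Path,
    models: CycleGanModels,
    gspec: GeneratorSpec,
    dspec: DiscriminatorSpec,
    cfg: TrainConfig,
    epoch: int,
    opt_g: Adam | None = None,
    opt_d_h: Adam | None = None,
    opt_d_l: Adam | None = None,
) -> None:
    """Single archive holding all four parameter sets, both specs, optimizer
    state, the epoch counter and the seed; version-tagged."""
    arrays: dict[str, np.ndarray] = {}
    for tag, m in (("g_h", models.g_h), ("g_l", models.g_l),
                   ("d_h", models.d_h), ("d_l", models.d_l)):
        for k, v in m.named_state().items():
            arrays[f"{tag}.{k}"] = v
    for tag, opt in (("opt_g", opt_g), ("opt_d_h", opt_d_h), ("opt_d_l", opt_d_l)):
        if opt is None:
            continue
        st = opt.state()
        arrays[f"{tag}.t"] = np.array(st["t"])
        arrays[f"{tag}.lr"] = np.array(st["lr"])
        for i, (m_arr, v_arr) in enumerate(zip(st["m"], st["v"])):
            arrays[f"{tag}.m{i}"] = m_arr
            arrays[f"{tag}.v{i}"] = v_arr
    meta = {
        "version": CHECKPOINT_VERSION,
        "epoch": epoch,
        "seed": cfg.seed,
        "generator_spec": asdict(gspec),
        "discriminator_spec": asdict(dspec),
        "train_config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(cfg).items()
        },
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> tuple[CycleGanModels, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        gspec_d = dict(meta["generator_spec"])
        gspec_d["dropout_stages"] = tuple(gspec_d["dropout_stages"])
        gspec = GeneratorSpec(**gspec_d)
        dspec = DiscriminatorSpec(**meta["discriminator_spec"])
        models = CycleGanModels.build(gspec, dspec, seed=meta["seed"])
        for tag, m in (("g_h", models.g_h), ("g_l", models.g_l),
                       ("d_h", models.d_h), ("d_l", models.d_l)):
            prefix = tag + "."
            state = {
                k[len(prefix):]: data[k]
                for k in data.files
                if k.startswith(prefix)
            }
            m.load_state(state)
    return models, meta


def enhance(
    checkpoint: str | Path | CycleGanModels, lows: list[np.ndarray] | np.ndarray
) -> list[np.ndarray]:
    """Apply the trained G_H in evaluation mode to [0, 1] images."""
    if isinstance(checkpoint, CycleGanModels):
        models = checkpoint
    else:
        models, _ = load_checkpoint(checkpoint)
    models.eval()
    single = isinstance(lows, np.ndarray) and np.ndim(lows) == 2
    stack = [lows] if single else list(lows)
    out = []
    for low in stack:
        enhanced = _from_net(models.g_h(_to_net(np.asarray(low)[None])).data)[0]
        out.append(enhanced.astype(np.float32))
    return out
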