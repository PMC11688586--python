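"""Split arithmetic, lr schedule, optimization step scope, and the fit loop."""

import dataclasses

import numpy as np
import pytest

from echogan.losses import FeatureExtractor, LossWeights
from echogan.metrics import MetricConfig
from echogan.nn import Adam, Tensor
from echogan.training import (
    CycleGanModels,
    SplitSpec,
    TrainConfig,
    enhance,
    fit,
    load_checkpoint,
    lr_at_epoch,
    split_dataset,
    train_step,
)

FAST_METRICS = MetricConfig(lncc_window=3)


class TestSplitDataset:
    def test_corpus_scale_split_sizes(self):
        """70/10/20 of 1050 -> 735/105/210 (210-pair hold-out test set)."""
        train, val, test = split_dataset(list(range(1050)), SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (735, 105, 210)

    def test_floor_arithmetic_remainder_to_train(self):
        train, val, test = split_dataset(list(range(10)), SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (7, 1, 2)

    def test_partition_is_disjoint_and_exhaustive(self):
        items = list(range(101))
        train, val, test = split_dataset(items, SplitSpec(seed=3))
        combined = sorted(train + val + test)
        assert combined == items

    def test_same_seed_reproduces_partition(self):
        items = list(range(50))
        a = split_dataset(items, SplitSpec(seed=9))
        b = split_dataset(items, SplitSpec(seed=9))
        assert a == b

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(list(range(10)), SplitSpec(0.5, 0.1, 0.2))

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_dataset([1, 2], SplitSpec())


class TestLrSchedule:
    @pytest.mark.parametrize(
        "epoch,expected", [(0, 3e-4), (99, 3e-4), (100, 1.5e-4), (150, 1.5e-4),
                           (299, 7.5e-5)]
    )
    def test_step_decay_values(self, epoch, expected):
        assert lr_at_epoch(TrainConfig(), epoch) == pytest.approx(expected)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            lr_at_epoch(TrainConfig(), -1)

    def test_trace_nonincreasing_with_breaks_at_step_multiples(self):
        cfg = TrainConfig(epochs=250, lr_step=100)
        trace = [lr_at_epoch(cfg, e) for e in range(250)]
        assert all(a >= b for a, b in zip(trace, trace[1:]))
        changes = [e for e in range(1, 250) if trace[e] != trace[e - 1]]
        assert changes == [100, 200]


def _tiny_setup(tiny_gspec, tiny_discspec, seed=0, weights=None):
    models = CycleGanModels.build(tiny_gspec, tiny_discspec, seed=seed)
    betas = (0.9, 0.999)
    opt_g = Adam(models.g_h.parameters() + models.g_l.parameters(),
                 lr=1e-3, betas=betas)
    opt_dh = Adam(models.d_h.parameters(), lr=1e-3, betas=betas)
    opt_dl = Adam(models.d_l.parameters(), lr=1e-3, betas=betas)
    fx = FeatureExtractor.random_conv(seed=0, n_stages=2, base_channels=4)
    return models, opt_g, opt_dh, opt_dl, fx, weights or LossWeights()


def _batch(rng, n=2, side=32):
    return Tensor(rng.uniform(-1, 1, (n, 1, side, side)).astype(np.float32))


class TestTrainStep:
    def test_all_four_networks_update(self, tiny_gspec, tiny_discspec, rng):
        models, og, odh, odl, fx, w = _tiny_setup(tiny_gspec, tiny_discspec)
        before = {
            tag: m.named_state()["enc0.weight" if "g" in tag else "conv0.weight"].copy()
            for tag, m in (("g_h", models.g_h), ("g_l", models.g_l),
                           ("d_h", models.d_h), ("d_l", models.d_l))
        }
        train_step(_batch(rng), _batch(rng), models, og, odh, odl, fx, w)
        after = {
            tag: m.named_state()["enc0.weight" if "g" in tag else "conv0.weight"]
            for tag, m in (("g_h", models.g_h), ("g_l", models.g_l),
                           ("d_h", models.d_h), ("d_l", models.d_l))
        }
        for tag in before:
            assert not np.array_equal(before[tag], after[tag]), tag

    def test_zero_weights_freeze_generators(self, tiny_gspec, tiny_discspec, rng):
        zero = LossWeights(0.0, 0.0, 0.0, 0.0)
        models, og, odh, odl, fx, w = _tiny_setup(
            tiny_gspec, tiny_discspec, weights=zero
        )
        before = models.g_h.named_state()["enc0.weight"].copy()
        train_step(_batch(rng), _batch(rng), models, og, odh, odl, fx, w)
        assert np.array_equal(before, models.g_h.named_state()["enc0.weight"])

    def test_generator_optimizer_owns_no_discriminator_parameters(
        self, tiny_gspec, tiny_discspec
    ):
        models, og, odh, odl, fx, w = _tiny_setup(tiny_gspec, tiny_discspec)
        disc_param_ids = {id(p) for p in models.d_h.parameters()}
        disc_param_ids |= {id(p) for p in models.d_l.parameters()}
        assert disc_param_ids.isdisjoint({id(p) for p in og.params})

    def test_identical_seeds_reproduce_first_step_record(
        self, tiny_gspec, tiny_discspec
    ):
        records = []
        for _ in range(2):
            models, og, odh, odl, fx, w = _tiny_setup(
                tiny_gspec, tiny_discspec, seed=5
            )
            r = np.random.default_rng(77)
            records.append(
                train_step(_batch(r), _batch(r), models, og, odh, odl, fx, w)
            )
        assert records[0] == records[1]

    def test_strict_label_rule_mode_runs(self, tiny_gspec, tiny_discspec, rng):
        models, og, odh, odl, fx, w = _tiny_setup(tiny_gspec, tiny_discspec)
        rec = train_step(_batch(rng), _batch(rng), models, og, odh, odl, fx, w,
                         label_rule="d_h_only")
        rec.validate(w)
        with pytest.raises(ValueError, match="label_rule"):
            train_step(_batch(rng), _batch(rng), models, og, odh, odl, fx, w,
                       label_rule="bogus")

    def test_feature_extractor_frozen_through_step(
        self, tiny_gspec, tiny_discspec, rng
    ):
        models, og, odh, odl, fx, w = _tiny_setup(tiny_gspec, tiny_discspec)
        before = {k: v.copy() for k, v in fx.state().items()}
        train_step(_batch(rng), _batch(rng), models, og, odh, odl, fx, w)
        after = fx.state()
        assert before.keys() == after.keys() and len(before) > 0
        for k in before:
            assert np.array_equal(before[k], after[k])

    def test_gradient_of_total_loss_is_finite_and_nonzero(
        self, tiny_gspec, tiny_discspec, rng
    ):
        from echogan.losses import (
            adversarial_term,
            lpips_distance,
            total_generator_loss,
        )

        models, *_rest, fx, w = _tiny_setup(tiny_gspec, tiny_discspec)
        L, H = _batch(rng), _batch(rng)
        fake_h = models.g_h(L)
        fake_l = models.g_l(H)
        adv = adversarial_term(models.d_h(fake_h), models.d_l(fake_l))
        cyc = (models.g_l(fake_h) - L).abs().mean() + (
            models.g_h(fake_l) - H
        ).abs().mean()
        l1 = (fake_h - H).abs().mean() + (fake_l - L).abs().mean()
        per = lpips_distance(fx, H, fake_h) + lpips_distance(fx, L, fake_l)
        total_generator_loss(adv, cyc, l1, per, w).backward()
        grads = [p.grad for p in models.g_h.parameters() if p.grad is not None]
        assert grads, "no gradients reached the generator"
        assert all(np.all(np.isfinite(g)) for g in grads)
        assert any(np.any(g != 0) for g in grads)


class TestFitAndEnhance:
    @pytest.fixture(scope="class")
    def fitted(self, tiny_pairs, tiny_gspec, tiny_discspec, tmp_path_factory):
        out = tmp_path_factory.mktemp("run")
        cfg = TrainConfig(epochs=2, batch_size=4, lr_initial=1e-3, seed=3)
        fx = FeatureExtractor.random_conv(seed=3, n_stages=2, base_channels=4)
        ckpt, history = fit(
            cfg, tiny_pairs[:6], tiny_pairs[6:], out,
            gspec=tiny_gspec, dspec=tiny_discspec, fx=fx,
            metric_cfg=FAST_METRICS,
        )
        return cfg, ckpt, history, out

    def test_history_has_one_row_per_epoch(self, fitted):
        cfg, _, history, _ = fitted
        frame = history.to_frame()
        assert len(frame) == cfg.epochs
        assert np.isfinite(frame["total"]).all()

    def test_lr_trace_matches_schedule(self, fitted):
        cfg, _, history, _ = fitted
        frame = history.to_frame()
        for _, row in frame.iterrows():
            assert row["lr"] == pytest.approx(lr_at_epoch(cfg, int(row["epoch"])))

    def test_training_log_written(self, fitted):
        *_, out = fitted
        assert (out / "training_log.csv").exists()
        assert (out / "history.csv").exists()

    def test_checkpoint_roundtrip_preserves_outputs(self, fitted, rng):
        _, ckpt, _, _ = fitted
        models, meta = load_checkpoint(ckpt)
        assert meta["epoch"] >= 0
        img = rng.uniform(0, 1, (32, 32)).astype(np.float32)
        out1 = enhance(models, img)[0]
        models2, _ = load_checkpoint(ckpt)
        out2 = enhance(models2, img)[0]
        assert np.array_equal(out1, out2)

    def test_enhance_preserves_shape_and_range(self, fitted, rng):
        _, ckpt, _, _ = fitted
        img = rng.uniform(0, 1, (32, 32)).astype(np.float32)
        out = enhance(ckpt, img)[0]
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert np.array_equal(out, enhance(ckpt, img)[0])

    def test_empty_training_set_rejected(self, tiny_gspec, tiny_discspec, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            fit(TrainConfig(epochs=1), [], [], tmp_path,
                gspec=tiny_gspec, dspec=tiny_discspec)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad", [{"epochs": 0}, {"batch_size": 0}, {"lr_gamma": 0.0},
                {"lr_gamma": 1.5}]
    )
    def test_invalid_train_config_rejected(self, bad):
        with pytest.raises(ValueError):
            dataclasses.replace(TrainConfig(), **bad).validate()
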