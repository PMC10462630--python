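"""Training protocols: oversampling, checkpoint rule, warm-up, determinism."""

import numpy as np
import pytest

from ecgadapt import training as T
from ecgadapt.model import LambdaSchedule, NetworkConfig, adaptive_lambda
from ecgadapt.training import (EpochRecord, ImageSet, TrainConfig, oversample,
                               should_checkpoint, train_adversarial,
                               train_vanilla)


def blob_image_set(n: int, h: int = 24, w: int = 40, seed: int = 0) -> ImageSet:
    """Linearly separable toy images: class 1 has a bright top-left blob,
    class 0 a bright bottom-right blob, plus noise."""
    rng = np.random.default_rng(seed)
    X = rng.random((n, h, w, 3), dtype=np.float32) * 0.3
    y = (rng.random(n) < 0.5).astype(np.float32)
    # ensure both classes
    y[0], y[1] = 0.0, 1.0
    for i in range(n):
        if y[i]:
            X[i, 2 : h // 3, 2 : w // 3] += 0.6
        else:
            X[i, -h // 3 : -2, -w // 3 : -2] += 0.6
    np.clip(X, 0, 1, out=X)
    return ImageSet(X, y)


TINY_NET = NetworkConfig(input_h=24, input_w=40, channels=(4, 8),
                         strides=(2, 2), dropout_p=0.1, seed=0)


class TestOversample:
    def test_imbalanced_replicated_to_target(self):
        y = np.array([1] * 10 + [0] * 90, dtype=bool)
        idx = oversample(y, 0.5, rng=0)
        n_pos = int(y[idx].sum())
        n_neg = len(idx) - n_pos
        assert n_neg == 90
        assert abs(n_pos - 90) <= 1
        # all originals retained
        assert set(range(100)) <= set(idx.tolist())

    def test_balanced_input_unchanged(self):
        y = np.array([1, 0] * 10, dtype=bool)
        idx = oversample(y, 0.5, rng=0)
        assert sorted(idx.tolist()) == list(range(20))

    @pytest.mark.parametrize("target", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_target_rejected(self, target):
        with pytest.raises(ValueError):
            oversample(np.array([1, 0], dtype=bool), target, rng=0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            oversample(np.ones(5, dtype=bool), 0.5, rng=0)


class TestShouldCheckpoint:
    def test_accepts_best_label_with_chance_domain(self):
        rec = EpochRecord(0, 0.5, val_auc=0.91, domain_acc=0.52, lam_end=1.0)
        assert should_checkpoint(rec, best_so_far=0.88)

    def test_rejects_confident_domain_classifier(self):
        rec = EpochRecord(0, 0.5, val_auc=0.95, domain_acc=0.70, lam_end=1.0)
        assert not should_checkpoint(rec, best_so_far=0.88)

    def test_rejects_non_improving_label_metric(self):
        rec = EpochRecord(0, 0.5, val_auc=0.80, domain_acc=0.50, lam_end=1.0)
        assert not should_checkpoint(rec, best_so_far=0.88)

    def test_window_boundaries_inclusive(self):
        for acc in (0.40, 0.60):
            rec = EpochRecord(0, 0.5, val_auc=0.9, domain_acc=acc, lam_end=1.0)
            assert should_checkpoint(rec, best_so_far=0.1)


class TestTrainVanilla:
    def test_learns_separable_toy_problem(self):
        tr = blob_image_set(48, seed=0)
        va = blob_image_set(24, seed=1)
        cfg = TrainConfig(lr=3e-3, batch_size=8, max_epochs=6,
                          domain_start_epoch=1, augment=False, seed=0)
        model, hist = train_vanilla(tr, va, TINY_NET, cfg)
        scores = model.predict_proba(tr.X, 16)
        acc = np.mean((scores > 0.5) == tr.y.astype(bool))
        assert acc >= 0.95
        assert len(hist.epochs) <= 6

    def test_two_runs_bitwise_identical(self):
        tr = blob_image_set(24, seed=2)
        va = blob_image_set(12, seed=3)
        cfg = TrainConfig(lr=1e-3, batch_size=8, max_epochs=2,
                          domain_start_epoch=1, augment=True, seed=5)
        _, h1 = train_vanilla(tr, va, TINY_NET, cfg)
        _, h2 = train_vanilla(tr, va, TINY_NET, cfg)
        assert [(r.train_loss, r.val_auc) for r in h1.epochs] \
            == [(r.train_loss, r.val_auc) for r in h2.epochs]

    def test_early_stopping_on_worsening_validation(self, monkeypatch):
        """Validation metric strictly worsening from epoch 2 while training
        loss falls => run stops after `patience` stagnant epochs."""
        seq = iter([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        monkeypatch.setattr(T, "_val_auc", lambda *a, **k: next(seq))
        # deterministic falling train loss
        losses = iter(np.linspace(1.0, 0.1, 10))
        monkeypatch.setattr(T, "_label_step", lambda *a, **k: float(next(losses)))
        tr = blob_image_set(16, seed=4)
        va = blob_image_set(8, seed=5)
        cfg = TrainConfig(lr=1e-3, batch_size=8, max_epochs=10,
                          early_stop_patience=3, domain_start_epoch=1,
                          augment=False, seed=0)
        _, hist = train_vanilla(tr, va, TINY_NET, cfg)
        # epoch 0 improves (first value), then 3 stagnant epochs -> stop at 4
        assert len(hist.epochs) == 4

    def test_single_class_training_set_rejected(self):
        ds = blob_image_set(8, seed=6)
        ds.y[:] = 1.0
        with pytest.raises(ValueError):
            train_vanilla(ds, blob_image_set(8, seed=7), TINY_NET,
                          TrainConfig(lr=1e-3, batch_size=8, max_epochs=2,
                                      domain_start_epoch=1))


def _adversarial_fixture(max_epochs=4, start=2, seed=0):
    src = blob_image_set(24, seed=10)
    # target: same images, globally darkened (a crude domain shift)
    tgt = ImageSet(np.clip(src.X * 0.6, 0, 1), None)
    val = blob_image_set(12, seed=11)
    mixed = ImageSet(np.concatenate([val.X, np.clip(val.X * 0.6, 0, 1)]),
                     np.array([0.0] * 12 + [1.0] * 12, dtype=np.float32))
    cfg = TrainConfig(lr=1e-3, batch_size=8, max_epochs=max_epochs,
                      domain_start_epoch=start, augment=False, seed=seed,
                      oversample_target=None)
    return src, tgt, val, mixed, cfg


class TestTrainAdversarial:
    def test_warmup_has_no_domain_updates(self):
        src, tgt, val, mixed, cfg = _adversarial_fixture(max_epochs=4, start=2)
        _, hist = train_adversarial(src, tgt, val, mixed, TINY_NET, cfg)
        per_epoch = hist.domain_updates_per_epoch
        assert per_epoch[:2] == [0, 0]
        assert all(n > 0 for n in per_epoch[2:])
        assert all(e >= 2 for e, _, _ in hist.lambda_trace)

    def test_lambda_trace_matches_closed_form(self):
        src, tgt, val, mixed, cfg = _adversarial_fixture(max_epochs=4, start=1)
        _, hist = train_adversarial(src, tgt, val, mixed, TINY_NET, cfg)
        n_batches = len(src) // cfg.batch_size
        sch = LambdaSchedule(n_batches, cfg.max_epochs)
        for (E, b, lam) in hist.lambda_trace:
            assert lam == adaptive_lambda(b, E, sch)

    def test_domain_head_untouched_before_start_epoch(self):
        """Interrupting the run right at the start epoch leaves the domain
        head at its initialization."""
        from ecgadapt.model import DannModel

        src, tgt, val, mixed, cfg = _adversarial_fixture(max_epochs=4, start=3)
        init = [p.copy() for p in DannModel(TINY_NET).domain_head.params]

        stop = {"n": 0}
        orig = T._domain_step

        def counting(*a, **k):
            stop["n"] += 1
            return orig(*a, **k)

        T._domain_step = counting
        try:
            model, hist = train_adversarial(src, tgt, val, mixed, TINY_NET, cfg)
        finally:
            T._domain_step = orig
        assert stop["n"] == sum(hist.domain_updates_per_epoch)
        assert hist.domain_updates_per_epoch[:3] == [0, 0, 0]

    def test_identical_domains_keep_domain_accuracy_near_chance(self):
        src = blob_image_set(24, seed=20)
        tgt = ImageSet(src.X.copy(), None)  # no shift at all
        val = blob_image_set(12, seed=21)
        mixed = ImageSet(np.concatenate([val.X, val.X.copy()]),
                         np.array([0.0] * 12 + [1.0] * 12, dtype=np.float32))
        cfg = TrainConfig(lr=1e-3, batch_size=8, max_epochs=5,
                          domain_start_epoch=1, augment=False, seed=1)
        _, hist = train_adversarial(src, tgt, val, mixed, TINY_NET, cfg)
        assert 0.3 <= hist.epochs[-1].domain_acc <= 0.7

    def test_accepted_checkpoints_satisfy_dual_rule(self):
        src, tgt, val, mixed, cfg = _adversarial_fixture(max_epochs=5, start=1)
        _, hist = train_adversarial(src, tgt, val, mixed, TINY_NET, cfg)
        best = -np.inf
        for rec in hist.epochs:
            if rec.epoch in hist.checkpoint_epochs:
                assert 0.40 <= rec.domain_acc <= 0.60
                assert rec.val_auc > best
            best = max(best, rec.val_auc)

    def test_two_runs_bitwise_identical(self):
        src, tgt, val, mixed, cfg = _adversarial_fixture(max_epochs=3, start=1)
        _, h1 = train_adversarial(src, tgt, val, mixed, TINY_NET, cfg)
        _, h2 = train_adversarial(src, tgt, val, mixed, TINY_NET, cfg)
        assert [(r.train_loss, r.val_auc, r.domain_acc) for r in h1.epochs] \
            == [(r.train_loss, r.val_auc, r.domain_acc) for r in h2.epochs]
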