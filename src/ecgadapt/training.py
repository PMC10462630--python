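"""Training protocols: supervised (vanilla) and domain-adversarial.

The adversarial protocol alternates two gradient streams. For the first
``domain_start_epoch`` epochs only labeled source (clean-page) minibatches
are used, updating feature extractor + label head by binary cross-entropy.
From then on every step alternates: (1) a source minibatch updates extractor
and label head; (2) a 50/50 random mix of source and target (captured)
images with domain labels (clean = 0, captured = 1) is pushed through the
domain head, and its loss is backpropagated into the extractor through the
gradient reversal layer with the adaptive coefficient lambda(b, E).

A model state is checkpointed only when the label metric (source-validation
ROC-AUC) strictly improves on the best so far AND the domain classifier is
near chance (accuracy in [0.40, 0.60] on a mixed validation set) — i.e. the
features solve the task while carrying no domain information. Training stops
at ``max_epochs`` or earlier, after ``early_stop_patience`` consecutive
epochs in which training loss keeps falling but the validation metric does
not improve (the overfitting signature).

Perspective augmentation is applied to source images only: captured images
are inherently augmented by the capture process itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .capture import random_perspective
from .metrics import roc_auc
from .model import DannModel, LambdaSchedule, NetworkConfig, adaptive_lambda
from .render import RenderedImage

__all__ = [
    "TrainConfig",
    "desk_train_config",
    "ImageSet",
    "EpochRecord",
    "TrainHistory",
    "oversample",
    "should_checkpoint",
    "train_vanilla",
    "train_adversarial",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults are the full-scale reference values)."""

    lr: float = 4e-5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 50
    max_epochs: int = 60
    early_stop_patience: int = 5
    domain_start_epoch: int = 5
    aug_distortion: float = 0.15
    aug_prob: float = 0.8
    augment: bool = True
    oversample_target: Optional[float] = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if not self.domain_start_epoch < self.max_epochs:
            raise ValueError("domain_start_epoch must be < max_epochs")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")


def desk_train_config(**kw) -> TrainConfig:
    """Study conditions for single-CPU desk runs.

    Short runs need proportionally larger steps: the desk benchmark trains
    for ~300 optimizer steps versus ~80k in a full-scale run,
    so the learning rate is raised and the schedule compressed (warm-up 3
    epochs, the shorter reference variant).
    """
    defaults = dict(lr=3e-4, batch_size=16, max_epochs=10, domain_start_epoch=3)
    defaults.update(kw)
    return TrainConfig(**defaults)


@dataclass
class ImageSet:
    """A stack of same-shape page images with optional binary labels."""

    X: np.ndarray  # (N, H, W, 3) float32 in [0, 1]
    y: Optional[np.ndarray] = None  # (N,) float32 labels, or None (unlabeled)
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.X.ndim != 4 or self.X.shape[3] != 3:
            raise ValueError("X must be (N, H, W, 3)")
        if self.y is not None and len(self.y) != len(self.X):
            raise ValueError("labels do not match images")

    def __len__(self) -> int:
        return len(self.X)

    @classmethod
    def from_images(cls, images: list[RenderedImage],
                    condition: Optional[str] = None) -> "ImageSet":
        """Stack rendered images; ``condition`` selects the label column
        (None leaves the set unlabeled, hiding labels from training)."""
        X = np.stack([im.pixels for im in images]).astype(np.float32)
        y = None
        if condition is not None:
            y = np.array([float(im.labels[condition]) for im in images],
                         dtype=np.float32)
        return cls(X, y, tuple(im.source_record_id for im in images))


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_auc: float
    domain_acc: float  # NaN for vanilla training
    lam_end: float  # NaN before the domain head activates


@dataclass
class TrainHistory:
    epochs: list[EpochRecord] = field(default_factory=list)
    checkpoint_epochs: list[int] = field(default_factory=list)
    lambda_trace: list[tuple[int, int, float]] = field(default_factory=list)
    domain_updates_per_epoch: list[int] = field(default_factory=list)
    no_checkpoint_warning: bool = False


def oversample(labels, target_positive_frac: float,
               rng: np.random.Generator | int = 0) -> np.ndarray:
    """Index array balancing a binary dataset by minority replication.

    All original examples are retained; the minority class is resampled with
    replacement until the positive fraction is within 1/n of the target.
    """
    if not 0 < target_positive_frac < 1:
        raise ValueError("target_positive_frac must be strictly inside (0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    y = np.asarray(labels, dtype=bool)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("oversampling requires both classes present")
    t = target_positive_frac
    idx = np.arange(len(y))
    if len(pos_idx) / len(y) < t:
        needed = round(t / (1 - t) * len(neg_idx)) - len(pos_idx)
        if needed > 0:
            idx = np.concatenate([idx, rng.choice(pos_idx, needed, replace=True)])
    else:
        needed = round((1 - t) / t * len(pos_idx)) - len(neg_idx)
        if needed > 0:
            idx = np.concatenate([idx, rng.choice(neg_idx, needed, replace=True)])
    return idx


def should_checkpoint(record: EpochRecord, best_so_far: float) -> bool:
    """The dual rule: label metric strictly beats the best so far AND the
    domain classifier is near chance (40-60% accuracy)."""
    return (record.val_auc > best_so_far
            and 0.40 <= record.domain_acc <= 0.60)


def _augment_batch(X: np.ndarray, cfg: TrainConfig,
                   rng: np.random.Generator) -> np.ndarray:
    if not cfg.augment:
        return X
    return np.stack([
        random_perspective(x, cfg.aug_distortion, cfg.aug_prob, rng) for x in X
    ])


def _label_step(model: DannModel, opt: nn.Adam, Xb: np.ndarray,
                yb: np.ndarray) -> float:
    feats = model.feature_extractor_forward(Xb, training=True)
    logits = model.label_head.forward(feats, training=True)
    loss, dlogits = nn.bce_with_logits(logits.ravel(), yb)
    dfeat = model.label_head.backward(dlogits.reshape(logits.shape))
    model.feature.backward(dfeat)
    opt.step(model.feature.grads + model.label_head.grads)
    if not np.isfinite(loss):
        raise FloatingPointError("label loss diverged to a non-finite value")
    return loss


def _domain_step(model: DannModel, opt: nn.Adam, Xb: np.ndarray,
                 db: np.ndarray, lam: float) -> float:
    feats = model.feature_extractor_forward(Xb, training=True)
    x = model.grl.forward(feats)
    logits = model.domain_head.forward(x, training=True)
    loss, dlogits = nn.bce_with_logits(logits.ravel(), db)
    dx = model.domain_head.backward(dlogits.reshape(logits.shape))
    model.grl.lam = lam
    model.feature.backward(model.grl.backward(dx))
    opt.step(model.feature.grads + model.domain_head.grads)
    if not np.isfinite(loss):
        raise FloatingPointError("domain loss diverged to a non-finite value")
    return loss


def _val_auc(model: DannModel, val: ImageSet, batch_size: int) -> float:
    scores = model.predict_proba(val.X, batch_size)
    return roc_auc(scores, val.y.astype(bool))


def _domain_acc(model: DannModel, mixed: ImageSet, batch_size: int) -> float:
    scores = model.predict_domain_proba(mixed.X, batch_size)
    return float(np.mean((scores > 0.5) == mixed.y.astype(bool)))


def _check_labeled(ds: ImageSet, name: str) -> None:
    if ds.y is None or len(ds) == 0:
        raise ValueError(f"{name} must be non-empty and labeled")
    if ds.y.all() or not ds.y.any():
        raise ValueError(f"{name} must contain both classes")


def train_vanilla(source_train: ImageSet, source_val: ImageSet,
                  net_config: NetworkConfig, cfg: TrainConfig
                  ) -> tuple[DannModel, TrainHistory]:
    """Supervised training of the feature extractor + label head.

    Returns the model restored to its best-validation epoch.
    """
    _check_labeled(source_train, "source_train")
    _check_labeled(source_val, "source_val")
    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, aug_rng, os_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    idx = np.arange(len(source_train))
    if cfg.oversample_target is not None:
        idx = oversample(source_train.y, cfg.oversample_target, os_rng)

    model = DannModel(net_config)
    opt = nn.Adam(model.feature.params + model.label_head.params, cfg.lr,
                  cfg.adam_beta1, cfg.adam_beta2)
    history = TrainHistory()
    n_batches = max(len(idx) // cfg.batch_size, 1)

    best_auc = -np.inf
    best_state = model.state_dict()
    prev_train_loss = np.inf
    stagnant = 0
    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(idx)
        losses = []
        for b in range(n_batches):
            sel = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            Xb = _augment_batch(source_train.X[sel], cfg, aug_rng)
            losses.append(_label_step(model, opt, Xb, source_train.y[sel]))
        train_loss = float(np.mean(losses))
        val_auc = _val_auc(model, source_val, cfg.batch_size)
        history.epochs.append(EpochRecord(epoch, train_loss, val_auc,
                                          np.nan, np.nan))
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
            history.checkpoint_epochs.append(epoch)
            stagnant = 0
        elif train_loss < prev_train_loss:
            stagnant += 1
        prev_train_loss = train_loss
        if stagnant >= cfg.early_stop_patience:
            break

    model.load_state(best_state)
    return model, history


def train_adversarial(source_train: ImageSet, target_train: ImageSet,
                      source_val: ImageSet, mixed_val: ImageSet,
                      net_config: NetworkConfig, cfg: TrainConfig,
                      model: Optional[DannModel] = None,
                      history: Optional[TrainHistory] = None,
                      start_epoch: int = 0,
                      ) -> tuple[DannModel, TrainHistory]:
    """Alternating domain-adversarial training.

    ``source_train`` is labeled clean-page data; ``target_train`` is
    unlabeled captured data; ``mixed_val`` holds domain labels (0 = clean,
    1 = captured) for the checkpoint rule. Passing an existing ``model`` /
    ``history`` / ``start_epoch`` resumes a run (e.g. after extending the
    target pool with unseen-format pages).

    Returns the model restored to the last accepted checkpoint; if no
    checkpoint was ever accepted, the best-label-metric state is returned
    and flagged in the history.
    """
    _check_labeled(source_train, "source_train")
    _check_labeled(source_val, "source_val")
    if len(target_train) == 0:
        raise ValueError("target_train must be non-empty")
    if mixed_val.y is None:
        raise ValueError("mixed_val needs domain labels")

    ss = np.random.SeedSequence(cfg.seed)
    shuffle_rng, aug_rng, mix_rng, os_rng = (
        np.random.default_rng(s) for s in ss.spawn(4))

    idx = np.arange(len(source_train))
    if cfg.oversample_target is not None:
        idx = oversample(source_train.y, cfg.oversample_target, os_rng)

    if model is None:
        model = DannModel(net_config)
    opt_label = nn.Adam(model.feature.params + model.label_head.params,
                        cfg.lr, cfg.adam_beta1, cfg.adam_beta2)
    opt_domain = nn.Adam(model.feature.params + model.domain_head.params,
                         cfg.lr, cfg.adam_beta1, cfg.adam_beta2)
    history = history if history is not None else TrainHistory()
    n_batches = max(len(idx) // cfg.batch_size, 1)
    schedule = LambdaSchedule(n_batches, cfg.max_epochs)

    best_auc = -np.inf
    best_state = model.state_dict()
    ckpt_state = None
    prev_train_loss = np.inf
    stagnant = 0
    for epoch in range(start_epoch, cfg.max_epochs):
        order = shuffle_rng.permutation(idx)
        losses = []
        lam = np.nan
        domain_updates = 0
        for b in range(n_batches):
            sel = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            Xb = _augment_batch(source_train.X[sel], cfg, aug_rng)
            losses.append(_label_step(model, opt_label, Xb, source_train.y[sel]))

            if epoch >= cfg.domain_start_epoch:
                # 50/50 random mix of source/target with domain labels
                from_target = mix_rng.random(cfg.batch_size) < 0.5
                src_pick = mix_rng.integers(len(source_train), size=cfg.batch_size)
                tgt_pick = mix_rng.integers(len(target_train), size=cfg.batch_size)
                Xm = np.empty((cfg.batch_size, *source_train.X.shape[1:]),
                              dtype=np.float32)
                n_src = int((~from_target).sum())
                if n_src:
                    Xm[~from_target] = _augment_batch(
                        source_train.X[src_pick[~from_target]], cfg, aug_rng)
                if cfg.batch_size - n_src:
                    Xm[from_target] = target_train.X[tgt_pick[from_target]]
                dm = from_target.astype(np.float32)
                lam = adaptive_lambda(b, epoch, schedule)
                history.lambda_trace.append((epoch, b, lam))
                _domain_step(model, opt_domain, Xm, dm, lam)
                domain_updates += 1

        train_loss = float(np.mean(losses))
        val_auc = _val_auc(model, source_val, cfg.batch_size)
        domain_acc = _domain_acc(model, mixed_val, cfg.batch_size)
        record = EpochRecord(epoch, train_loss, val_auc, domain_acc, lam)
        history.epochs.append(record)
        history.domain_updates_per_epoch.append(domain_updates)

        if should_checkpoint(record, best_auc):
            ckpt_state = model.state_dict()
            history.checkpoint_epochs.append(epoch)
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
            stagnant = 0
        elif train_loss < prev_train_loss:
            stagnant += 1
        prev_train_loss = train_loss
        if stagnant >= cfg.early_stop_patience:
            break

    if ckpt_state is not None:
        model.load_state(ckpt_state)
    else:
        model.load_state(best_state)
        history.no_checkpoint_warning = True
    return model, history
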