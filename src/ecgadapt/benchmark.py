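"""End-to-end synthetic benchmark: vanilla vs adversarial under domain shift.

Reproduces the experimental design at desk scale: labeled clean printed
pages are the source domain, unlabeled capture-artifact pages the target
domain, and page-layout variants the "unseen formats". Each (condition,
seed) cell generates signals, renders pages, simulates captures, trains both
classifiers at matched architecture/seeds, and evaluates ROC-AUC on clean,
captured, and unseen-format captured test sets. The headline quantity is the
adaptation gap  delta = AUC_adversarial - AUC_vanilla  on the captured test
set.

Splitting is by source record (the patient-level analog): every page or
frame derived from one ECG record stays on one side of every split, which
``run_benchmark`` asserts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .capture import CaptureConfig, capture_dataset
from .metrics import confusion, metrics, roc_auc, select_threshold
from .model import DannModel, NetworkConfig
from .render import FormatSpec, RenderedImage, make_format_variants, render
from .signals import generate_dataset
from .training import (ImageSet, TrainConfig, TrainHistory, desk_train_config,
                       train_adversarial, train_vanilla)

__all__ = [
    "BenchmarkConfig",
    "BenchmarkData",
    "BenchmarkResult",
    "make_benchmark_data",
    "run_benchmark",
    "report_writer",
    "adaptation_gaps",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    conditions: tuple[str, ...] = (
        "sinus_bradycardia", "sinus_tachycardia", "atrial_fibrillation")
    n_train: int = 400  # clean training pages (captured frames derive from these)
    n_val: int = 100
    n_test: int = 200
    image_hw: tuple[int, int] = (220, 412)
    base_format: FormatSpec = field(default_factory=FormatSpec)
    n_unseen_formats: int = 3
    capture: CaptureConfig = field(default_factory=CaptureConfig)
    train: TrainConfig = field(default_factory=desk_train_config)
    net: NetworkConfig = field(default_factory=NetworkConfig.desk)
    seeds: tuple[int, ...] = (0, 1, 2)
    frames_per_image: int = 1
    signal_fs: float = 250.0
    run_unseen: bool = True
    resume_epochs: int = 0  # >0: resume adversarial run with unseen-format pages

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("at least one seed required")
        if self.image_hw != (self.net.input_h, self.net.input_w):
            raise ValueError("image size must match the network input size")


@dataclass
class BenchmarkData:
    """All image sets for one (condition, seed) benchmark cell."""

    condition: str
    seed: int
    source_train: ImageSet  # labeled clean
    target_train: ImageSet  # unlabeled captured
    source_val: ImageSet  # labeled clean
    mixed_val: ImageSet  # domain labels: 0 clean / 1 captured
    test_clean: ImageSet
    test_captured: ImageSet
    test_unseen: ImageSet | None  # captured pages in unseen formats
    unseen_pool: ImageSet | None  # unlabeled unseen-format pages for resuming


def _render_all(records, spec_for, hw) -> list[RenderedImage]:
    return [render(r, spec_for(i), hw[0], hw[1]) for i, r in enumerate(records)]


def make_benchmark_data(condition: str, seed: int,
                        config: BenchmarkConfig) -> BenchmarkData:
    """Generate signals, render pages and simulate captures for one cell."""
    n_total = config.n_train + config.n_val + config.n_test
    records = generate_dataset(
        n_total, {condition: 0.5, "normal": 0.5},
        fs=config.signal_fs, seed=seed)
    tr = records[: config.n_train]
    va = records[config.n_train : config.n_train + config.n_val]
    te = records[config.n_train + config.n_val :]

    ids = [set(r.record_id for r in part) for part in (tr, va, te)]
    assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2]), \
        "record-level split contamination"

    hw = config.image_hw
    base = config.base_format
    ss = np.random.SeedSequence((seed, 0xC0FFEE))
    cap_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(4)]

    clean_tr = _render_all(tr, lambda i: base, hw)
    clean_va = _render_all(va, lambda i: base, hw)
    clean_te = _render_all(te, lambda i: base, hw)

    cap_tr = capture_dataset(clean_tr, config.capture,
                             config.frames_per_image, cap_seeds[0])
    cap_va = capture_dataset(clean_va, config.capture, 1, cap_seeds[1])
    cap_te = capture_dataset(clean_te, config.capture, 1, cap_seeds[2])

    mixed_imgs = clean_va + cap_va
    mixed = ImageSet(
        np.stack([im.pixels for im in mixed_imgs]).astype(np.float32),
        np.array([0.0] * len(clean_va) + [1.0] * len(cap_va), dtype=np.float32),
        tuple(im.source_record_id for im in mixed_imgs))

    test_unseen = unseen_pool = None
    if config.run_unseen and config.n_unseen_formats > 0:
        variants = make_format_variants(base, config.n_unseen_formats,
                                        np.random.default_rng(seed + 1))
        unseen_clean_te = _render_all(
            te, lambda i: variants[i % len(variants)], hw)
        unseen_cap_te = capture_dataset(unseen_clean_te, config.capture, 1,
                                        cap_seeds[3])
        test_unseen = ImageSet.from_images(unseen_cap_te, condition)
        if config.resume_epochs > 0:
            # unlabeled unseen-format pool drawn from *training* records only
            pool_clean = _render_all(
                tr[: min(len(tr), 50)], lambda i: variants[i % len(variants)], hw)
            pool_cap = capture_dataset(pool_clean, config.capture, 1,
                                       cap_seeds[3] + 1)
            unseen_pool = ImageSet.from_images(pool_cap, None)

    return BenchmarkData(
        condition=condition, seed=seed,
        source_train=ImageSet.from_images(clean_tr, condition),
        target_train=ImageSet.from_images(cap_tr, None),
        source_val=ImageSet.from_images(clean_va, condition),
        mixed_val=mixed,
        test_clean=ImageSet.from_images(clean_te, condition),
        test_captured=ImageSet.from_images(cap_te, condition),
        test_unseen=test_unseen,
        unseen_pool=unseen_pool,
    )


@dataclass
class BenchmarkResult:
    rows: list[dict]
    histories: dict[tuple, TrainHistory] = field(default_factory=dict)
    final_domain_acc: dict[tuple, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _eval_rows(model: DannModel, data: BenchmarkData, arm: str,
               batch_size: int) -> list[dict]:
    val_scores = model.predict_proba(data.source_val.X, batch_size)
    thr = select_threshold(val_scores, data.source_val.y.astype(bool))
    arms = [("clean", "seen", data.test_clean),
            ("captured", "seen", data.test_captured)]
    if data.test_unseen is not None:
        arms.append(("captured", "unseen", data.test_unseen))
    rows = []
    for domain, fmt, ds in arms:
        scores = model.predict_proba(ds.X, batch_size)
        y = ds.y.astype(bool)
        rep = metrics(confusion(y, scores >= thr))
        rows.append(dict(
            condition=data.condition, arm=arm, domain=domain, format=fmt,
            seed=data.seed, auc=roc_auc(scores, y), acc=rep.acc, f1=rep.f1,
        ))
    return rows


def run_benchmark(config: BenchmarkConfig, verbose: bool = False
                  ) -> BenchmarkResult:
    """Run all (condition, seed) cells; both training arms per cell."""
    result = BenchmarkResult(rows=[])
    for condition in config.conditions:
        for seed in config.seeds:
            data = make_benchmark_data(condition, seed, config)
            net = replace(config.net, seed=seed)
            cfg = replace(config.train, seed=seed)

            if verbose:
                print(f"[benchmark] {condition} seed={seed}: vanilla")
            van, van_hist = train_vanilla(
                data.source_train, data.source_val, net, cfg)
            result.rows += _eval_rows(van, data, "vanilla", cfg.batch_size)
            result.histories[(condition, seed, "vanilla")] = van_hist

            if verbose:
                print(f"[benchmark] {condition} seed={seed}: adversarial")
            adv, adv_hist = train_adversarial(
                data.source_train, data.target_train, data.source_val,
                data.mixed_val, net, cfg)
            result.rows += _eval_rows(adv, data, "adversarial", cfg.batch_size)
            result.histories[(condition, seed, "adversarial")] = adv_hist
            from .training import _domain_acc  # final-checkpoint domain accuracy
            result.final_domain_acc[(condition, seed)] = _domain_acc(
                adv, data.mixed_val, cfg.batch_size)

            if config.resume_epochs > 0 and data.unseen_pool is not None:
                before = [r for r in result.rows
                          if r["arm"] == "adversarial" and r["format"] == "unseen"
                          and r["condition"] == condition and r["seed"] == seed]
                extended = ImageSet(
                    np.concatenate([data.target_train.X, data.unseen_pool.X]),
                    None,
                    data.target_train.ids + data.unseen_pool.ids)
                resume_cfg = replace(
                    cfg, max_epochs=cfg.max_epochs + config.resume_epochs)
                adv, adv_hist = train_adversarial(
                    data.source_train, extended, data.source_val,
                    data.mixed_val, net, resume_cfg, model=adv,
                    history=adv_hist, start_epoch=cfg.max_epochs)
                result.rows += _eval_rows(adv, data, "adversarial_resumed",
                                          cfg.batch_size)
                result.histories[(condition, seed, "adversarial_resumed")] = adv_hist
    return result


def adaptation_gaps(rows: list[dict]) -> pd.DataFrame:
    """Per (condition, seed): delta = adversarial - vanilla captured-test AUC."""
    df = pd.DataFrame(rows)
    sub = df[(df.domain == "captured") & (df.format == "seen")
             & df.arm.isin(["vanilla", "adversarial"])]
    wide = sub.pivot_table(index=["condition", "seed"], columns="arm",
                           values="auc")
    for arm in ("vanilla", "adversarial"):
        if arm not in wide.columns:
            wide[arm] = np.nan
    wide["delta"] = wide["adversarial"] - wide["vanilla"]
    return wide.reset_index()


def report_writer(result: BenchmarkResult, outdir: str | Path) -> pd.DataFrame:
    """Serialize benchmark results as CSV + JSON + markdown summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = ["condition", "arm", "domain", "format", "seed", "auc", "acc", "f1"]
    df = pd.DataFrame(result.rows, columns=cols)
    df.to_csv(outdir / "results.csv", index=False)
    (outdir / "results.json").write_text(
        json.dumps(result.rows, indent=1, default=float))

    lines = ["# Benchmark summary", ""]
    gaps = adaptation_gaps(result.rows) if len(df) else pd.DataFrame()
    if len(gaps) and gaps["delta"].notna().any():
        med = gaps.groupby("condition")["delta"].median()
        lines.append("| condition | median captured-test AUC gap (adv - van) |")
        lines.append("|---|---|")
        for cond, d in med.items():
            lines.append(f"| {cond} | {d:+.3f} |")
        lines.append("")
        lines.append(f"Overall median gap: {gaps['delta'].median():+.3f}")
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    return df
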