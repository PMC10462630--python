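"""Synthetic labeled 12-lead ECG signal generator.

Each record is a sum of per-beat localized wave components (P, Q, R, S, T
modeled as Gaussian bumps on a beat-relative time axis) projected onto the 12
standard leads through a fixed amplitude matrix, plus baseline wander and
sensor noise. The model is deliberately parametric rather than physiological:
every label (rate class, rhythm irregularity, QT prolongation, QRS widening,
P-wave absence) maps to a generator parameter that an independent measurement
oracle can recover from the waveform.

Conditions provided (binary label per condition):

* ``normal`` — sinus rhythm 60-95 bpm
* ``sinus_bradycardia`` — sinus rhythm 40-55 bpm
* ``sinus_tachycardia`` — sinus rhythm 105-140 bpm
* ``atrial_fibrillation`` — irregular RR (CV 0.2-0.3), absent P waves
* ``prolonged_qt`` — QT interval scaled 1.3-1.5x
* ``wide_qrs`` — QRS width scaled 1.6-2.0x (bundle-branch-block-like)
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LEAD_NAMES",
    "ECGRecord",
    "ConditionSpec",
    "CONDITIONS",
    "generate_record",
    "generate_dataset",
    "write_record",
    "read_record",
    "write_manifest",
    "read_manifest",
]

LEAD_NAMES = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

# Wave order used by the amplitude projection matrix below.
_WAVES = ("P", "Q", "R", "S", "T")

# Per-lead multiplier for each wave component, loosely following textbook
# lead morphology (aVR inverted, V1 mostly negative QRS, tall R in V4-V6).
# Rows: leads in LEAD_NAMES order; columns: P, Q, R, S, T.
_LEAD_AMP = np.array(
    [
        # P      Q      R      S      T
        [0.7, -0.6, 0.60, -0.5, 0.6],   # I
        [1.0, -1.0, 1.00, -1.0, 1.0],   # II
        [0.5, -0.7, 0.55, -0.9, 0.5],   # III
        [-0.8, 0.6, -0.75, 0.7, -0.8],  # aVR
        [0.3, -0.4, 0.30, -0.3, 0.25],  # aVL
        [0.75, -0.8, 0.80, -0.9, 0.7],  # aVF
        [0.25, 0.2, 0.30, -1.6, -0.3],  # V1
        [0.35, 0.1, 0.55, -1.4, 0.45],  # V2
        [0.45, -0.2, 0.80, -1.0, 0.75], # V3
        [0.55, -0.5, 1.20, -0.6, 0.95], # V4
        [0.60, -0.8, 1.10, -0.4, 0.85], # V5
        [0.60, -0.9, 0.95, -0.3, 0.70], # V6
    ]
)

# Beat-template parameters on a beat-relative time axis (seconds, 0 = R peak):
# (center offset, width sigma, amplitude in mV) for the lead-II reference.
_BASE_WAVES = {
    "P": (-0.17, 0.025, 0.15),
    "Q": (-0.028, 0.009, 0.15),
    "R": (0.0, 0.013, 1.2),
    "S": (0.028, 0.009, 0.3),
    "T": (0.30, 0.055, 0.35),
}


@dataclass(frozen=True)
class ConditionSpec:
    """Generator parameters defining one cardiac-condition class."""

    name: str
    hr_range: tuple[float, float] = (60.0, 95.0)  # bpm
    rr_cv_range: tuple[float, float] = (0.02, 0.05)  # RR coefficient of variation
    qt_scale_range: tuple[float, float] = (1.0, 1.0)
    qrs_scale_range: tuple[float, float] = (1.0, 1.0)
    p_wave: bool = True
    amp_jitter: float = 0.1  # relative per-record amplitude jitter

    def __post_init__(self) -> None:
        for rng_name in ("hr_range", "rr_cv_range", "qt_scale_range", "qrs_scale_range"):
            lo, hi = getattr(self, rng_name)
            if not (lo <= hi):
                raise ValueError(f"{rng_name} must be a non-empty range")
        if self.hr_range[0] <= 0:
            raise ValueError("heart-rate bounds must be positive")


CONDITIONS: dict[str, ConditionSpec] = {
    "normal": ConditionSpec("normal"),
    "sinus_bradycardia": ConditionSpec("sinus_bradycardia", hr_range=(40.0, 55.0)),
    "sinus_tachycardia": ConditionSpec("sinus_tachycardia", hr_range=(105.0, 140.0)),
    "atrial_fibrillation": ConditionSpec(
        "atrial_fibrillation",
        hr_range=(70.0, 120.0),
        rr_cv_range=(0.2, 0.3),
        p_wave=False,
    ),
    "prolonged_qt": ConditionSpec("prolonged_qt", qt_scale_range=(1.3, 1.5)),
    "wide_qrs": ConditionSpec("wide_qrs", qrs_scale_range=(1.6, 2.0)),
}


@dataclass
class ECGRecord:
    """A 12-lead ECG signal record with binary condition labels."""

    record_id: str
    leads: dict[str, np.ndarray]  # lead name -> samples in mV
    fs: float  # Hz
    duration_s: float
    labels: dict[str, bool]
    seed: int

    def __post_init__(self) -> None:
        if set(self.leads) != set(LEAD_NAMES):
            raise ValueError("record must contain exactly the 12 standard leads")
        n = round(self.fs * self.duration_s)
        for name, sig in self.leads.items():
            if len(sig) != n:
                raise ValueError(f"lead {name} has {len(sig)} samples, expected {n}")
            if not np.all(np.isfinite(sig)):
                raise ValueError(f"lead {name} contains non-finite samples")
        if self.duration_s < 10:
            raise ValueError("duration_s must be >= 10 (page renderer uses 10 s)")

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.duration_s)

    def lead_array(self) -> np.ndarray:
        """Signals stacked in standard lead order, shape (12, n_samples)."""
        return np.stack([self.leads[name] for name in LEAD_NAMES])


def _beat_times(spec: ConditionSpec, duration_s: float, rng: np.random.Generator):
    """R-peak times covering [0, duration]; returns (times, mean RR)."""
    hr = rng.uniform(*spec.hr_range)
    cv = rng.uniform(*spec.rr_cv_range)
    rr_mean = 60.0 / hr
    times = [float(rng.uniform(0.0, rr_mean))]
    while times[-1] < duration_s + rr_mean:
        rr = rr_mean * (1.0 + cv * float(np.clip(rng.standard_normal(), -2.5, 2.5)))
        times.append(times[-1] + max(rr, 0.2))
    return np.array(times), rr_mean


def generate_record(
    spec: ConditionSpec,
    fs: float = 500.0,
    duration_s: float = 10.0,
    rng: np.random.Generator | int | None = None,
    record_id: str | None = None,
    condition_set: tuple[str, ...] | None = None,
    noise_std: float = 0.02,
) -> ECGRecord:
    """Generate one labeled 12-lead record from a condition specification.

    Deterministic given (spec, fs, duration_s, seed). ``condition_set``
    controls which label keys are present (default: all known conditions);
    the label is True exactly for ``spec.name``.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10 s")
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed = int(rng if rng is not None else 0)
        rng = np.random.default_rng(seed)
    else:
        seed = -1  # external generator; record seed unknown
    if condition_set is None:
        condition_set = tuple(CONDITIONS)

    n = round(fs * duration_s)
    t = np.arange(n) / fs
    beat_times, _ = _beat_times(spec, duration_s, rng)
    qt_scale = rng.uniform(*spec.qt_scale_range)
    qrs_scale = rng.uniform(*spec.qrs_scale_range)
    amp_gain = 1.0 + spec.amp_jitter * float(np.clip(rng.standard_normal(), -2, 2))

    sig = np.zeros((12, n))
    for tr in beat_times:
        for wi, wave in enumerate(_WAVES):
            center, sigma, amp = _BASE_WAVES[wave]
            if wave == "P":
                if not spec.p_wave:
                    continue
            elif wave == "T":
                center, sigma = center * qt_scale, sigma * qt_scale
            elif wave in ("Q", "R", "S"):
                center, sigma = center * qrs_scale, sigma * qrs_scale
            c = tr + center
            if c < -0.5 or c > duration_s + 0.5:
                continue
            bump = amp * amp_gain * np.exp(-0.5 * ((t - c) / sigma) ** 2)
            sig += _LEAD_AMP[:, wi : wi + 1] * bump[None, :]

    # baseline wander: one slow sinusoid per lead, plus white sensor noise
    wander_f = rng.uniform(0.15, 0.4)
    wander_phase = rng.uniform(0, 2 * np.pi, size=12)
    sig += 0.04 * np.sin(2 * np.pi * wander_f * t[None, :] + wander_phase[:, None])
    sig += rng.normal(0.0, noise_std, size=sig.shape)

    rid = record_id or f"{spec.name}-{seed}"
    labels = {c: (c == spec.name) for c in condition_set}
    leads = {name: sig[i] for i, name in enumerate(LEAD_NAMES)}
    return ECGRecord(rid, leads, float(fs), float(duration_s), labels, seed)


def generate_dataset(
    n: int,
    condition_mix: dict[str, float],
    fs: float = 500.0,
    duration_s: float = 10.0,
    seed: int = 0,
) -> list[ECGRecord]:
    """Generate ``n`` records with class fractions following ``condition_mix``.

    Counts are allocated by largest remainder (so empirical fractions are
    within 1/n of the request) and the record order is shuffled. Record seeds
    are derived deterministically from the master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not condition_mix:
        raise ValueError("condition_mix must be non-empty")
    fracs = np.array(list(condition_mix.values()), dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("condition fractions must sum to 1")
    names = list(condition_mix)
    for name in names:
        if name not in CONDITIONS:
            raise ValueError(f"unknown condition {name!r}")

    # largest-remainder allocation of n among classes
    raw = fracs * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1

    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    assignment = np.repeat(np.arange(len(names)), counts)
    order_rng.shuffle(assignment)

    condition_set = tuple(CONDITIONS)
    records = []
    for i, ci in enumerate(assignment):
        child_seed = int(ss.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
        # spawn() above advances ss's child counter, so seeds are distinct
        records.append(
            generate_record(
                CONDITIONS[names[ci]],
                fs=fs,
                duration_s=duration_s,
                rng=child_seed,
                record_id=f"rec{i:05d}-{names[ci]}",
                condition_set=condition_set,
            )
        )
    return records


# ---------------------------------------------------------------------------
# plain-text IO: one CSV per record + JSON sidecar, and a dataset manifest
# ---------------------------------------------------------------------------

def write_record(record: ECGRecord, directory: str | Path) -> Path:
    """Write a record as ``<id>.csv`` (time + 12 leads) with JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{record.record_id}.csv"
    t = np.arange(record.n_samples) / record.fs
    arr = np.column_stack([t] + [record.leads[name] for name in LEAD_NAMES])
    header = ",".join(["time_s", *LEAD_NAMES])
    np.savetxt(csv_path, arr, delimiter=",", header=header, comments="", fmt="%.6f")
    sidecar = {
        "record_id": record.record_id,
        "fs": record.fs,
        "duration_s": record.duration_s,
        "labels": record.labels,
        "seed": record.seed,
    }
    (directory / f"{record.record_id}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_record(csv_path: str | Path) -> ECGRecord:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    arr = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    leads = {name: arr[:, i + 1] for i, name in enumerate(LEAD_NAMES)}
    return ECGRecord(
        meta["record_id"], leads, meta["fs"], meta["duration_s"],
        {k: bool(v) for k, v in meta["labels"].items()}, meta["seed"],
    )


def write_manifest(records: list[ECGRecord], directory: str | Path,
                   path: str | Path | None = None) -> Path:
    """Write all records plus a manifest CSV (record_id, path, label columns)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = Path(path) if path else directory / "manifest.csv"
    conditions = sorted({c for r in records for c in r.labels})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "path", *conditions])
        for rec in records:
            rec_path = write_record(rec, directory)
            writer.writerow(
                [rec.record_id, rec_path.name,
                 *[int(rec.labels.get(c, False)) for c in conditions]]
            )
    return path


def read_manifest(path: str | Path) -> list[ECGRecord]:
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(read_record(path.parent / row["path"]))
    return records
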