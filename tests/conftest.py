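"""Shared fixtures and independent measurement oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import find_peaks

from ecgadapt.signals import LEAD_NAMES, ECGRecord


# ---------------------------------------------------------------------------
# independent waveform-measurement oracle (R peaks + interval statistics)
# ---------------------------------------------------------------------------

def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Simple threshold R-peak detector on lead II (test oracle only)."""
    height = 0.5 * np.percentile(signal, 99.9)
    peaks, _ = find_peaks(signal, height=height, distance=int(0.25 * fs))
    return peaks


def measure_heart_rate(record: ECGRecord) -> float:
    """Mean heart rate (bpm) measured from lead II R peaks."""
    peaks = detect_r_peaks(record.leads["II"], record.fs)
    rr = np.diff(peaks) / record.fs
    return 60.0 / rr.mean()


def measure_rr_cv(record: ECGRecord) -> float:
    peaks = detect_r_peaks(record.leads["II"], record.fs)
    rr = np.diff(peaks) / record.fs
    return float(rr.std() / rr.mean())


def measure_p_amplitude(record: ECGRecord) -> float:
    """Median peak amplitude in the pre-QRS window where a P wave would sit."""
    sig = record.leads["II"]
    fs = record.fs
    peaks = detect_r_peaks(sig, fs)
    amps = []
    for p in peaks:
        lo, hi = int(p - 0.24 * fs), int(p - 0.09 * fs)
        if lo < 0:
            continue
        seg = sig[lo:hi]
        amps.append(seg.max() - np.median(sig))
    return float(np.median(amps))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_flat_record(fs: float = 250.0, duration_s: float = 10.0,
                     labels: dict | None = None) -> ECGRecord:
    """All-zero record (flat baselines in every lead)."""
    n = round(fs * duration_s)
    leads = {name: np.zeros(n) for name in LEAD_NAMES}
    return ECGRecord("flat", leads, fs, duration_s,
                     labels or {"normal": True}, seed=0)


@pytest.fixture(scope="session")
def flat_record() -> ECGRecord:
    return make_flat_record()


@pytest.fixture(scope="session")
def small_clean_image():
    """A small rendered page reused by capture tests."""
    from ecgadapt.render import FormatSpec, render
    from ecgadapt.signals import CONDITIONS, generate_record

    rec = generate_record(CONDITIONS["normal"], fs=250, duration_s=10, rng=11)
    return render(rec, FormatSpec(), 88, 164)
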