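"""Render 12-lead ECG records to printed-page images.

The page follows clinical plotting conventions: a calibrated grid background
(1 mm minor / 5 mm major boxes), paper speed 25 mm/s, gain 10 mm/mV, a grid
of short-lead panels showing 2.5 s each (consecutive panels in a row show
consecutive time windows), an optional full-10-s rhythm strip along the
bottom, and an optional 1 mV calibration pulse at the start of each row.

Rendering happens on a full-resolution canvas at ``px_per_mm`` density and is
then bilinearly resampled to the requested output size. ``render_canvas``
exposes the pre-resample canvas together with its geometry so pixel-exact
properties (calibration-pulse height, time-to-pixel mapping) can be verified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

from .signals import LEAD_NAMES, ECGRecord

__all__ = [
    "FormatSpec",
    "RenderedImage",
    "PanelBox",
    "CanvasGeometry",
    "render",
    "render_canvas",
    "make_format_variants",
    "write_image",
    "read_image",
    "write_image_manifest",
]

_DEFAULT_LEAD_ORDER = (
    "I", "aVR", "V1", "V4",
    "II", "aVL", "V2", "V5",
    "III", "aVF", "V3", "V6",
)


@dataclass(frozen=True)
class FormatSpec:
    """A printed-page layout description (one per vendor-like format)."""

    format_id: str = "standard-3x4"
    panel_grid: tuple[int, int] = (3, 4)  # rows x cols of short-lead panels
    lead_order: tuple[str, ...] = _DEFAULT_LEAD_ORDER
    rhythm_lead: str | None = "II"
    seconds_per_panel: float = 2.5
    rhythm_seconds: float = 10.0
    mm_per_s: float = 25.0
    mm_per_mV: float = 10.0
    px_per_mm: int = 4
    grid_minor: tuple[float, float, float] = (1.0, 0.87, 0.87)
    grid_major: tuple[float, float, float] = (1.0, 0.62, 0.62)
    trace_color: tuple[float, float, float] = (0.0, 0.0, 0.0)
    calibration_pulse: bool = True
    margins_mm: float = 4.0
    row_height_mm: float = 35.0
    cal_width_mm: float = 5.0

    def __post_init__(self) -> None:
        rows, cols = self.panel_grid
        if rows * cols != 12:
            raise ValueError("panel_grid rows*cols must equal 12")
        if sorted(self.lead_order) != sorted(LEAD_NAMES):
            raise ValueError("lead_order must be a permutation of the 12 leads")
        if self.rhythm_lead is not None:
            if self.rhythm_lead not in LEAD_NAMES:
                raise ValueError(f"unknown rhythm lead {self.rhythm_lead!r}")
            if self.seconds_per_panel * cols > self.rhythm_seconds + 1e-9:
                raise ValueError("panel rows must not span more time than the rhythm strip")

    @property
    def canvas_shape(self) -> tuple[int, int]:
        """Pre-resample canvas (height, width) in pixels."""
        rows, cols = self.panel_grid
        n_bands = rows + (1 if self.rhythm_lead else 0)
        cal = self.cal_width_mm if self.calibration_pulse else 0.0
        w_mm = 2 * self.margins_mm + cal + cols * self.seconds_per_panel * self.mm_per_s
        h_mm = 2 * self.margins_mm + n_bands * self.row_height_mm
        return (round(h_mm * self.px_per_mm), round(w_mm * self.px_per_mm))


@dataclass
class RenderedImage:
    """An H x W x 3 page image with domain tag and inherited labels."""

    pixels: np.ndarray  # float in [0, 1]
    domain: str  # "clean" | "captured"
    format_id: str
    labels: dict[str, bool]
    source_record_id: str

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("empty image")
        if self.domain not in ("clean", "captured"):
            raise ValueError(f"unknown domain {self.domain!r}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"pixel values outside [0,1]: [{lo}, {hi}]")


@dataclass(frozen=True)
class PanelBox:
    """Pixel box of one trace panel on the pre-resample canvas."""

    lead: str
    x0: int  # first signal column (after any calibration pulse)
    y_center: int
    width: int
    half_height: int
    t0: float  # start of the time window shown (s)
    t1: float


@dataclass
class CanvasGeometry:
    panels: list[PanelBox]
    rhythm: PanelBox | None
    px_per_mm: int


def _draw_grid(canvas: np.ndarray, spec: FormatSpec) -> None:
    h, w = canvas.shape[:2]
    m = round(spec.margins_mm * spec.px_per_mm)
    step = spec.px_per_mm
    minor = np.array(spec.grid_minor)
    major = np.array(spec.grid_major)
    for x in range(m, w - m, step):
        canvas[m : h - m, x] = minor
    for y in range(m, h - m, step):
        canvas[y, m : w - m] = minor
    for x in range(m, w - m, 5 * step):
        canvas[m : h - m, x] = major
    for y in range(m, h - m, 5 * step):
        canvas[y, m : w - m] = major


def _draw_polyline(canvas: np.ndarray, ys: np.ndarray, x0: int,
                   color: tuple[float, float, float]) -> None:
    """Paint a trace given per-column integer y positions, connecting
    consecutive columns with vertical fills (1 px nominal thickness)."""
    col = np.array(color)
    prev = ys[0]
    for i, y in enumerate(ys):
        lo, hi = (y, prev) if y <= prev else (prev, y)
        canvas[lo : hi + 1, x0 + i] = col
        prev = y


def _draw_trace(canvas: np.ndarray, box: PanelBox, samples: np.ndarray,
                fs: float, spec: FormatSpec) -> None:
    px_s = spec.mm_per_s * spec.px_per_mm  # px per second
    px_mv = spec.mm_per_mV * spec.px_per_mm  # px per mV
    xs = np.arange(box.width)
    t = box.t0 + xs / px_s
    v = np.interp(t, np.arange(len(samples)) / fs, samples)
    y = np.rint(box.y_center - v * px_mv).astype(int)
    np.clip(y, box.y_center - box.half_height, box.y_center + box.half_height, out=y)
    _draw_polyline(canvas, y, box.x0, spec.trace_color)


def _draw_cal_pulse(canvas: np.ndarray, x0: int, y_center: int,
                    spec: FormatSpec) -> None:
    """1 mV square pulse: 1 mm baseline, 3 mm plateau at 1 mV, 1 mm baseline."""
    ppm = spec.px_per_mm
    top = y_center - round(spec.mm_per_mV * ppm)
    col = np.array(spec.trace_color)
    w1, w4 = ppm, 4 * ppm
    canvas[y_center, x0 : x0 + w1 + 1] = col
    canvas[top : y_center + 1, x0 + w1] = col
    canvas[top, x0 + w1 : x0 + w4 + 1] = col
    canvas[top : y_center + 1, x0 + w4] = col
    canvas[y_center, x0 + w4 : x0 + 5 * ppm] = col


def render_canvas(record: ECGRecord, spec: FormatSpec) -> tuple[np.ndarray, CanvasGeometry]:
    """Draw the full-resolution page canvas; returns (canvas, geometry)."""
    rows, cols = spec.panel_grid
    if record.duration_s + 1e-9 < spec.rhythm_seconds:
        raise ValueError("record shorter than the rhythm-strip window")
    if record.duration_s + 1e-9 < spec.seconds_per_panel * cols:
        raise ValueError("record shorter than one panel row")

    h, w = spec.canvas_shape
    canvas = np.ones((h, w, 3), dtype=np.float64)
    _draw_grid(canvas, spec)

    ppm = spec.px_per_mm
    m = round(spec.margins_mm * ppm)
    cal_px = round(spec.cal_width_mm * ppm) if spec.calibration_pulse else 0
    band_px = round(spec.row_height_mm * ppm)
    half = band_px // 2 - 1
    panel_w = round(spec.seconds_per_panel * spec.mm_per_s * ppm)

    panels: list[PanelBox] = []
    for r in range(rows):
        y_center = m + r * band_px + band_px // 2
        if spec.calibration_pulse:
            _draw_cal_pulse(canvas, m, y_center, spec)
        for c in range(cols):
            lead = spec.lead_order[r * cols + c]
            t0 = c * spec.seconds_per_panel
            box = PanelBox(
                lead=lead, x0=m + cal_px + c * panel_w, y_center=y_center,
                width=panel_w, half_height=half,
                t0=t0, t1=t0 + spec.seconds_per_panel,
            )
            _draw_trace(canvas, box, record.leads[lead], record.fs, spec)
            panels.append(box)

    rhythm_box = None
    if spec.rhythm_lead:
        y_center = m + rows * band_px + band_px // 2
        if spec.calibration_pulse:
            _draw_cal_pulse(canvas, m, y_center, spec)
        rhythm_w = round(spec.rhythm_seconds * spec.mm_per_s * ppm)
        rhythm_box = PanelBox(
            lead=spec.rhythm_lead, x0=m + cal_px, y_center=y_center,
            width=rhythm_w, half_height=half, t0=0.0, t1=spec.rhythm_seconds,
        )
        _draw_trace(canvas, rhythm_box, record.leads[spec.rhythm_lead],
                    record.fs, spec)

    return canvas, CanvasGeometry(panels, rhythm_box, ppm)


def render(record: ECGRecord, spec: FormatSpec,
           out_h: int = 220, out_w: int = 412) -> RenderedImage:
    """Render a record to a clean page image of shape (out_h, out_w, 3)."""
    if out_h <= 0 or out_w <= 0:
        raise ValueError("output dimensions must be positive")
    canvas, _ = render_canvas(record, spec)
    pixels = resize(canvas, (out_h, out_w), order=1, anti_aliasing=True,
                    preserve_range=True).astype(np.float32)
    np.clip(pixels, 0.0, 1.0, out=pixels)
    return RenderedImage(
        pixels=pixels, domain="clean", format_id=spec.format_id,
        labels=dict(record.labels), source_record_id=record.record_id,
    )


_GRID_PALETTE = [
    ((1.0, 0.87, 0.87), (1.0, 0.62, 0.62)),  # classic red
    ((0.87, 0.92, 1.0), (0.55, 0.70, 0.95)),  # blue
    ((0.88, 0.94, 0.88), (0.60, 0.80, 0.60)),  # green
    ((0.92, 0.92, 0.92), (0.70, 0.70, 0.70)),  # gray
]


def make_format_variants(base: FormatSpec, n: int,
                         rng: np.random.Generator | int = 0) -> list[FormatSpec]:
    """Produce ``n`` distinct layout variants (unseen-format emulation).

    Variants permute panel lead placement, toggle rhythm-strip presence,
    and vary grid colors and margins; deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    variants: list[FormatSpec] = []
    seen = {(base.lead_order, base.rhythm_lead)}
    attempt = 0
    while len(variants) < n:
        attempt += 1
        if attempt > 1000 * n:
            raise RuntimeError("failed to generate distinct format variants")
        order = tuple(rng.permutation(list(base.lead_order)))
        rhythm = base.rhythm_lead if rng.random() < 0.5 else None
        if rhythm is None and base.rhythm_lead is None:
            rhythm = "II"
        key = (order, rhythm)
        if key in seen:
            continue
        seen.add(key)
        minor, major = _GRID_PALETTE[int(rng.integers(len(_GRID_PALETTE)))]
        variants.append(replace(
            base,
            format_id=f"{base.format_id}-var{len(variants)}",
            lead_order=order,
            rhythm_lead=rhythm,
            grid_minor=minor,
            grid_major=major,
            margins_mm=float(rng.uniform(2.0, 7.0)),
        ))
    return variants


# ---------------------------------------------------------------------------
# PNG + JSON sidecar IO
# ---------------------------------------------------------------------------

def write_image(image: RenderedImage, directory: str | Path,
                stem: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{image.source_record_id}-{image.domain}"
    png_path = directory / f"{stem}.png"
    arr = np.rint(np.clip(image.pixels, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr).save(png_path)
    sidecar = {
        "domain": image.domain,
        "format_id": image.format_id,
        "labels": image.labels,
        "source_record_id": image.source_record_id,
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return png_path


def read_image(png_path: str | Path) -> RenderedImage:
    png_path = Path(png_path)
    meta = json.loads(png_path.with_suffix(".json").read_text())
    arr = np.asarray(Image.open(png_path), dtype=np.float32) / 255.0
    return RenderedImage(
        pixels=arr, domain=meta["domain"], format_id=meta["format_id"],
        labels={k: bool(v) for k, v in meta["labels"].items()},
        source_record_id=meta["source_record_id"],
    )


def write_image_manifest(images: list[RenderedImage], directory: str | Path) -> Path:
    """Write images plus a manifest CSV (path, domain, format, labels)."""
    import csv as _csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    conditions = sorted({c for im in images for c in im.labels})
    path = directory / "manifest.csv"
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["path", "source_record_id", "domain", "format_id", *conditions])
        for i, im in enumerate(images):
            p = write_image(im, directory, stem=f"img{i:05d}")
            writer.writerow([p.name, im.source_record_id, im.domain, im.format_id,
                             *[int(im.labels.get(c, False)) for c in conditions]])
    return path
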