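"""Software emulation of mobile-device capture artifacts.

The physical analog is a printed ECG page photographed in a clinic: the page
is crumpled (smooth sinusoidal warp), viewed off-axis (projective warp),
unevenly lit (smooth multiplicative shading), partially occluded (soft dark
patches), slightly out of focus (Gaussian blur) and sensor-noisy. Operators
are applied in that physical-formation order; every operator is label- and
shape-preserving and outputs stay in [0, 1].

``random_perspective`` doubles as the training-time augmentation (distortion
0.15, probability 0.8 on clean source images).

All random draws are consumed regardless of whether a strength is zero, so
two configs differing only in amplitudes produce identically shaped artifact
fields — degradation is then monotone in each strength at a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import ProjectiveTransform, warp

from .render import RenderedImage

__all__ = [
    "CaptureConfig",
    "sample_corner_offsets",
    "random_perspective",
    "simulate_capture",
    "capture_dataset",
]


@dataclass(frozen=True)
class CaptureConfig:
    """Artifact strengths for one capture condition."""

    perspective_strength: float = 0.12  # corner displacement bound (fraction/2)
    illumination_amp: float = 0.35  # multiplicative shading amplitude
    occlusion_count: int = 2
    occlusion_max_frac: float = 0.08  # max area fraction per occlusion
    wave_amp_px: float = 3.0  # crumple displacement amplitude
    blur_sigma_px: float = 0.8
    noise_std: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("perspective_strength", "illumination_amp", "occlusion_count",
                     "occlusion_max_frac", "wave_amp_px", "blur_sigma_px", "noise_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.occlusion_max_frac < 0.25:
            raise ValueError("occlusion_max_frac must be < 0.25")
        if not self.illumination_amp < 1.0:
            raise ValueError("illumination_amp must be < 1")

    def zeroed(self) -> "CaptureConfig":
        """Identity configuration (useful as a no-domain-shift control)."""
        return replace(self, perspective_strength=0.0, illumination_amp=0.0,
                       occlusion_count=0, wave_amp_px=0.0, blur_sigma_px=0.0,
                       noise_std=0.0)


def sample_corner_offsets(rng: np.random.Generator, h: int, w: int,
                          distortion: float) -> np.ndarray:
    """Sample 4 corner displacements, each uniform with |dx| <= distortion*W/2
    and |dy| <= distortion*H/2. Returned shape (4, 2) in (x, y) order for
    corners (TL, TR, BR, BL)."""
    dx = rng.uniform(-distortion * w / 2, distortion * w / 2, size=4)
    dy = rng.uniform(-distortion * h / 2, distortion * h / 2, size=4)
    return np.column_stack([dx, dy])


def _perspective_warp(img: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    h, w = img.shape[:2]
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    # T maps output coords -> input coords; displaced corners show the original
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(corners + offsets, corners)
        if not tform:
            return img.copy()
    else:  # scikit-image < 0.26
        tform = ProjectiveTransform()
        if not tform.estimate(corners + offsets, corners):
            return img.copy()
    return warp(img, tform, order=1, cval=1.0, mode="constant",
                preserve_range=True).astype(img.dtype)


def random_perspective(image: np.ndarray, distortion: float = 0.15,
                       prob: float = 0.8,
                       rng: np.random.Generator | int = 0) -> np.ndarray:
    """Random projective warp of an H x W x 3 image (white fill).

    With probability ``prob`` each corner is displaced independently and
    uniformly by at most ``distortion * dimension / 2``; otherwise the image
    is returned unchanged.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if not 0 <= distortion <= 0.5:
        raise ValueError("distortion must be in [0, 0.5]")
    if not 0 <= prob <= 1:
        raise ValueError("prob must be in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if rng.random() >= prob:
        return image.copy()
    offsets = sample_corner_offsets(rng, image.shape[0], image.shape[1], distortion)
    if distortion == 0:
        return image.copy()
    return _perspective_warp(image, offsets)


def _wave_warp(img: np.ndarray, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth sinusoidal displacement field (crumple/fluttering-page warp)."""
    h, w = img.shape[:2]
    ph = rng.uniform(0, 2 * np.pi, size=4)
    ny = rng.uniform(1.0, 3.0, size=2)  # cycles across the page
    nx = rng.uniform(1.0, 3.0, size=2)
    if amp == 0:
        return img
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dx = amp * np.sin(2 * np.pi * ny[0] * rr / h + ph[0]) \
        * np.cos(2 * np.pi * nx[0] * cc / w + ph[1])
    dy = amp * np.sin(2 * np.pi * nx[1] * cc / w + ph[2]) \
        * np.cos(2 * np.pi * ny[1] * rr / h + ph[3])
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[..., ch] = map_coordinates(img[..., ch], [rr + dy, cc + dx],
                                       order=1, cval=1.0, mode="constant")
    return out


def _illumination_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth random field with values in [-1, 1] (unit shading pattern)."""
    h, w = shape
    ph = rng.uniform(0, 2 * np.pi, size=2)
    fy, fx = rng.uniform(0.5, 1.5, size=2)
    ang = rng.uniform(0, np.pi)
    rr, cc = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    u = np.cos(2 * np.pi * fy * (rr * np.cos(ang) + cc * np.sin(ang)) + ph[0])
    v = np.cos(2 * np.pi * fx * (cc * np.cos(ang) - rr * np.sin(ang)) + ph[1])
    return (u + v) / 2.0


def _occlusion_mask(shape: tuple[int, int], max_frac: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One soft-edged elliptical mask in [0,1] with area <= max_frac; the
    random shape draws do not depend on max_frac's value."""
    h, w = shape
    cy, cx = rng.uniform(0.1, 0.9) * h, rng.uniform(0.1, 0.9) * w
    aspect = rng.uniform(0.4, 2.5)
    frac = rng.uniform(0.3, 1.0)  # fraction of the allowed area actually used
    darkness = rng.uniform(0.5, 0.9)
    ang = rng.uniform(0, np.pi)
    area = frac * max_frac * h * w
    a = np.sqrt(area * aspect / np.pi)
    b = area / (np.pi * a)
    rr, cc = np.meshgrid(np.arange(h) - cy, np.arange(w) - cx, indexing="ij")
    xr = cc * np.cos(ang) + rr * np.sin(ang)
    yr = -cc * np.sin(ang) + rr * np.cos(ang)
    mask = ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0).astype(float)
    mask = gaussian_filter(mask, sigma=max(2.0, 0.02 * min(h, w)))
    return mask, darkness


def simulate_capture(image: RenderedImage, config: CaptureConfig,
                     rng: np.random.Generator | None = None) -> RenderedImage:
    """Apply the capture-artifact pipeline to a clean page image.

    Order: crumple warp -> perspective -> illumination -> occlusions ->
    blur -> noise -> clamp. Labels and format id are preserved; the output
    domain is ``captured``.
    """
    if image.domain != "clean":
        raise ValueError("simulate_capture expects a clean-domain image")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    img = image.pixels.astype(np.float64)
    h, w = img.shape[:2]

    img = _wave_warp(img, config.wave_amp_px, rng)

    offsets = sample_corner_offsets(rng, h, w, config.perspective_strength)
    if config.perspective_strength > 0:
        img = _perspective_warp(img, offsets)

    field = _illumination_field((h, w), rng)
    if config.illumination_amp > 0:
        img = img * (1.0 + config.illumination_amp * field)[..., None]

    for _ in range(config.occlusion_count):
        mask, darkness = _occlusion_mask((h, w), config.occlusion_max_frac, rng)
        img = img * (1.0 - darkness * np.clip(mask, 0, 1))[..., None]

    if config.blur_sigma_px > 0:
        img = gaussian_filter(img, sigma=(config.blur_sigma_px,
                                          config.blur_sigma_px, 0))

    noise = rng.normal(0.0, 1.0, size=img.shape)
    if config.noise_std > 0:
        img = img + config.noise_std * noise

    np.clip(img, 0.0, 1.0, out=img)
    return RenderedImage(
        pixels=img.astype(np.float32), domain="captured",
        format_id=image.format_id, labels=dict(image.labels),
        source_record_id=image.source_record_id,
    )


def capture_dataset(images: list[RenderedImage], config: CaptureConfig,
                    frames_per_image: int = 1, seed: int = 0) -> list[RenderedImage]:
    """Emit ``frames_per_image`` independently perturbed captures per input,
    mirroring consecutive video frames of the same printed page (each frame
    is its own record). Deterministic given ``seed``."""
    if frames_per_image < 1:
        raise ValueError("frames_per_image must be >= 1")
    ss = np.random.SeedSequence(seed)
    out: list[RenderedImage] = []
    for image in images:
        for child in ss.spawn(frames_per_image):
            out.append(simulate_capture(image, config, np.random.default_rng(child)))
    return out
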