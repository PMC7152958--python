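"""Grayscale image container, intensity-scale conventions, and the Gaussian
noise model.

Two intensity scales coexist in MR denoising practice: noise variances are
conventionally quoted on the *unit* scale (pixel values in [0, 1], so variance
0.01 means a noise standard deviation of 0.1, i.e. ~25.5 grey levels), while
MSE/PSNR are quoted on the *byte* scale with peak L = 255.  ``GrayImage``
carries an explicit ``scale`` tag so every conversion between the two is a
deliberate, lossless linear map; quantization to 8-bit happens only when a
file is written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np

Scale = Literal["unit", "byte"]

#: Rec.601 luma weights used when a color image is loaded by accident.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Minimum image extent required by the multiscale transforms downstream.
MIN_SIZE = 8


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D real-valued grayscale image with a declared intensity scale.

    Pixels are stored as float64 and are *not* quantized in memory; ``unit``
    scale means values live in [0, 1], ``byte`` scale means [0, 255].
    """

    pixels: np.ndarray
    scale: Scale = "unit"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError(f"expected a 2-D image, got ndim={arr.ndim}")
        if arr.shape[0] < MIN_SIZE or arr.shape[1] < MIN_SIZE:
            raise ValidationError(
                f"image must be at least {MIN_SIZE}x{MIN_SIZE}, got {arr.shape}"
            )
        if self.scale not in ("unit", "byte"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def clamped(self) -> "GrayImage":
        """Return a copy with pixels clipped to the scale's valid range."""
        hi = 1.0 if self.scale == "unit" else 255.0
        return GrayImage(np.clip(self.pixels, 0.0, hi), self.scale)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive zero-mean Gaussian noise, variance on the unit scale.

    The benchmark sweep uses variances {0.01, 0.03, 0.05, 0.07, 0.09}.
    """

    variance: float
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.variance < 1.0:
            raise ValidationError(
                f"noise variance must lie in (0, 1), got {self.variance}"
            )


def load_image(path: str | Path) -> GrayImage:
    """Read a PNG/TIFF file as a byte-scale grayscale image.

    Color inputs are converted to luminance (Rec.601); 16-bit inputs are
    rescaled linearly so full scale maps to 255.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if raw.size == 0:
        raise ValidationError(f"image file {path} is zero-sized")
    arr = np.asarray(raw)
    if arr.ndim == 3:  # RGB or RGBA -> luminance, alpha dropped
        arr = arr[..., :3].astype(np.float64) @ _LUMA_WEIGHTS
    else:
        arr = arr.astype(np.float64)
    if raw.dtype == np.uint16:
        arr *= 255.0 / 65535.0
    return GrayImage(arr, scale="byte")


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF (the only point of quantization)."""
    byte = convert_scale(img, "byte").clamped()
    iio.imwrite(Path(path), np.round(byte.pixels).astype(np.uint8))


def convert_scale(img: GrayImage, target: Scale) -> GrayImage:
    """Linear scale conversion (factor 255); lossless in memory."""
    if target not in ("unit", "byte"):
        raise ValidationError(f"unknown target scale {target!r}")
    if target == img.scale:
        return img
    factor = 255.0 if target == "byte" else 1.0 / 255.0
    return GrayImage(img.pixels * factor, target)


def add_gaussian_noise(img: GrayImage, spec: NoiseSpec) -> GrayImage:
    """Add i.i.d. Gaussian noise on the unit scale and clamp to [0, 1].

    Deterministic in ``spec.seed``: the same (image, spec) pair always
    produces a bit-identical noisy image.
    """
    if img.scale != "unit":
        raise ValidationError("noise is applied on the unit scale; convert first")
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(spec.mean, np.sqrt(spec.variance), size=img.shape)
    return GrayImage(np.clip(img.pixels + noise, 0.0, 1.0), "unit")


def as_unit_array(img: GrayImage | np.ndarray) -> np.ndarray:
    """Coerce a GrayImage (any scale) or bare array to a unit-scale float array."""
    if isinstance(img, GrayImage):
        return convert_scale(img, "unit").pixels
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D array, got ndim={arr.ndim}")
    return arr
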