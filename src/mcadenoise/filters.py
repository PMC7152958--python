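"""The three per-part denoisers: Wiener filtering and wavelet hard/soft
thresholding.

Wiener filtering comes in two forms.  The *frequency-domain* form applies the
classical transfer function  H* / (|H|^2 + S_eta/S_f)  with the noise power
spectrum taken as flat (white noise) and the signal spectrum estimated from
the observation; the *local-adaptive* form (the practical default, and the
stock denoiser of common numerical environments) estimates a mean and
variance in a sliding window and shrinks each pixel towards its local mean by
the factor (sigma^2 - v)/sigma^2.

Wavelet shrinkage transforms the image, applies hard (keep-or-kill) or soft
(kill-and-shrink) thresholding to the detail coefficients, and inverts.  The
threshold defaults to the Donoho–Johnstone universal rule
lambda = sigma_hat * sqrt(2 ln n) with sigma_hat the median absolute
deviation of the finest diagonal band divided by 0.6745.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pywt
from scipy.ndimage import uniform_filter

from .image_model import GrayImage, ValidationError

_MAD_TO_SIGMA = 0.6745  # Phi^{-1}(0.75): MAD of a centred Gaussian in sigma units


# ---------------------------------------------------------------------------
# Threshold functions
# ---------------------------------------------------------------------------


def hard_threshold(w, lam: float):
    """Keep-or-kill: w where |w| >= lam, else 0.  Scalar or array."""
    if lam < 0:
        raise ValidationError(f"threshold must be >= 0, got {lam}")
    w_arr = np.asarray(w, dtype=np.float64)
    out = np.where(np.abs(w_arr) >= lam, w_arr, 0.0)
    return out if w_arr.ndim else float(out)


def soft_threshold(w, lam: float):
    """Kill-and-shrink: sgn(w) * (|w| - lam) where |w| >= lam, else 0."""
    if lam < 0:
        raise ValidationError(f"threshold must be >= 0, got {lam}")
    w_arr = np.asarray(w, dtype=np.float64)
    out = np.sign(w_arr) * np.maximum(np.abs(w_arr) - lam, 0.0)
    return out if w_arr.ndim else float(out)


def universal_lambda(detail_coeffs: np.ndarray, n_pixels: int) -> float:
    """Universal threshold sigma_hat * sqrt(2 ln n).

    sigma_hat = median(|d|) / 0.6745 from the finest-scale diagonal band,
    the standard robust estimate of the noise level.
    """
    d = np.asarray(detail_coeffs, dtype=np.float64).ravel()
    if d.size == 0:
        raise ValidationError("cannot estimate noise from an empty coefficient band")
    sigma_hat = float(np.median(np.abs(d))) / _MAD_TO_SIGMA
    return sigma_hat * float(np.sqrt(2.0 * np.log(n_pixels)))


# ---------------------------------------------------------------------------
# Wavelet shrinkage denoiser
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveletShrinkConfig:
    wavelet_name: str = "sym4"
    levels: int = 3
    threshold_rule: str = "universal"  # or "fixed"
    fixed_lambda: float = 0.0
    mode: str = "hard"  # or "soft"
    shrink_approximation_band: bool = False

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValidationError("levels must be >= 1")
        if self.threshold_rule not in ("universal", "fixed"):
            raise ValidationError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.fixed_lambda < 0:
            raise ValidationError("fixed_lambda must be >= 0")
        if self.mode not in ("hard", "soft"):
            raise ValidationError(f"unknown shrink mode {self.mode!r}")


def _coerce(img: Union[GrayImage, np.ndarray]) -> tuple[np.ndarray, bool, str]:
    if isinstance(img, GrayImage):
        return img.pixels, True, img.scale
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D image, got ndim={arr.ndim}")
    return arr, False, "unit"


def _wrap(out: np.ndarray, was_image: bool, scale: str):
    return GrayImage(out, scale) if was_image else out


def wavelet_denoise(img: Union[GrayImage, np.ndarray],
                    config: WaveletShrinkConfig | None = None):
    """Multi-level wavelet transform, threshold detail bands, invert.

    The approximation band is left untouched unless
    ``shrink_approximation_band`` is set.  A fixed threshold of 0 is the
    identity (to reconstruction round-off).
    """
    config = config or WaveletShrinkConfig()
    x, was_image, scale = _coerce(img)
    if not np.all(np.isfinite(x)):
        raise ValidationError("input image contains non-finite pixels")
    wavelet = pywt.Wavelet(config.wavelet_name)
    max_lev = pywt.dwtn_max_level(x.shape, wavelet)
    if config.levels > max_lev:
        raise ValidationError(
            f"{config.levels} levels infeasible for shape {x.shape}; max is {max_lev}"
        )
    coeffs = pywt.wavedec2(x, wavelet, mode="symmetric", level=config.levels)
    if config.threshold_rule == "universal":
        finest_diag = coeffs[-1][2]
        lam = universal_lambda(finest_diag, x.size)
    else:
        lam = config.fixed_lambda
    shrink = hard_threshold if config.mode == "hard" else soft_threshold
    new = [shrink(coeffs[0], lam) if config.shrink_approximation_band else coeffs[0]]
    for bands in coeffs[1:]:
        new.append(tuple(shrink(b, lam) for b in bands))
    rec = pywt.waverec2(new, wavelet, mode="symmetric")
    rec = rec[: x.shape[0], : x.shape[1]]  # waverec2 may overshoot odd dims by 1
    return _wrap(rec, was_image, scale)


# ---------------------------------------------------------------------------
# Wiener filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WienerConfig:
    mode: str = "local"  # or "frequency"
    window: int = 3
    noise_variance: Union[float, str] = "estimate"
    blur_kernel: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("local", "frequency"):
            raise ValidationError(f"unknown Wiener mode {self.mode!r}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be an odd integer >= 3")
        if isinstance(self.noise_variance, str):
            if self.noise_variance != "estimate":
                raise ValidationError(
                    f"noise_variance must be a number or 'estimate', got {self.noise_variance!r}"
                )
        elif self.noise_variance < 0:
            raise ValidationError("noise_variance must be >= 0")


def wiener_local(img: Union[GrayImage, np.ndarray],
                 config: WienerConfig | None = None):
    """Pixelwise-adaptive Wiener filter from local window statistics.

    out = mu + (max(sigma^2 - v, 0) / max(sigma^2, v)) * (x - mu), with the
    window mean mu and variance sigma^2 computed under mirror padding and the
    noise power v either given or estimated as the mean local variance.
    """
    config = config or WienerConfig()
    if config.mode != "local":
        raise ValidationError("wiener_local requires mode='local'")
    x, was_image, scale = _coerce(img)
    if config.window >= min(x.shape):
        raise ValidationError(
            f"window {config.window} must be smaller than the image extent {min(x.shape)}"
        )
    v = config.noise_variance
    if v == 0:
        return _wrap(x.copy(), was_image, scale)  # unit gain: exact pass-through
    mu = uniform_filter(x, size=config.window, mode="reflect")
    mu2 = uniform_filter(x * x, size=config.window, mode="reflect")
    var = np.maximum(mu2 - mu * mu, 0.0)
    v = float(var.mean()) if v == "estimate" else float(v)
    num = np.maximum(var - v, 0.0)
    den = np.maximum(var, v)
    gain = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out = mu + gain * (x - mu)
    # A window that is constant at floating precision carries no information
    # to filter: return the pixel itself rather than its round-off-shifted
    # local mean (also covers v estimated as ~0 on a constant image).
    locally_constant = var <= 1e-14 * np.maximum(1.0, mu * mu)
    out[locally_constant] = x[locally_constant]
    return _wrap(out, was_image, scale)


def _kernel_to_otf(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad a centred PSF to `shape` and FFT it (centre at the origin)."""
    kh, kw = kernel.shape
    if kh > shape[0] or kw > shape[1]:
        raise ValidationError(f"blur kernel {kernel.shape} larger than image {shape}")
    padded = np.zeros(shape)
    padded[:kh, :kw] = kernel
    padded = np.roll(padded, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return np.fft.fft2(padded)


def wiener_frequency(img: Union[GrayImage, np.ndarray],
                     config: WienerConfig | None = None):
    """Frequency-domain Wiener deconvolution/denoising.

    Applies  F_hat = G * H_conj / (|H|^2 + S_eta / S_f)  with a flat noise
    spectrum S_eta = v * M * N and the signal spectrum estimated as
    max(|G|^2 - S_eta, delta).  With v = 0 and no blur this is the identity.
    """
    config = config or WienerConfig(mode="frequency", noise_variance=0.0)
    if config.mode != "frequency":
        raise ValidationError("wiener_frequency requires mode='frequency'")
    if config.noise_variance == "estimate":
        raise ValidationError("frequency mode needs an explicit noise_variance")
    x, was_image, scale = _coerce(img)
    m, n = x.shape
    G = np.fft.fft2(x)
    H = (np.ones((m, n), dtype=complex) if config.blur_kernel is None
         else _kernel_to_otf(np.asarray(config.blur_kernel, dtype=np.float64), (m, n)))
    s_eta = float(config.noise_variance) * m * n
    s_f = np.maximum(np.abs(G) ** 2 - s_eta, 1e-12)
    F_hat = np.conj(H) / (np.abs(H) ** 2 + s_eta / s_f) * G
    out = np.real(np.fft.ifft2(F_hat))
    return _wrap(out, was_image, scale)
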