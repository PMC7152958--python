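"""Synthetic test phantoms with known cartoon and texture ground truth.

A phantom is built from two separately stored layers whose morphologies match
the two dictionaries of the sparse decomposition:

* a *cartoon* layer — nested smoothed ellipses (Shepp–Logan-like piecewise
  smooth structure with sharp-but-softened contours), and
* a *texture* layer — an oriented cosine grating windowed either by the
  outermost ellipse ("mask", the default: texture lives inside the brain-like
  region) or by a global Hann envelope ("global").

The clean phantom is the clamped sum of the two layers.  Because both layers
are returned, decomposition quality can be scored against ground truth — a
sharper test than any real MR image allows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_model import GrayImage, NoiseSpec, ValidationError, add_gaussian_noise, save_image

DEFAULT_VARIANCES = (0.01, 0.03, 0.05, 0.07, 0.09)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``texture_frequency`` is in cycles per image width; the default 32 gives
    2 cycles per 16-pixel transform block, a frequency the texture dictionary
    represents sparsely.  ``smooth_sigma`` softens ellipse edges (pixels).
    """

    size: int = 256
    n_ellipses: int = 4
    ellipse_intensity_range: tuple[float, float] = (0.12, 0.28)
    texture_frequency: float = 32.0
    texture_amplitude: float = 0.10
    texture_orientation: float = 30.0  # degrees
    texture_region: str = "mask"
    smooth_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValidationError("phantom size must be >= 16")
        if self.n_ellipses < 1:
            raise ValidationError("n_ellipses must be >= 1")
        lo, hi = self.ellipse_intensity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("ellipse_intensity_range must be within [0, 1]")
        if self.texture_region not in ("mask", "global"):
            raise ValidationError(f"unknown texture_region {self.texture_region!r}")
        if self.smooth_sigma < 0:
            raise ValidationError("smooth_sigma must be >= 0")


def _ellipse_mask(n: int, cy: float, cx: float, ry: float, rx: float, angle: float) -> np.ndarray:
    """Boolean indicator of a rotated ellipse on an n x n grid."""
    y, x = np.mgrid[0:n, 0:n].astype(np.float64)
    y = y - cy
    x = x - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, GrayImage, GrayImage]:
    """Build (clean, cartoon_truth, texture_truth), all unit-scale.

    clean = clip(cartoon_truth + texture_truth, 0, 1); construction keeps the
    sum inside [0, 1] almost everywhere, and an error is raised if clamping
    would destroy more than 5% of the texture layer's energy.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    lo, hi = spec.ellipse_intensity_range

    # Nested ellipses: axes shrink geometrically, centers jitter slightly.
    cartoon = np.zeros((n, n))
    cy0, cx0 = n / 2.0, n / 2.0
    ry, rx = 0.42 * n, 0.34 * n
    outer = None
    for k in range(spec.n_ellipses):
        cy = cy0 + rng.uniform(-0.02, 0.02) * n
        cx = cx0 + rng.uniform(-0.02, 0.02) * n
        angle = rng.uniform(0, np.pi)
        mask = _ellipse_mask(n, cy, cx, ry, rx, angle)
        if outer is None:
            outer = mask
        cartoon += rng.uniform(lo, hi) * mask
        ry *= 0.72
        rx *= 0.72
    if spec.smooth_sigma > 0:
        cartoon = gaussian_filter(cartoon, spec.smooth_sigma, mode="nearest")
        outer_soft = gaussian_filter(outer.astype(np.float64), spec.smooth_sigma, mode="nearest")
    else:
        outer_soft = outer.astype(np.float64)
    cartoon = np.clip(cartoon, 0.0, 1.0)

    # Oriented cosine grating, windowed.
    y, x = np.mgrid[0:n, 0:n].astype(np.float64)
    theta = np.deg2rad(spec.texture_orientation)
    phase = 2.0 * np.pi * spec.texture_frequency * (x * np.cos(theta) + y * np.sin(theta)) / n
    grating = np.cos(phase)
    if spec.texture_region == "mask":
        window = outer_soft
    else:
        hann = np.hanning(n)
        window = np.outer(hann, hann)
    texture = spec.texture_amplitude * grating * window

    raw = cartoon + texture
    clean = np.clip(raw, 0.0, 1.0)
    tex_energy = float(np.sum(texture**2))
    lost = float(np.sum((clean - raw) ** 2))
    if tex_energy > 0 and lost > 0.05 * tex_energy:
        raise ValidationError(
            "clamping destroys more than 5% of the texture layer's energy; "
            "reduce texture_amplitude or ellipse intensities"
        )
    return (
        GrayImage(clean, "unit"),
        GrayImage(cartoon, "unit"),
        GrayImage(texture, "unit"),
    )


def default_phantoms(size: int = 256) -> dict[str, PhantomSpec]:
    """The three stock phantoms used by the benchmark harness.

    They differ in ellipse count, grating frequency/orientation and seed, the
    way the three MR images of a typical evaluation differ in content.
    """
    return {
        "phantom1": PhantomSpec(size=size, n_ellipses=4, texture_frequency=32.0,
                                texture_orientation=30.0, seed=101),
        "phantom2": PhantomSpec(size=size, n_ellipses=5, texture_frequency=24.0,
                                texture_orientation=75.0, seed=202),
        "phantom3": PhantomSpec(size=size, n_ellipses=3, texture_frequency=40.0,
                                texture_orientation=0.0, texture_amplitude=0.08,
                                seed=303),
    }


def make_test_suite(
    out_dir: str | Path,
    seeds: list[int] | tuple[int, ...] = (0,),
    variances: tuple[float, ...] = DEFAULT_VARIANCES,
    size: int = 256,
) -> dict:
    """Write the three stock phantoms plus noisy versions; return the manifest.

    For each phantom: a clean PNG, a lossless NPZ sidecar with the float
    layers, and one noisy PNG+NPZ per (variance, seed).  The manifest JSON
    lists every file with its generating parameters.
    """
    if not seeds or not variances:
        raise ValidationError("seeds and variances must be non-empty")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    manifest: dict = {"phantoms": {}, "variances": list(variances), "seeds": list(seeds)}
    for name, spec in default_phantoms(size=size).items():
        clean, cartoon, texture = make_phantom(spec)
        save_image(clean, out_dir / f"{name}_clean.png")
        np.savez(
            out_dir / f"{name}_layers.npz",
            clean=clean.pixels, cartoon=cartoon.pixels, texture=texture.pixels,
        )
        entry = {
            "spec": {k: getattr(spec, k) for k in (
                "size", "n_ellipses", "texture_frequency", "texture_amplitude",
                "texture_orientation", "texture_region", "smooth_sigma", "seed")},
            "clean": f"{name}_clean.png",
            "layers": f"{name}_layers.npz",
            "noisy": [],
        }
        for var in variances:
            for seed in seeds:
                noisy = add_gaussian_noise(clean, NoiseSpec(variance=var, seed=seed))
                fname = f"{name}_noisy_v{var:g}_s{seed}"
                save_image(noisy, out_dir / f"{fname}.png")
                np.savez(out_dir / f"{fname}.npz", noisy=noisy.pixels)
                entry["noisy"].append(
                    {"file": f"{fname}.png", "sidecar": f"{fname}.npz",
                     "variance": var, "seed": seed}
                )
        manifest["phantoms"][name] = entry
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
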