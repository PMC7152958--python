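"""Morphological component analysis: cartoon + texture + residual.

An image ``s`` is separated into a piecewise-smooth *cartoon* part, an
oscillatory *texture* part, and a *residual* holding whatever neither
dictionary represents sparsely:

    s = cartoon + texture + residual        (exact, by construction)

Each morphological part is represented in its own dictionary — an undecimated
(stationary) wavelet frame for the cartoon, an overlapping windowed block-DCT
frame for the texture — and the l1-relaxed separation problem is solved by
block-coordinate relaxation: alternately re-estimate each part from its
marginal residual through analysis, hard thresholding at a threshold that
decreases linearly over the iterations, and synthesis.  Unlike classical MCA
denoising, the final residual is *retained* as a third part rather than
discarded, so the identity above holds for every input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dctn, idctn

from .filters import hard_threshold
from .image_model import GrayImage, ValidationError, as_unit_array

# ---------------------------------------------------------------------------
# Coefficient container and dictionary protocol
# ---------------------------------------------------------------------------


@dataclass
class CoefficientSet:
    """Transform coefficients plus the geometry needed for exact synthesis.

    ``bands`` is a list of coefficient arrays: for the wavelet dictionary one
    array per subband (approximation first, then detail bands coarse→fine,
    each tagged in ``meta['structure']``); for the block-DCT dictionary a
    single 4-D array indexed (block_row, block_col, i, j).
    """

    bands: list[np.ndarray]
    meta: dict

    def map(self, fn: Callable[[np.ndarray], np.ndarray]) -> "CoefficientSet":
        return CoefficientSet([fn(b) for b in self.bands], self.meta)

    def max_abs(self) -> float:
        return max(float(np.abs(b).max()) for b in self.bands)

    def abs_values(self) -> np.ndarray:
        return np.concatenate([np.abs(b).ravel() for b in self.bands])


@dataclass
class Dictionary:
    """A perfect-reconstruction analysis/synthesis pair for one morphology.

    ``shrink`` applies the dictionary's coefficient-selection policy at
    threshold λ inside the separation solver; ``shrinkable_values`` returns
    the magnitudes of the coefficients the policy may kill (used to set the
    solver's starting threshold).  The policies restrict which atoms a
    *component* may use — they do not affect the transform pair itself,
    which reconstructs exactly.
    """

    name: str
    kind: str  # "cartoon" | "texture"
    analyze: Callable[[np.ndarray], CoefficientSet]
    synthesize: Callable[[CoefficientSet], np.ndarray]
    shrink: Callable[[CoefficientSet, float], CoefficientSet] = None  # type: ignore[assignment]
    shrinkable_values: Callable[[CoefficientSet], np.ndarray] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.shrink is None:
            self.shrink = lambda cs, lam: cs.map(lambda b: hard_threshold(b, lam))
        if self.shrinkable_values is None:
            self.shrinkable_values = lambda cs: cs.abs_values()


# ---------------------------------------------------------------------------
# Cartoon dictionary: undecimated wavelet transform
# ---------------------------------------------------------------------------


def build_cartoon_dictionary(levels: int = 3, wavelet_name: str = "sym4") -> Dictionary:
    """Shift-invariant wavelet frame (stationary wavelet transform).

    Images are mirror-padded to a multiple of 2**levels; the original extent
    is recorded so synthesis crops back exactly.
    """
    if levels < 1:
        raise ValidationError("levels must be >= 1")
    wavelet = pywt.Wavelet(wavelet_name)
    div = 2**levels

    def analyze(x: np.ndarray) -> CoefficientSet:
        x = np.asarray(x, dtype=np.float64)
        m, n = x.shape
        max_levels = int(np.floor(np.log2(min(m, n))))
        if levels > max_levels:
            raise ValidationError(
                f"{levels} levels too deep for a {m}x{n} image; max feasible is {max_levels}"
            )
        pm = (-m) % div
        pn = (-n) % div
        xp = np.pad(x, ((0, pm), (0, pn)), mode="symmetric")
        coeffs = pywt.swt2(xp, wavelet, level=levels, norm=True, trim_approx=True)
        bands = [coeffs[0]]
        structure = ["approx"]
        for lev, (ch, cv, cd) in enumerate(coeffs[1:]):
            bands.extend([ch, cv, cd])
            depth = levels - lev  # coarse -> fine
            structure.extend([f"H{depth}", f"V{depth}", f"D{depth}"])
        return CoefficientSet(bands, {"shape": (m, n), "levels": levels,
                                      "structure": structure})

    def synthesize(cs: CoefficientSet) -> np.ndarray:
        lv = cs.meta["levels"]
        coeffs = [cs.bands[0]]
        for k in range(lv):
            i = 1 + 3 * k
            coeffs.append(tuple(cs.bands[i:i + 3]))
        rec = pywt.iswt2(coeffs, wavelet, norm=True)
        m, n = cs.meta["shape"]
        return np.ascontiguousarray(rec[:m, :n])

    # Selection policy: the approximation (lowpass) band always belongs to
    # the cartoon component, so it is exempt from thresholding.
    def shrink(cs: CoefficientSet, lam: float) -> CoefficientSet:
        bands = [cs.bands[0]] + [hard_threshold(b, lam) for b in cs.bands[1:]]
        return CoefficientSet(bands, cs.meta)

    def shrinkable_values(cs: CoefficientSet) -> np.ndarray:
        return np.concatenate([np.abs(b).ravel() for b in cs.bands[1:]])

    return Dictionary(f"uwt:{wavelet_name}:{levels}", "cartoon", analyze, synthesize,
                      shrink, shrinkable_values)


# ---------------------------------------------------------------------------
# Texture dictionary: overlapping windowed block DCT
# ---------------------------------------------------------------------------


def build_texture_dictionary(block_size: int = 16, overlap: float = 0.5) -> Dictionary:
    """Overlapping block-DCT frame with a sine window.

    With ``overlap=1/2`` the blocks are weighted by a separable sine window
    whose squares sum to a constant over half-block hops, so weighted
    overlap-add synthesis reconstructs exactly; with ``overlap=0`` the blocks
    tile and the window is flat.
    """
    if block_size not in (8, 16, 32):
        raise ValidationError("block_size must be one of 8, 16, 32")
    if overlap not in (0, 0.5):
        raise ValidationError("overlap must be 0 or 1/2")
    B = block_size
    hop = B if overlap == 0 else B // 2
    if overlap == 0:
        w2d = np.ones((B, B))
    else:
        w = np.sin(np.pi * (np.arange(B) + 0.5) / B)
        w2d = np.outer(w, w)

    def _geometry(m: int, n: int) -> tuple[int, int, int, int]:
        pad = B - hop  # reflect margin so every original pixel is fully covered
        mp = m + 2 * pad
        np_ = n + 2 * pad
        mp += (-(mp - B)) % hop if mp >= B else 0
        np_ += (-(np_ - B)) % hop if np_ >= B else 0
        return pad, mp, np_, hop

    def analyze(x: np.ndarray) -> CoefficientSet:
        x = np.asarray(x, dtype=np.float64)
        m, n = x.shape
        if m < B or n < B:
            raise ValidationError(
                f"image {m}x{n} smaller than one {B}x{B} block"
            )
        pad, mp, np_, _ = _geometry(m, n)
        xp = np.pad(x, ((pad, mp - m - pad), (pad, np_ - n - pad)), mode="symmetric")
        blocks = sliding_window_view(xp, (B, B))[::hop, ::hop]
        coeffs = dctn(blocks * w2d, axes=(-2, -1), norm="ortho")
        return CoefficientSet([np.ascontiguousarray(coeffs)],
                              {"shape": (m, n), "block_size": B, "hop": hop,
                               "padded_shape": (mp, np_), "pad": pad})

    def synthesize(cs: CoefficientSet) -> np.ndarray:
        (coeffs,) = cs.bands
        m, n = cs.meta["shape"]
        mp, np_ = cs.meta["padded_shape"]
        pad = cs.meta["pad"]
        rec = idctn(coeffs, axes=(-2, -1), norm="ortho") * w2d
        out = np.zeros((mp, np_))
        den = np.zeros((mp, np_))
        w2sq = w2d * w2d
        nby, nbx = coeffs.shape[:2]
        for i in range(nby):
            r0 = i * hop
            for j in range(nbx):
                c0 = j * hop
                out[r0:r0 + B, c0:c0 + B] += rec[i, j]
                den[r0:r0 + B, c0:c0 + B] += w2sq
        return out[pad:pad + m, pad:pad + n] / den[pad:pad + m, pad:pad + n]

    # Selection policy: block-DCT atoms of very low spatial frequency can
    # also code piecewise-smooth content, so the texture component is barred
    # from using them (coefficients with index sum below the cutoff are
    # zeroed); smooth content is left for the cartoon dictionary.
    low_freq_cutoff = max(2, B // 8)

    def shrink(cs: CoefficientSet, lam: float) -> CoefficientSet:
        (coeffs,) = cs.bands
        out = hard_threshold(coeffs, lam)
        ii, jj = np.meshgrid(np.arange(B), np.arange(B), indexing="ij")
        out[..., ii + jj < low_freq_cutoff] = 0.0
        return CoefficientSet([out], cs.meta)

    def shrinkable_values(cs: CoefficientSet) -> np.ndarray:
        (coeffs,) = cs.bands
        ii, jj = np.meshgrid(np.arange(B), np.arange(B), indexing="ij")
        return np.abs(coeffs[..., ii + jj >= low_freq_cutoff]).ravel()

    return Dictionary(f"dct:{B}:{overlap:g}", "texture", analyze, synthesize,
                      shrink, shrinkable_values)


def build_dictionary(name: str) -> Dictionary:
    """Build a dictionary from its compact name, e.g. ``uwt:sym4:3`` or ``dct:16:0.5``."""
    parts = name.split(":")
    if parts[0] == "uwt" and len(parts) == 3:
        return build_cartoon_dictionary(levels=int(parts[2]), wavelet_name=parts[1])
    if parts[0] == "dct" and len(parts) == 3:
        return build_texture_dictionary(block_size=int(parts[1]), overlap=float(parts[2]))
    raise ValidationError(f"unknown dictionary name {name!r}")


# ---------------------------------------------------------------------------
# The decomposition solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McaConfig:
    """Solver settings for the block-coordinate relaxation.

    The threshold descends linearly from λ_max (set from the data: the
    second-largest coefficient magnitude across both dictionaries, so the
    very first iteration already transfers at least one atom) towards
    ``lambda_min``.  With the default ``lambda_min = 0`` the schedule stops
    one step short of zero (final threshold λ_max/n): a threshold of exactly
    zero would make the last pass a perfect-reconstruction copy and collapse
    the residual identically to zero.
    """

    n_iterations: int = 100
    lambda_min: float = 0.0
    schedule: str = "linear"
    cartoon_dictionary: str = "uwt:sym4:3"
    texture_dictionary: str = "dct:16:0.5"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.lambda_min < 0:
            raise ValidationError("lambda_min must be >= 0")
        if self.schedule != "linear":
            raise ValidationError(f"unknown schedule {self.schedule!r}")


@dataclass
class Decomposition:
    """The three additive parts; ``cartoon + texture + residual == input`` exactly."""

    cartoon: np.ndarray
    texture: np.ndarray
    residual: np.ndarray
    iterations_run: int
    final_threshold: float


def _lambda_max(dicts: list[Dictionary], s: np.ndarray) -> float:
    mags = np.concatenate([d.shrinkable_values(d.analyze(s)) for d in dicts])
    if mags.size < 2:
        return float(mags.max(initial=0.0))
    return float(np.partition(mags, -2)[-2])  # second largest


def mca_decompose(
    img: GrayImage | np.ndarray,
    config: McaConfig | None = None,
    callback: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
) -> Decomposition:
    """Separate an image into cartoon, texture, and residual parts.

    ``callback(t, cartoon, texture)`` (if given) is invoked after each
    iteration, enabling convergence diagnostics.  The parts are unit-scale
    but individually unclamped — only their sum is an image.
    """
    config = config or McaConfig()
    s = as_unit_array(img)
    if not np.all(np.isfinite(s)):
        raise ValidationError("input image contains non-finite pixels")

    dict_c = build_dictionary(config.cartoon_dictionary)
    dict_t = build_dictionary(config.texture_dictionary)

    if not s.any():  # all-zero fixed point, skip the iterations
        z = np.zeros_like(s)
        return Decomposition(z, z.copy(), z.copy(), config.n_iterations, 0.0)

    lam_max = _lambda_max([dict_c, dict_t], s)
    n = config.n_iterations
    cartoon = np.zeros_like(s)
    texture = np.zeros_like(s)
    lam = lam_max
    for t in range(n):
        lam = lam_max - (lam_max - config.lambda_min) * t / n
        r = s - texture
        cartoon = dict_c.synthesize(dict_c.shrink(dict_c.analyze(r), lam))
        r = s - cartoon
        texture = dict_t.synthesize(dict_t.shrink(dict_t.analyze(r), lam))
        if callback is not None:
            callback(t + 1, cartoon, texture)
    residual = s - cartoon - texture
    return Decomposition(cartoon, texture, residual, n, lam)
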