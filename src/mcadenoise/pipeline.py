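"""The hybrid denoiser: decompose, filter each part, superimpose.

The proposed method is **WHS**: Wiener on the cartoon part, wavelet hard
thresholding on the texture part, wavelet soft thresholding on the residual.
All six assignments of the three filters to the three parts are supported for
ablation; ``enumerate_assignments`` lists them in the canonical order
SHW, SWH, HSW, HWS, WSH, WHS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .filters import WaveletShrinkConfig, WienerConfig, wavelet_denoise, wiener_local
from .image_model import GrayImage, ValidationError
from .mca import Decomposition, McaConfig, mca_decompose

METHOD_IDS = ("wiener", "hard", "soft")
_INITIAL = {"wiener": "W", "hard": "H", "soft": "S"}
_FROM_INITIAL = {v: k for k, v in _INITIAL.items()}


@dataclass(frozen=True)
class MethodAssignment:
    """Which filter denoises which part; labelled by initials in part order."""

    cartoon: str = "wiener"
    texture: str = "hard"
    residual: str = "soft"

    def __post_init__(self) -> None:
        for part in (self.cartoon, self.texture, self.residual):
            if part not in METHOD_IDS:
                raise ValidationError(f"unknown method id {part!r}; use one of {METHOD_IDS}")

    @property
    def label(self) -> str:
        return _INITIAL[self.cartoon] + _INITIAL[self.texture] + _INITIAL[self.residual]

    @classmethod
    def from_label(cls, label: str) -> "MethodAssignment":
        if len(label) != 3 or any(ch not in _FROM_INITIAL for ch in label.upper()):
            raise ValidationError(f"assignment label must be 3 of W/H/S, got {label!r}")
        c, t, r = (_FROM_INITIAL[ch] for ch in label.upper())
        return cls(cartoon=c, texture=t, residual=r)


#: Canonical ablation order; the proposed method (WHS) comes last.
ASSIGNMENT_ORDER = ("SHW", "SWH", "HSW", "HWS", "WSH", "WHS")


def enumerate_assignments() -> list[MethodAssignment]:
    """All six assignments of {Wiener, hard, soft} to the three parts."""
    return [MethodAssignment.from_label(lbl) for lbl in ASSIGNMENT_ORDER]


@dataclass(frozen=True)
class FilterConfigs:
    """Per-method filter settings shared by all parts a method is assigned to."""

    wiener: WienerConfig = field(default_factory=WienerConfig)
    hard: WaveletShrinkConfig = field(default_factory=lambda: WaveletShrinkConfig(mode="hard"))
    soft: WaveletShrinkConfig = field(default_factory=lambda: WaveletShrinkConfig(mode="soft"))


def _apply_method(part: np.ndarray, method: str, configs: FilterConfigs) -> np.ndarray:
    if method == "wiener":
        return wiener_local(part, configs.wiener)
    config = configs.hard if method == "hard" else configs.soft
    if config.mode != method:
        config = replace(config, mode=method)
    return wavelet_denoise(part, config)


def denoise_parts(
    decomposition: Decomposition,
    assignment: MethodAssignment,
    filter_configs: FilterConfigs | None = None,
) -> GrayImage:
    """Filter each part of an existing decomposition and superimpose.

    Useful when several assignments are evaluated on the same noisy image:
    the (deterministic) decomposition is computed once and shared.
    """
    configs = filter_configs or FilterConfigs()
    total = (
        _apply_method(decomposition.cartoon, assignment.cartoon, configs)
        + _apply_method(decomposition.texture, assignment.texture, configs)
        + _apply_method(decomposition.residual, assignment.residual, configs)
    )
    return GrayImage(np.clip(total, 0.0, 1.0), "unit")


def denoise_hybrid(
    noisy: GrayImage,
    assignment: MethodAssignment | str = "WHS",
    mca_config: McaConfig | None = None,
    filter_configs: FilterConfigs | None = None,
) -> GrayImage:
    """Full hybrid pipeline: MCA decomposition, per-part filtering, clamp.

    Parts are filtered unclamped (only their sum is an image); the
    superposition is clamped to [0, 1] so the result is a valid image.
    """
    if isinstance(assignment, str):
        assignment = MethodAssignment.from_label(assignment)
    if noisy.scale != "unit":
        raise ValidationError("hybrid denoising expects a unit-scale image")
    decomposition = mca_decompose(noisy, mca_config)
    return denoise_parts(decomposition, assignment, filter_configs)
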