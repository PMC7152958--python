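"""Image-quality metrics (MSE, PSNR) and the benchmark harness.

MSE is computed on the byte scale (peak L = 255), PSNR = 10 log10(L^2 / MSE)
in dB, the convention under which a byte-scale MSE of 87 corresponds to
28.74 dB.  The harness adds seeded Gaussian noise to each clean image once
per (variance, seed) cell and scores every method on the *same* noisy
realization, so that differences between rows isolate the method effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import wavelet_denoise, wiener_local
from .image_model import GrayImage, NoiseSpec, ValidationError, add_gaussian_noise, convert_scale
from .mca import McaConfig, mca_decompose
from .pipeline import ASSIGNMENT_ORDER, FilterConfigs, MethodAssignment, denoise_parts

PEAK = 255.0


def mse(reference: GrayImage, test: GrayImage) -> float:
    """Mean squared error on the byte scale: (1/MN) * sum (f - f_hat)^2."""
    ref = convert_scale(reference, "byte").pixels
    tst = convert_scale(test, "byte").pixels
    if ref.shape != tst.shape:
        raise ValidationError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    return float(np.mean((ref - tst) ** 2))


def psnr(reference: GrayImage, test: GrayImage, peak: float = PEAK) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE), +inf for equal images."""
    err = mse(reference, test)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / err))


#: Methods the harness understands besides 3-letter assignment labels.
STANDALONE_METHODS = ("wiener", "hard", "soft")


def _denoise_standalone(noisy: GrayImage, method: str, configs: FilterConfigs) -> GrayImage:
    from dataclasses import replace

    if method == "wiener":
        return wiener_local(noisy, configs.wiener).clamped()
    config = configs.hard if method == "hard" else configs.soft
    if config.mode != method:
        config = replace(config, mode=method)
    return wavelet_denoise(noisy, config).clamped()


def run_benchmark(
    clean_images: dict[str, GrayImage],
    variances=(0.01, 0.03, 0.05, 0.07, 0.09),
    methods=("wiener", "hard", "soft", "WHS"),
    seeds=(0,),
    mca_config: McaConfig | None = None,
    filter_configs: FilterConfigs | None = None,
    include_noisy_baseline: bool = True,
) -> pd.DataFrame:
    """Evaluate methods over a noise-variance sweep.

    ``methods`` may mix standalone filters ("wiener", "hard", "soft" applied
    to the whole image) with 3-letter assignment labels ("WHS", ...); all
    assignments share one decomposition per noisy realization.  Returns one
    row per (image, variance, seed, method) with byte-scale MSE and PSNR in
    dB; the "noisy" baseline row scores the noisy input itself.
    """
    if not clean_images or not len(variances) or not len(methods) or not len(seeds):
        raise ValidationError("clean_images, variances, methods, seeds must be non-empty")
    configs = filter_configs or FilterConfigs()
    assignment_labels = [m for m in methods if len(m) == 3 and m.upper() == m]
    rows = []
    for image_id, clean in clean_images.items():
        for variance in variances:
            for seed in seeds:
                noisy = add_gaussian_noise(clean, NoiseSpec(variance=variance, seed=seed))
                decomposition = (
                    mca_decompose(noisy, mca_config) if assignment_labels else None
                )
                results: dict[str, GrayImage] = {}
                if include_noisy_baseline:
                    results["noisy"] = noisy
                for method in methods:
                    if method in STANDALONE_METHODS:
                        results[method] = _denoise_standalone(noisy, method, configs)
                    else:
                        assignment = MethodAssignment.from_label(method)
                        results[method] = denoise_parts(decomposition, assignment, configs)
                for method, out in results.items():
                    err = mse(clean, out)
                    rows.append(
                        {"image_id": image_id, "variance": variance, "seed": seed,
                         "method": method, "mse": err,
                         "psnr": psnr(clean, out)}
                    )
    return pd.DataFrame(rows)


def average_table(records: pd.DataFrame) -> pd.DataFrame:
    """Mean MSE/PSNR per (method, variance), averaged over images and seeds."""
    return (
        records.groupby(["method", "variance"], as_index=False)[["mse", "psnr"]]
        .mean()
        .sort_values(["method", "variance"], ignore_index=True)
    )


def ablation_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-image PSNR of the six assignments plus a "Max" row per variance.

    Rows are ordered SHW, SWH, HSW, HWS, WSH, WHS, Max within each image;
    columns are the noise variances.
    """
    labels = [lbl for lbl in ASSIGNMENT_ORDER if lbl in set(records["method"])]
    sub = records[records["method"].isin(labels)]
    table = (
        sub.pivot_table(index=["image_id", "method"], columns="variance",
                        values="psnr", aggfunc="mean")
        .reindex(labels, level="method")
    )
    pieces = []
    for image_id, block in table.groupby(level="image_id"):
        max_row = block.max(axis=0).to_frame().T
        max_row.index = pd.MultiIndex.from_tuples(
            [(image_id, "Max")], names=["image_id", "method"]
        )
        pieces.append(pd.concat([block, max_row]))
    return pd.concat(pieces)
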