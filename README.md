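# mcadenoise

Hybrid denoising of MR images based on morphological component analysis
(MCA). A noisy image is separated into three additive parts —

* **cartoon**: piecewise-smooth regions with sharp contours, represented
  sparsely in a shift-invariant wavelet frame,
* **texture**: oscillatory, locally periodic content, represented sparsely
  in an overlapping windowed block-DCT frame,
* **residual**: whatever neither dictionary codes sparsely, *retained* as a
  third part rather than discarded,

so that `s = cartoon + texture + residual` holds exactly. Each part is then
denoised by the classical filter suited to its morphology — adaptive
**W**iener filtering, wavelet **H**ard thresholding (keep |w| ≥ λ, kill the
rest), wavelet **S**oft thresholding (sgn(w)(|w| − λ)) with the universal
threshold λ = σ̂√(2 ln n) — and the filtered parts are superimposed. The
proposed assignment is **WHS** (Wiener→cartoon, hard→texture,
soft→residual); all six assignments are available for ablation. Quality is
scored by byte-scale MSE and PSNR = 10 log₁₀(255²/MSE) dB over a Gaussian
noise-variance sweep σ² ∈ {0.01, 0.03, 0.05, 0.07, 0.09} (unit intensity
scale).

The package is aimed at medical-image-analysis practitioners who want a
transparent, fully deterministic reference implementation of
decompose-then-filter denoising, together with synthetic brain-like
phantoms whose cartoon/texture ground-truth layers make separation quality
measurable. See `docs/methods.md` for the model, solver and design choices.

## Worked example

```python
from mcadenoise import (PhantomSpec, NoiseSpec, make_phantom, add_gaussian_noise,
                        mca_decompose, denoise_parts, MethodAssignment, mse, psnr)

clean, cartoon_truth, texture_truth = make_phantom(PhantomSpec(size=256, seed=0))
noisy = add_gaussian_noise(clean, NoiseSpec(variance=0.05, seed=42))

decomp = mca_decompose(noisy)                      # cartoon/texture/residual
denoised = denoise_parts(decomp, MethodAssignment.from_label("WHS"))

print(f"noisy:    MSE {mse(clean, noisy):7.1f}   PSNR {psnr(clean, noisy):.2f} dB")
print(f"denoised: MSE {mse(clean, denoised):7.1f}   PSNR {psnr(clean, denoised):.2f} dB")
```

prints

```
noisy:    MSE  2023.4   PSNR 15.07 dB
denoised: MSE   795.1   PSNR 19.13 dB
```

i.e. at noise variance 0.05 the hybrid WHS pipeline cuts the mean squared
error by ~60% and gains ~4 dB PSNR over the noisy input on the default
phantom.

## Command line

```sh
mcadenoise phantom   --out-dir phantoms --size 256          # stock test images
mcadenoise decompose --in noisy.png --out-prefix parts      # 3-part split
mcadenoise denoise   --in noisy.png --out clean_est.png --assignment WHS \
                     --clean reference.png                  # reports MSE/PSNR
mcadenoise benchmark --out bench.csv                        # variance sweep
```

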