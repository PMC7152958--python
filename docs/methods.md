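# Methods

## The model

An observed MR image is modelled as a clean image plus i.i.d. zero-mean
Gaussian noise,

    g(x, y) = f(x, y) + η(x, y),    η ~ N(0, σ²),

with the noise variance quoted on the unit intensity scale (σ² = 0.01–0.09,
i.e. σ ≈ 25–76 grey levels on the byte scale). Gaussian noise is the standard
high-SNR approximation to the Rician statistics of magnitude MRI; Rician
modelling is out of scope.

The denoiser rests on a three-part additive decomposition of the noisy
image,

    s = Φ_c α_c + Φ_t α_t + R,

where Φ_c and Φ_t are two mutually incoherent overcomplete dictionaries — a
shift-invariant (stationary) wavelet frame for the piecewise-smooth *cartoon*
morphology and an overlapping windowed block-DCT frame for the oscillatory
*texture* morphology — and R is the *residual*, defined as whatever neither
dictionary codes sparsely. The residual is retained as a first-class part
rather than discarded. Each part is then denoised by the filter best suited
to its morphology and the filtered parts are superimposed and clamped to
[0, 1]. The proposed assignment is **WHS**: adaptive **W**iener on the
cartoon, wavelet **H**ard thresholding on the texture, wavelet **S**oft
thresholding on the residual. All 3! = 6 assignments are available for
ablation, enumerated in the fixed order SHW, SWH, HSW, HWS, WSH, WHS.

## The separation solver

The l1-relaxed separation problem

    min ‖α_c‖₁ + ‖α_t‖₁   s.t.  ‖s − Φ_c α_c − Φ_t α_t‖² ≤ ε

is solved by block-coordinate relaxation with iterative hard thresholding:
at iteration t each component is re-estimated from its marginal residual
(`r = s − other component`) by analysis → hard threshold at λ(t) →
synthesis. λ(t) descends linearly from λ_max, the second-largest shrinkable
coefficient magnitude at initialisation (so the first iteration already
transfers at least one atom), towards `lambda_min` over a fixed budget of
`n_iterations` (default 100). The tolerance ε is realised implicitly by the
finite schedule, which also makes the solver fully deterministic.

Two deliberate refinements of the textbook update:

* **The schedule stops one step short of `lambda_min` = 0.** A final
  threshold of exactly zero would make the last pass a perfect-reconstruction
  copy (hard thresholding at 0 keeps every coefficient), which forces the
  residual to be identically zero and degenerates the three-part model into
  a two-part one. With λ(t) = λ_max − (λ_max − λ_min)·t/n for t = 0…n−1 the
  last threshold applied is λ_max/n.
* **Per-dictionary atom-selection policies.** The wavelet approximation
  (lowpass) band is exempt from thresholding — lowpass content always
  belongs to the cartoon. Block-DCT coefficients with frequency-index sum
  below max(2, B/8) are barred from the texture component, because those
  atoms can also code smooth content: without this exclusion the block DC
  atoms absorb the entire image into the texture part and the separation
  collapses. Both policies are standard practice for this dictionary pairing
  (the "low-frequency-discarded local DCT"); they restrict which atoms a
  *component* may use and do not affect the transforms, which remain exact
  analysis/synthesis pairs.

Exact additivity (cartoon + texture + residual = input, to machine
precision) holds for every input and configuration because the residual is
computed by subtraction.

### Dictionaries

* Cartoon: undecimated 2-D wavelet transform, `sym4`, 3 levels, normalised
  (`uwt:sym4:3`). Inputs are padded (mirror) to a multiple of 2^levels and
  cropped after synthesis; the stationary transform itself is periodic, so
  wrap-seam coefficients exist for images with unequal opposite borders —
  negligible for brain-like images with dark margins.
* Texture: block DCT, 16×16 blocks, half-block overlap with a separable sine
  window, weighted overlap-add synthesis normalised by the accumulated
  squared window (`dct:16:0.5`). Reconstruction is exact for any window.
  Overlap 0 (flat window) is also available.

## Per-part filters

* **Adaptive Wiener** (`wiener_local`, pipeline default): per-pixel
  shrinkage towards the local mean, `out = μ + (max(σ²_loc − v, 0) /
  max(σ²_loc, v))(x − μ)`, window 3×3, mirror-padded moments, `v` estimated
  as the mean local variance unless given. Windows that are constant at
  floating precision pass the pixel through unchanged, so constant images
  and the zero-noise limit are exact identities. The frequency-domain form
  (`wiener_frequency`) implements the classical transfer function
  H*/(|H|² + S_η/S_f) with a flat noise spectrum S_η = vMN, signal spectrum
  estimated as max(|G|² − S_η, 10⁻¹²), and an optional blur OTF H (default:
  identity — the benchmark adds noise but no blur). The local form is the
  pipeline default because the frequency form needs spectra that are not
  available for a single observed image.
* **Wavelet shrinkage** (`wavelet_denoise`): `sym4`, 3 levels, symmetric
  boundary, decimated transform. Hard rule keeps coefficients with
  |w| ≥ λ; soft rule additionally shrinks survivors by λ. λ follows the
  Donoho–Johnstone universal rule σ̂√(2 ln n) with σ̂ = MAD/0.6745 estimated
  from the finest diagonal band of the image being filtered, shared across
  levels; a fixed λ is available for calibration (λ = 0 is the identity).
  The approximation band is never thresholded by default.

## Metrics and benchmark

MSE is computed on the byte scale, MSE = (1/MN) Σ (f − f̂)², and
PSNR = 10 log₁₀(255²/MSE) dB (+∞ sentinel at MSE = 0); under this
convention an MSE of 87 pairs with 28.74 dB. The harness adds noise once
per (image, variance, seed) cell and scores every method on the same noisy
realisation, so that row differences isolate the method effect. All six
assignments share one decomposition per cell — exact, since the solver is
deterministic. Reports include per-cell records, per-variance averages, and
a per-image "Max over assignments" row.

## Phantoms

Real reference MR images cannot be redistributed, so the test images are
synthetic phantoms with *known* layers: a cartoon layer of nested smoothed
ellipses (Shepp–Logan-like) and a texture layer of an oriented cosine
grating windowed by the outer ellipse (texture inside the brain-like
region; a global Hann-windowed variant exists). The clean phantom is the
clamped sum, and generation fails if clamping would destroy more than 5% of
the texture energy. Defaults: 256×256, 4 ellipses of intensity 0.12–0.28,
grating of amplitude 0.10 at 32 cycles/image (2 cycles per transform block,
hence sparse in the texture dictionary), edge softening σ = 1.5 px. Three
stock phantoms differing in ellipse count, grating frequency/orientation
and geometry seed stand in for the customary three test images. Everything
is seed-deterministic.

What the phantoms do *not* emulate: anatomical texture diversity, partial
volume effects, bias fields, and the dense multi-scale detail of real MR
anatomy. Consequences for interpreting results:

* Separation quality on phantoms (≈98–99% of each layer's energy captured
  by the right part) is an upper bound on what real anatomy would give.
* On these wavelet-sparse phantoms, *full-image* universal-threshold
  shrinkage is close to ideal, so standalone hard/soft thresholding can
  outperform the hybrid WHS at variances ≥ 0.03 — the opposite of the
  ordering reported on real MR images, where universal shrinkage
  over-smooths anatomy. The benchmark reports this ordering as measured
  rather than re-tuning per-part parameters to force it; the hybrid's
  improvement over the noisy input (≈3–5 dB mean PSNR gain) is robust
  across all phantoms, variances and seeds.

## Numerical choices and problem sizes

Noise is applied on the unit scale and clamped to [0, 1] (display-valid
images); decomposition parts are *not* clamped individually — only their sum
is an image. In-memory images are float64 throughout; quantisation to 8 bits
happens only at file write, avoiding double-quantisation bias in MSE.
Colour inputs are converted with Rec.601 luma weights; 16-bit inputs map
linearly to [0, 255].

The benchmark sweep runs on 128×128 phantoms (a decomposition costs ~1 s
there at the default 100 iterations), while separation quality is scored on
the 256×256 default phantom. Dictionary reconstruction is exact to ~1e-12
relative; additivity to machine epsilon; the local Wiener filter matches a
brute-force sliding-window oracle to 1e-12.

## Known limitations

* `lambda_min = 0` leaves only sub-λ_max/n content in the residual; for
  noisy inputs most noise is therefore absorbed into the cartoon and
  texture parts and handled by their filters. Classical MCA denoising stops
  the schedule at ~3σ instead; `lambda_min` is exposed in `McaConfig` for
  that use.
* Single 2-D slices only; no DICOM/NIfTI, no Rician noise, no curvelet or
  learned dictionaries, no total-variation regularisation of the cartoon.
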