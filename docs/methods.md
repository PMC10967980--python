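# Methods

## The problem

CT slices are acquired in Hounsfield units (HU), a calibrated attenuation
scale spanning roughly [−1024, 3071] (air ≈ −1000, water = 0, cortical bone
up to ≈ 3071). Segmentation models and most vision tooling consume 8-bit
gray images. A naive min-max conversion of a whole slice compresses the
few tens of HU that separate abdominal soft tissues (liver ≈ 50–70 HU,
other soft tissue ≈ 0–40 HU) into a handful of gray levels, and low-dose
acquisitions add noise on top. This package implements a dual-path
enhancement that (i) denoises in HU, (ii) enhances global contrast, (iii)
enhances the target-tissue window, and (iv) blends the two, producing
8-bit slices in which the target organ is both high-contrast and smooth.

## Pipeline

One HU slice `I` is processed as:

1. **Anisotropic diffusion** (Perona–Malik). Explicit Jacobi update
   `I ← I + λ Σ_dir c_dir ∇_dir I` over the four axial neighbors, with
   conduction `c = exp(−(∇/κ)²)` and replicate (Neumann) borders.
   Diffusion runs once, before the paths split, and operates in HU so κ
   has physical units.
2. **Global path**: min-max normalization to [0, 255] followed by global
   histogram equalization (`lut[k] = round(s_k · 255)` with the inclusive
   CDF `s_k = Σ_{j≤k} n_j / N`). All pixels participate — the path is
   deliberately global; equalization is defined on the 256-level image, so
   normalization precedes it.
3. **Local path**: window level/width mapping
   `y = (g/w)·x + (w/2 − c)·(g/w)` inside `[c − w/2, c + w/2]`, saturating
   to 0/255 outside; boundary points belong to the linear branch.
4. **Blend**: `round(α · local + (1−α) · global)` in 8-bit space, where
   both paths already live.

Four variants are exposed for ablation: `normalization` (plain min-max,
no diffusion — the baseline conversion), `histeq`, `window`, `proposed`
(the blend). No stage consumes randomness; outputs are bit-reproducible.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| κ (kappa) | 30 | HU | conventional Perona–Malik edge scale at CT noise magnitude: noise gradients (≈10–15 HU) are smoothed, tissue boundaries (≥100 HU) preserved |
| λ (lam) | 0.25 | — | largest step with guaranteed extremum principle (see below) |
| iterations | 15 | — | enough for noise plateaus on 128–512 px slices without visible flattening |
| window center / width | 60 / 200 | HU | a conventional liver display window; covers ≈ [−40, 160] HU |
| α (alpha) | 0.5 | — | symmetric blend; task-dependent by design, a first-class CLI flag |

All are CLI-configurable (`--kappa --lambda --iterations --window-center
--window-width --alpha`), with a `key=value` config file mirroring flags
(flags win).

## Numerical choices

* **Quantization rule.** Everywhere a real value becomes an 8-bit level —
  normalization, the equalization LUT, windowing, blending — the same rule
  applies: round half-up, clamp to [0, 255]. Rendered metric tables use
  decimal half-up at 4 places (`round4`), evaluated on the shortest decimal
  repr so printed-table ties (e.g. 0.98615) round the way tables print them.
* **λ ≤ 1/4 stability bound.** The update adds four fluxes with `c ≤ 1`;
  for λ ≤ 1/4 each output pixel is a convex combination of its 4-neighbor
  stencil, giving min/max preservation and exact total-intensity
  conservation (replicate borders make fluxes cancel pairwise).
* **λ = 1/4 is the oscillatory boundary.** In the linear limit (c → 1) the
  highest-frequency (checkerboard) Fourier mode has Jacobi amplification
  `1 − 8λc`, which is −1 at λ = 1/4: that mode flips sign each iteration
  and never decays, so *smoothing strength is not monotone in κ* at the
  default λ. For λ ≤ 1/8 every mode factor lies in [0, 1] and larger κ
  monotonically reduces total variation; the monotone-smoothing regression
  test therefore runs at λ = 0.125. The λ = 0.25 default is kept because
  the extremum principle (the property users rely on) holds there and the
  oscillating mode is irrelevant after the first few iterations on real
  noise.
* **Degenerate inputs.** A constant slice min-max normalizes to all zeros
  (any constant is equally uninformative); a constant image equalizes to
  all 255 (its single occupied level has CDF 1); empty-denominator metrics
  are total: 1.0 when both masks agree the relevant side is empty, 0.0
  when only one side is empty.
* **Equalization is not quite a bijection on uniform input.** With the
  inclusive CDF, the one-pixel-per-level image maps 256 inputs onto levels
  1..255; exactly one two-pixel collision (at 128) is forced by pigeonhole.
* **F1 in reduced form.** F1 is evaluated as `2tp/(2tp+fp+fn)` so the
  identities `f1 = dice = 2·iou/(1+iou)` hold exactly in floating point;
  tests cross-check against the `2PR/(P+R)` form to 1 ulp.

## Segmentation metrics and reporting

Eight per-case statistics (IoU, Dice, accuracy, precision, recall,
sensitivity, F1, specificity) from pixel confusion counts with
1 = foreground; per-report mean rows are arithmetic means at full
precision, rounded last. `compare` differences the *rounded* means — the
convention under which published benchmark deltas are computed — so its
output matches table arithmetic rather than full-precision arithmetic.

## The phantom

`make_phantom` renders a deterministic geometric slice — air background
(−1000 HU), elliptical soft-tissue body (20 HU) with a thin bone rim
(1200 HU), an elliptical liver (55 HU) containing two hypodense lesions
(25 HU) — plus seeded additive Gaussian noise whose standard deviation is
`sigma_full / sqrt(dose_fraction)` (photon statistics; half dose ⇒ ≈ +41%
noise, the commonly quoted ≈ 40%). Default full-dose sigma is 10 HU, a
typical abdominal CT noise level. Masks derive from geometry before
noise, so they are exact.

What the phantom does *not* emulate: real anatomy and texture, partial
volume at boundaries, beam hardening and streak artifacts, correlated
reconstruction noise, tumor heterogeneity. Tests passing on the phantom
show the pipeline's algebraic and ordering properties under controlled
contrast and noise; they do not certify performance on patient data.

The bundled `toy_segment` (fixed 8-bit band [150, 240] → largest
4-connected component → hole fill) exists only to close the loop from
enhancement to a measurable IoU. The band brackets where the default
liver window places liver parenchyma after blending (≈ 170) while
excluding other soft tissue (≈ 135) and the saturated rim (255). It is a
harness device; it would be useless on real CT.

## End-to-end regression

On half-dose phantoms (seeds 1–5), the toy segmenter on the `proposed`
output reaches liver IoU ≈ 0.93–0.94 versus ≈ 0.0 on the `normalization`
baseline, whose 4-level liver/tissue separation falls entirely outside
the band. The suite asserts the ordering (proposed > baseline), not the
absolute numbers.

A note on the contrast comparison between the blend and the global path:
on this phantom, global equalization *expands* the liver–tissue mean
separation more than the blend does, because nearly 40% of the histogram
mass (soft tissue) lies between air and liver, and the CDF stretch is
mass-driven — but it amplifies the noise inside both tissues by the same
factor. The quantity that predicts downstream separability is the
contrast-to-noise ratio (CNR, mean difference over pooled within-tissue
standard deviation), and by CNR the blend beats the global path on every
seed and dose tested (≈ 6.1 vs ≈ 4.7 at half dose). The regression test
asserts the CNR ordering.

## Known limitations

* 2-D only: slices are the unit of processing; no 3-D diffusion or
  multi-planar windowing.
* Single conduction function (exponential); the rational Perona–Malik
  variant is out of scope.
* Plain global equalization; no CLAHE.
* DICOM support covers single-frame CT series with uniform rescale tags;
  multi-frame DICOM, PAR/REC, ANALYZE, NRRD, MINC are out of scope.
* The blend weight that best serves a given downstream model is task- and
  dataset-dependent; 0.5 is a neutral default, not a tuned optimum.
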