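# ctenhance

Dual-path enhancement of CT slices for segmentation preprocessing, with a
segmentation-metrics reporter and a synthetic liver-CT phantom.

## Why

CT images live in Hounsfield units (HU), roughly [−1024, 3071], while
segmentation models consume 8-bit gray images. Converting a whole slice
with plain min-max normalization crushes the few tens of HU separating
abdominal soft tissues into a handful of gray levels — the liver and its
surroundings become nearly indistinguishable, and low-dose noise makes it
worse. `ctenhance` implements a preprocessing scheme that keeps both
global detail and target-tissue contrast:

1. **Denoise** the HU slice with Perona–Malik anisotropic diffusion
   (`I ← I + λ Σ c_dir ∇_dir I`, `c = exp(−(∇/κ)²)`) — smooths noise,
   preserves edges;
2. **Global path** — min-max normalize to 8-bit, then global histogram
   equalization through the image CDF (`lut[k] = round(s_k · 255)`);
3. **Local path** — HU window level/width mapping (default liver window
   c = 60 HU, w = 200 HU): linear inside `[c − w/2, c + w/2]`, saturated
   outside;
4. **Blend** — `round(α·local + (1−α)·global)`, α = 0.5 by default.

It also provides the eight standard overlap metrics for binary masks
(IoU, Dice, accuracy, precision, recall, sensitivity, F1, specificity)
with per-case rows, mean-row aggregation and rounded-mean deltas, plus a
seeded CT phantom (air / soft tissue / bone rim / liver / lesions, noise
∝ 1/√dose) so the whole pipeline runs without patient data.

## Worked example

Score the bundled toy threshold segmenter on blended enhancements of
three half-dose phantoms:

```python
from ctenhance.phantom import PhantomSpec, make_phantom, toy_segment
from ctenhance.pipeline import PipelineConfig, enhance
from ctenhance.seg_metrics import aggregate, confusion_counts, metrics_row

rows = []
for seed in (1, 2, 3):
    case = make_phantom(PhantomSpec(dose_fraction=0.5, seed=seed))
    out = enhance(case.image, PipelineConfig(variant="proposed"))
    pred = toy_segment(out)
    rows.append(metrics_row(confusion_counts(pred, case.liver_mask), case_id=f"seed{seed}"))

report = aggregate(rows)
for r in (*report.rows, report.mean_row):
    print(f"{r.case_id:>6}  IoU {r.iou:.4f}  Dice {r.dice:.4f}  "
          f"sens {r.sensitivity:.4f}  spec {r.specificity:.4f}")
```

prints

```
 seed1  IoU 0.9386  Dice 0.9683  sens 0.9995  spec 0.9914
 seed2  IoU 0.9400  Dice 0.9691  sens 1.0000  spec 0.9915
 seed3  IoU 0.9470  Dice 0.9728  sens 1.0000  spec 0.9925
  mean  IoU 0.9419  Dice 0.9701  sens 0.9998  spec 0.9918
```

IoU is intersection-over-union against the phantom's exact liver mask;
the mean row is the per-metric arithmetic mean. Running the same
segmenter on the plain min-max baseline (`variant="normalization"`)
yields IoU ≈ 0 on these slices — the liver/tissue separation survives the
blend but not the naive conversion.

The same flow from the shell:

```sh
ctenhance phantom --dose 0.5 --seed 1 --out ph
ctenhance enhance --input ph/image.nii.gz --output enhanced --variant proposed
ctenhance evaluate --pred pred_masks/ --truth truth_masks/ --out report.csv
ctenhance compare report_a.csv report_b.csv
```

`enhance` reads DICOM series directories or NIfTI volumes, writes one PNG
per slice plus a JSON run manifest, and exposes every pipeline parameter
(`--kappa --lambda --iterations --window-center --window-width --alpha
--variant`).

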