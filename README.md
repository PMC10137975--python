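# btrkit — brain-MRI tumor recognition on synthetic phantoms

`btrkit` implements a classical (non-deep-learning) pipeline for detecting
brain tumors in single 2-D MRI slices, aimed at researchers studying
texture-based lesion detection and at anyone who needs a fully seeded,
download-free testbed for such pipelines. Real T1/T2-weighted slices can
be fed in as PNG/JPEG (or DICOM), but every stage is exercised end to end
on a built-in **phantom generator** that renders elliptical "head" slices
with textured tissue, optional hyperintense tumor disks, exact ground-truth
masks, and Gaussian acquisition noise — so every claim the package makes is
scored against known truth.

## The method

1. **Contrast stretch** — the occupied intensity range is mapped linearly
   onto [0, 1] (percentile-robust min–max stretch), preserving gray-level
   ordering.
2. **Anisotropic diffusion denoising** (Perona–Malik). The image evolves by
   `dI/dt = div(c · ∇I)` discretized explicitly on the 4-neighborhood:

   ```
   I[i,j] ← I[i,j] + dt · Σ_{k∈N4} c_edge · (I[k] − I[i,j]),   dt = 1/4
   ```

   with conduction `g(s) = exp(−(s/κ)²)` (or `1/(1+(s/κ)²)`), and the
   per-edge coefficient averaged from the two endpoint pixels. Edges
   (gradient ≫ κ) conduct weakly and are preserved; noise conducts freely
   and is smoothed. Iteration stops when the relative change
   `IE = ‖Iₙ − Iₙ₋₁‖_F / ‖Iₙ‖_F` reaches the tolerance.
3. **Texture features** — an 11-element vector: mean, SD, histogram
   entropy, skewness, kurtosis (first-order); energy, contrast, inverse
   difference moment, directional moment, correlation from the gray-level
   co-occurrence matrix (GLCM, 8 levels, 4 symmetric unit offsets,
   averaged); plus coarseness.
4. **Tumor localization** — Otsu brightness threshold restricted to the
   (eroded) head region, morphological opening/closing with a disk element,
   largest connected component, contrast gates, bounding box + overlay.
5. **Classification** — Gaussian-kernel (RBF) soft-margin SVM on
   standardized features, normal (0) vs abnormal (1), with confusion-matrix
   evaluation.
6. **Quality metrics** — MSE, PSNR, window-mean SSIM, and Dice overlap.

## Worked example

```bash
python examples/denoise_phantom.py
```

```
diffusion stopped after 12 sweeps (last iteration error 0.0194)
MSE  vs clean: noisy 0.00187  ->  filtered 0.00040
PSNR vs clean: noisy 27.29 dB  ->  filtered 34.02 dB
SSIM vs clean: noisy 0.522  ->  filtered 0.903
```

The filter stops by its iteration-error rule after 12 sweeps and cuts the
mean-squared error against the noise-free rendering by ~4.7×, raising PSNR
by ~6.7 dB and SSIM from 0.52 to 0.90 — noise removed, anatomy kept. The
other scripts in `examples/` walk through feature extraction
(`texture_features.py`), localization (`localize_tumor.py`, Dice 0.917
against the ground-truth disk), classification (`classify_cohort.py`), and
the one-call configured pipeline (`run_pipeline_report.py`).

The same stages are available from the shell:

```bash
btrkit phantom --n-abnormal 10 --n-normal 10 --seed 0 --out-dir cohort/
btrkit denoise cohort/phantom_0000.png denoised.png
btrkit segment denoised.png --out mask.png --report seg.json
btrkit run config.yaml --report report.json
```

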