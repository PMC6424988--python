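# bonespect

Quantitative bone SPECT with **emission-based segmented attenuation
correction (B-SAC)** — a complete, simulation-backed pipeline for asking:
*how well can SUVs be measured on a dedicated SPECT system that has no CT?*

Attenuation correction (AC) normally needs a co-registered CT converted to a
μ-map. B-SAC instead derives the μ-map from the bone-SPECT emission data
itself: a preliminary reconstruction is thresholded, relative to the mean
count level *L* in a 60 mm spherical lung VOI, into three tissue classes

| class | rule | substituted CT number |
|---|---|---|
| bone (A) | value ≥ 5 *L* | 300 HU (variant N) or 600 HU (variant M) |
| soft tissue (B) | *L* ≤ value < 5 *L* | 50 HU |
| air (C) | value < *L* | −1000 HU |

and the resulting "virtual CT" is converted voxel-for-voxel to attenuation
coefficients. The package implements everything needed to evaluate this
method against CT-based AC on synthetic ground truth:

- **phantoms** — seeded digital thorax phantoms (body, lungs, vertebral
  column, focal bone lesions) and the 160 × 150 mm calibration cylinder,
  with truth masks and lesion tables;
- **projector** — attenuated parallel-beam forward model (60 views/360°,
  12 s/view, 141 keV ± 10 % photopeak, 120 keV ± 5 % scatter window) with
  distance-dependent detector blur, emulated scatter and Poisson noise, and
  an exact adjoint;
- **recon** — OSEM (10 it × 10 ss, 3 mm post-filter; segmentation preset
  5 it × 10 ss, 4 mm) with optional attenuation modelling and resolution
  recovery, dual-energy-window scatter subtraction, and first-order Chang
  uniform AC (μ₀ = 0.11 cm⁻¹) — realizing the six study conditions CTAC,
  B-SAC_N, B-SAC_M, UAC, AC(−)SC(+)RR(+), and NC;
- **quantify** — calibration factor from the cylinder (CF, Bq/cps), the SUV
  equation `SUV = CF · density · (1/T) · W/A`, SUVpeak (1-cc sphere), MTV at
  50/55/60 % of SUVmax, and total bone uptake `TBU = Σ MTV · SUVmean`;
- **stats** — Pearson correlation and Bland-Altman agreement (mean
  difference, 1.96·SD limits, proportional-bias slope) of every condition
  against the CT-based gold standard.

## A worked example

```python
from bonespect.study import run_study

result = run_study(seed=1, n_phantoms=5)   # ~20 lesions, 6 conditions
for a in result.agreements:
    print(f"{a.test:9s} r={a.pearson_r:.3f}  mean diff {a.mean_diff:+.2f}")
```

prints (differences are test − CTAC, on SUVpeak; CTAC lesion mean ≈ 16):

```
AC_MINUS  r=0.964  mean diff -2.86
BSAC_M    r=0.948  mean diff +4.14
BSAC_N    r=0.948  mean diff +3.28
NC        r=0.945  mean diff -7.92
UAC       r=0.974  mean diff +0.36
```

Reading it: reconstructions without attenuation correction underestimate
lesion SUVs (NC worst, since it also lacks scatter and resolution
compensation); the emission-segmented maps track the CT-based gold standard
tightly (r ≈ 0.95) but read high — they inherit the uniform-AC calibration
factor, whose cylinder measurement under-recovers at μ₀ = 0.11 cm⁻¹. The
same run reports the per-patient total-bone-uptake ratio
`result.tbu["ratio_BSAC_N"]` ≈ 1.2, the simulation analogue of the
systematic overestimation of tumour burden by B-SAC at equal MTV threshold.

The `examples/` scripts walk the same chain one capability at a time
(phantom + projection, attenuation-map derivation, six-condition SUVs,
cohort agreement). A thin CLI mirrors the stages:

```bash
bonespect simulate --out run/ --seed 1
bonespect attenmap --sino run/sinogram --variant N --lung-center=-69,9,51 --out run/mu.nii.gz
bonespect pipeline --seed 1 --n-phantoms 2 --out run/study/
```

## Documentation

`docs/methods.md` describes the physical model, the simulated study
conditions and their rationale, numerical choices, and known limitations.
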