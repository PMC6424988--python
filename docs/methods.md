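# Methods

## The problem

Standardized uptake values (SUV) in bone SPECT require attenuation
correction (AC), which normally comes from a co-acquired CT. B-SAC
(bone-SPECT-based segmented attenuation correction) replaces the CT with a
three-class segmentation of the emission image itself. This package
implements the full measurement chain — digital phantoms, an attenuated
projector, OSEM reconstruction under six correction conditions, the
emission-derived attenuation map, SUV/MTV/TBU quantitation, and agreement
statistics — so the method can be evaluated against CT-based AC on known
ground truth.

## System model

**Geometry.** Parallel-beam, step-and-shoot: 60 views over 360° at
12 s/view, detector bins equal to the in-plane voxel grid (no detector
resampling), photopeak window 141 keV ± 10 % (28.2 keV wide), scatter
window 120 keV ± 5 % (12 keV wide). Detector radius 250 mm.

**Rotation operator.** Projection is rotation-based: per view a sparse
bilinear operator rotates the volume so the detector lies along one grid
axis. Two flavours of the operator are used deliberately:

- for *emission* (counts), the gather matrix is column-normalized so every
  in-field voxel contributes exactly its content to each view — emission is
  conserved per view, and the stored sparse transpose is the projector's
  exact adjoint (OSEM's backprojector);
- for *value fields* (μ-maps, body masks), plain bilinear interpolation is
  used, because column normalization is a mass redistribution that distorts
  pointwise values (at 45° it mis-scales a mask centre by ~25 %).

**Attenuation.** Each voxel's contribution is weighted by
`exp(-Σ μ·Δl)` over the voxels strictly between it and the detector in the
rotated frame (midpoint-rule line integral; Δl = voxel pitch). CT numbers
convert to μ at 140 keV by a piecewise-linear map anchored at air
(−1000 HU → 0) and water (0 HU → μ_w = 0.151 cm⁻¹), with the slope above
water reduced by a bone factor 0.5 — bone attenuates less per HU at SPECT
energies than the water scale extrapolates. Both μ_w and the bone factor
are configuration values; no conversion is prescribed by the clinical
workflow being modelled, so the map is the package's own choice.

**Detector response.** The collimator PSF is a Gaussian in the detector
plane — both bin and axial directions, since a collimator response is
isotropic on the detector face — with FWHM(d) = 3 mm + 0.02·d at distance
d. The same model serves as the resolution-recovery (RR) operator inside
reconstruction, keeping system and model matched in the way vendors match
theirs.

**Scatter.** The sub-window sinogram is a wide (60 mm FWHM) Gaussian blur
of the primary counts scaled to a scatter fraction of 0.3 — typical for
Tc-99m photopeak imaging — renormalized so sub-window totals are exactly
the stated fraction of the primary. The same field contaminates the
photopeak, so dual-energy-window (DEW) correction has a real component to
remove: `corrected = max(0, main − k·(W_main/W_sub)·sub)` with the classic
multiplier k = 0.5. With these defaults DEW slightly over-subtracts
(k·W_main/W_sub ≈ 1.18), a realistic imperfection that the per-condition
calibration factors largely absorb.

**Counting statistics.** Expected counts are scaled by a system
sensitivity; the study presets use 10⁻⁴ cps/Bq, giving a few million
photopeak counts per acquisition — clinical scale for bone SPECT. Each
bin is an independent Poisson draw, seeded.

**Avoiding the inverse crime.** Study simulations rasterize the analytic
phantom and compute attenuation and blur on a grid twice as fine as the
reconstruction grid, then sum 2×2 detector bins back to the acquisition
matrix. The reconstruction therefore never inverts the exact
discretization that generated the data; without this, OSEM + RR
deconvolves its own forward model and produces exaggerated single-voxel
edge overshoot that dominates small-volume statistics such as SUVpeak.

## Reconstruction conditions

OSEM with 10 subsets of 6 views each (round-robin by angle, fixed order),
initialized uniform inside the field-of-view circle; voxels with zero
subset sensitivity stay zero. The quantitative preset runs 10 iterations
with a 3 mm Gaussian post-filter; the segmentation-input preset 5
iterations with 4 mm. The post-filter uses a periodic boundary so the
volume total is preserved exactly.

| label | μ source | scatter corr. | resolution recovery |
|---|---|---|---|
| CTAC | CT-derived μ-map | on | on |
| BSAC_N | virtual CT, bone = 300 HU | on | on |
| BSAC_M | virtual CT, bone = 600 HU | on | on |
| UAC | Chang, μ₀ = 0.11 cm⁻¹ | on | on |
| AC_MINUS | none | on | on |
| NC | none | off | off |

**Chang correction** is first-order and post-hoc: every voxel inside the
body contour is multiplied by `M / Σᵢ exp(−μ₀·lᵢ)`, where lᵢ is the path
length to the contour along view angle i (computed on the rotated mask
with a half-voxel self term). The body contour is always data-derived:
the uncorrected-style reconstruction is thresholded — at the lung
reference L for patients, at 5 % of maximum for the lung-less calibration
cylinder — and holes (the lungs) are filled slice by slice. The same rule
serves both arms so patient and calibration measurements are consistent.

**Segmentation-input reconstruction** runs without scatter correction.
This is a deliberate choice for an open protocol question: the lung
reference L sits at the scatter/background shoulder, and the
lung-relative thresholds (soft tissue in [L, 5L)) only partition tissues
the way the method assumes when that shoulder is present. With scatter
fully subtracted the lung level collapses and soft tissue crosses the 5L
bone threshold. The preset is configurable.

## B-SAC

The chain is: segmentation-input OSEM → mean count L in a 60 mm spherical
lung VOI (auto-placed in synthetic mode at the deepest point of the upper
third of the right lung mask; in general use the centre is a required
input) → exact thresholds bone ≥ 5L, soft [L, 5L), air < L, compared on
raw floating-point voxel values with no epsilon and no morphological
cleanup (an optional median filter exists but is off by default — the
canonical method has no contouring step and its noise susceptibility is a
property worth preserving) → substitution 300/600, 50, −1000 HU → the
same HU→μ map as CT, on the same grid (no resampling). Hot extraosseous
structures would be classified bone by construction; the phantom module
can place a bladder primitive to exercise that failure mode.

## Quantitation

The calibration factor is measured on a uniform 160 mm × 150 mm cylinder
(~25 MBq of Tc-99m solution, ≈ 8.3 kBq/mL): five circular ROIs (30 mm
radius; central slice and ± 1, ± 2 cm) give
`CF = true concentration / mean(count density / scan duration)` in Bq/cps.
Scan duration is the total acquisition time contributing to a voxel
(60 × 12 s under parallel geometry); the choice of total versus per-view
time is absorbed by CF either way but is fixed and recorded. CFs are
measured under CTAC, UAC, AC(−) and NC; the B-SAC conditions use the UAC
factor, because the calibration solution contains no bone or air
compartment for a segmented map to represent.

SUV is `CF · density · (1/duration) · weight / injected`, dimensionless,
with no decay term by default (an optional flag decays the injected
activity over the injection-to-scan interval with the 6.0067 h Tc-99m
half-life). SUVpeak is the mean over voxels whose centres fall in a 1-cc
sphere (radius (3000/4π)^{1/3} = 6.2035 mm) centred on the hottest voxel;
at a volume edge only in-bounds voxels enter. MTV at threshold f is the
26-connected component, containing the hottest voxel, of voxels with
SUV ≥ f·SUVmax inside the lesion's search region (inclusive ≥; ties at
the maximum break to the lowest linear index). TBU is Σ MTV·SUVmean over
lesions, in grams, reported at 50/55/60 %.

The search region is a ball around a supplied seed (truth lesion centroid
in synthetic mode). The cohort study uses an 18 mm radius — small enough
that, given the cohort's enforced lesion spacing, no region can capture a
neighbouring lesion's voxels; the reference recovery phantom, whose
lesions are farther apart, uses 25 mm.

## The simulated study

The phantom generator defines the study conditions. The reference thorax
is an elliptical body (320 × 220 mm) with soft tissue at SUV 0.8 / 40 HU,
two lung ellipsoids at SUV 0.08 / −800 HU, a 40 mm-wide posterior
vertebral column at SUV 4 / 300 HU, and spherical lesions (SUV 8–25,
600 HU, diameters 18–29 mm in the cohort; the fixed reference phantom
includes one 32 mm lesion). Lesions sit on the column at stratified axial
stations with jitter, fully inside bone and separated enough for
independent delineation. Grids: 128×128×40 at 4.42 mm (clinical preset)
or 64×64×32 at 6 mm (fast preset, used by tests and the acceptance
script for desk-scale runtimes).

What the generator does *not* emulate: anatomical realism (no ribs by
default, no organs with tracer uptake, no bladder unless requested),
respiratory motion, septal penetration, energy-spectrum physics beyond
the two-window abstraction, detector non-uniformity, and patient-to-
patient anatomical variation (cohort phantoms differ only in lesions and
noise). Passing tests therefore demonstrate the internal consistency and
qualitative behaviour of the correction chain, not clinical accuracy.

A full study run: cylinder → CFs; per patient: sinogram → B-SAC maps →
six reconstructions → SUV maps → lesion metrics → TBU; then Pearson and
Bland-Altman agreement (differences test − CTAC, stated in every report)
on SUVpeak, and per-patient TBU ratios.

## Observed behaviour and its mechanism

On the default study conditions, reconstructions without AC underestimate
lesion SUVs (NC most strongly — it also lacks scatter and resolution
compensation), while both B-SAC variants correlate tightly with CTAC but
overestimate, B-SAC_M more than B-SAC_N, and the TBU ratio sits near 1.2.
The overestimation is structural: B-SAC reconstructions themselves track
CTAC closely (the μ-map is nearly right), but the paired calibration
factor is measured under uniform Chang AC at μ₀ = 0.11 cm⁻¹ on a water
cylinder whose true μ is 0.151 cm⁻¹, so the cylinder density is
under-recovered and the CF — and with it every B-SAC SUV — is inflated by
that ratio. On clinical systems the UAC/CTAC factor ratio depends on
vendor normalization internals that a physics-level simulation does not
contain, so the *relative ranking* of B-SAC and UAC biases is the one
aspect of the clinical comparison this simulation does not reproduce;
the signs, the correlation strengths, and the ordering of the
uncorrected conditions are reproduced.

## Numerical choices

- Exact adjoint by construction (stored sparse transpose); OSEM ratio
  where the forward projection is 0 is set to 0; subset sensitivities
  below 1e−12 freeze the voxel at 0.
- All thresholds (segmentation, MTV) are exact ≥/< comparisons on
  floating-point values; no epsilon.
- Gaussian kernels are truncated at 4σ; blur matrices are symmetric, so
  the PSF is self-adjoint.
- Bilinear interpolation can produce small negative values only through
  the attenuation tail sum; tails are clamped at 0 before exponentiation.
- Determinism: every stochastic element (lesion draws, Poisson noise)
  derives from a single integer seed through `numpy.random.default_rng`;
  identical configuration and seed reproduce bit-identical outputs.

## Known limitations

- The rotation-based projector is a discretization, exact only against
  its own interpolation model; a ray-driven oracle coincides with it only
  at axis-aligned angles.
- First-order post-hoc Chang undercorrects off-centre structures; this is
  a property of the method as implemented, prominent for the posterior
  spine.
- SUVpeak on a 6 mm grid averages ~7 voxels; it remains the noisiest of
  the reported metrics.
- The 64×64 fast preset trades partial-volume severity for runtime; the
  clinical preset reduces discretization effects at ~5× the cost.
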