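"""Derive an attenuation map from the emission data alone (B-SAC).

Reconstructs a segmentation-input volume from a simulated bone-SPECT
acquisition, measures the lung reference level L in a 60 mm spherical
VOI, segments the volume into bone (>= 5L) / soft tissue ([L, 5L)) /
air (< L), substitutes fixed CT numbers, and converts to attenuation
coefficients -- no CT involved.
"""

import numpy as np

from bonespect import default_thorax_spec, make_thorax_phantom
from bonespect.bsac import auto_lung_center, bsac_attenuation_map
from bonespect.study import simulate_patient_sinogram, study_geometry

truth = make_thorax_phantom(default_thorax_spec())
sino = simulate_patient_sinogram(truth, study_geometry(), seed=7)

lung_center = auto_lung_center(truth.masks["lung"], truth.ct)
mu, prov = bsac_attenuation_map(sino, lung_center, variant="N")

print(f"lung VOI centre (mm): {tuple(round(c, 1) for c in lung_center)}")
print(f"lung reference L = {prov['lung'].value:.3f} counts/cc "
      f"({prov['lung'].n_voxels} voxels)")
seg = prov["segmentation"]
print("class fractions: bone %.3f  soft %.3f  air %.3f"
      % (seg.fraction(2), seg.fraction(1), seg.fraction(0)))
print("virtual-CT values:", sorted(np.unique(prov['virtual_ct'].hu.data)))
print("mu-map values (1/cm):", [round(v, 4) for v in np.unique(mu.data)])

bone_sens = (seg.labels[truth.bone_mask] == 2).mean()
print(f"fraction of true bone labelled bone: {bone_sens:.3f}")
# The three mu values correspond to air, soft tissue (50 HU) and the
# normal-vertebra average (300 HU); variant M would use 600 HU instead.
# On a noiseless acquisition the bone sensitivity exceeds 0.9; Poisson
# noise erodes the thin edge of the vertebral column (the segmentation
# has deliberately no contouring or cleanup step).
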