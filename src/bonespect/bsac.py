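"""Emission-based segmented attenuation correction (B-SAC).

The method derives an attenuation map from the bone-SPECT emission data
itself, with no CT: a segmentation-input reconstruction is thresholded
relative to the mean count level L in a 60 mm spherical lung VOI into
three classes -- bone (>= 5L), soft tissue ([L, 5L)), and air (< L) --
whose voxels are then replaced by fixed CT numbers (300 or 600 HU for
bone, 50 HU for soft tissue, -1000 HU for air).  The resulting "virtual
CT" is converted to attenuation coefficients voxel-for-voxel (same grid,
no resampling) and used exactly like a CT-based mu-map.

The two bone replacement values correspond to population-average CT
numbers of normal vertebrae (variant N, 300 HU) and of metastatic bone
(variant M, 600 HU).

The segmentation is deliberately a pure threshold rule: no contouring or
morphological cleanup is applied (an optional median filter is exposed but
off by default), and hot extraosseous structures are knowingly classified
as bone -- both properties of the method itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.ndimage import distance_transform_edt, median_filter

from .grid import VoxelGrid, sphere_mask
from .projector import RotationSet, Sinogram, hu_to_mu
from .recon import ReconCondition, gaussian_postfilter, osem, dew_scatter_correct

LUNG_VOI_DIAMETER_MM = 60.0
BONE_HU = {"N": 300.0, "M": 600.0}
SOFT_HU = 50.0
AIR_HU = -1000.0

CLASS_AIR, CLASS_SOFT, CLASS_BONE = 0, 1, 2


class DegenerateReferenceError(ValueError):
    """Raised when the lung reference level is non-positive."""


@dataclass(frozen=True)
class LungReference:
    """Mean count level inside the lung VOI, used as the threshold unit L."""

    center_mm: tuple[float, float, float]
    diameter_mm: float
    value: float          # L, in the units of the measured volume
    n_voxels: int


@dataclass
class SegmentationMap:
    """Per-voxel three-class labels (0 air, 1 soft tissue, 2 bone)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    lung: LungReference

    def fraction(self, cls: int) -> float:
        return float((self.labels == cls).mean())


@dataclass
class VirtualCT:
    """HU-substituted twin of the emission volume (value set {bone, 50, -1000})."""

    hu: VoxelGrid
    bone_hu: float
    variant: str


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def measure_lung_count(volume: VoxelGrid,
                       center_mm: tuple[float, float, float],
                       diameter_mm: float = LUNG_VOI_DIAMETER_MM) -> LungReference:
    """Mean voxel value in a spherical VOI (voxel-centre membership).

    The sphere must lie entirely inside the volume; a clipped sphere or a
    non-positive mean is an error because every threshold is a multiple
    of this value.
    """
    r = diameter_mm / 2.0
    for n, s, c in zip(volume.shape, volume.spacing, center_mm):
        half = n * s / 2.0
        if c - r < -half or c + r > half:
            raise ValueError(
                f"lung VOI (centre {center_mm} mm, diameter {diameter_mm} mm) "
                "extends outside the volume")
    member = sphere_mask(volume, center_mm, r)
    n_vox = int(member.sum())
    value = float(volume.data[member].mean())
    if value <= 0:
        raise DegenerateReferenceError(
            f"lung reference L={value:g} is not positive; thresholds degenerate")
    return LungReference(tuple(center_mm), diameter_mm, value, n_vox)


def auto_lung_center(lung_mask: np.ndarray, grid: VoxelGrid,
                     diameter_mm: float = LUNG_VOI_DIAMETER_MM,
                     ) -> tuple[float, float, float]:
    """Place the lung VOI automatically from a truth lung mask.

    Mirrors the manual "right upper lung" placement: restricted to the
    right-lung half (negative x) and the upper third of the lung's axial
    extent, the centre is the voxel deepest inside the lung (maximum
    distance to the lung boundary), so the sphere stays as clear of soft
    tissue as the anatomy allows.
    """
    if not lung_mask.any():
        raise ValueError("empty lung mask")
    zs = np.flatnonzero(lung_mask.any(axis=(0, 1)))
    z_top = zs[int(2 * len(zs) / 3):]      # upper third of axial stations
    sub = np.zeros_like(lung_mask)
    sub[:, :, z_top] = lung_mask[:, :, z_top]
    sub[sub.shape[0] // 2:, :, :] = False  # right lung = negative-x half
    if not sub.any():
        sub = lung_mask
    dist = distance_transform_edt(sub, sampling=grid.spacing)
    idx = np.unravel_index(int(np.argmax(dist)), sub.shape)
    xs, ys, zsw = grid.world_coords()
    return (float(xs[idx[0]]), float(ys[idx[1]]), float(zsw[idx[2]]))


def segment_three_classes(volume: VoxelGrid, lung: LungReference | float,
                          median_size: int = 0) -> SegmentationMap:
    """Threshold the emission volume into bone / soft tissue / air.

    Exact rule (no epsilon): bone iff value >= 5L; soft iff L <= value < 5L;
    air iff value < L.  ``median_size`` > 1 applies an optional median
    filter to the label map (off by default; the canonical method has no
    cleanup step).
    """
    L = lung.value if isinstance(lung, LungReference) else float(lung)
    if L <= 0:
        raise DegenerateReferenceError("lung reference must be positive")
    data = volume.data
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite voxels")
    labels = np.full(volume.shape, CLASS_AIR, dtype=np.uint8)
    labels[data >= L] = CLASS_SOFT
    labels[data >= 5.0 * L] = CLASS_BONE
    if median_size > 1:
        labels = median_filter(labels, size=median_size)
    ref = lung if isinstance(lung, LungReference) else \
        LungReference((np.nan,) * 3, np.nan, L, 0)
    return SegmentationMap(labels, volume.spacing, ref)


def build_virtual_ct(seg: SegmentationMap, variant: str = "N") -> VirtualCT:
    """Substitute class labels with fixed CT numbers.

    Bone -> 300 HU (variant N) or 600 HU (variant M); soft tissue -> 50 HU;
    air -> -1000 HU.
    """
    if variant not in BONE_HU:
        raise ValueError(f"unknown variant {variant!r}; expected 'N' or 'M'")
    bone = BONE_HU[variant]
    hu = np.full(seg.labels.shape, AIR_HU, dtype=float)
    hu[seg.labels == CLASS_SOFT] = SOFT_HU
    hu[seg.labels == CLASS_BONE] = bone
    grid = VoxelGrid(hu, seg.spacing, "hu",
                     {"bsac_variant": variant, "bone_hu": bone,
                      "lung_reference": seg.lung.value})
    return VirtualCT(grid, bone, variant)


def bsac_attenuation_map(sino: Sinogram,
                         lung_center_mm: tuple[float, float, float],
                         variant: str = "N",
                         mu_water_cm1: float = 0.151,
                         bone_slope: float = 0.5,
                         rotations: RotationSet | None = None,
                         seg_condition: ReconCondition | None = None,
                         ) -> tuple[VoxelGrid, dict[str, Any]]:
    """Full emission-to-mu-map chain.

    Segmentation-input OSEM (5 it x 10 ss, 4 mm filter) -> lung reference L
    -> three-class segmentation -> virtual CT -> attenuation coefficients.
    Returns the mu-map and a provenance dict with every intermediate.
    """
    cond = seg_condition or ReconCondition.preset("SEG")
    work = dew_scatter_correct(sino) if cond.sc else sino
    vol = osem(work, mu=None, rr=cond.rr, iterations=cond.iterations,
               subsets=cond.subsets, rotations=rotations)
    vol = gaussian_postfilter(vol, cond.postfilter_fwhm_mm)
    lung = measure_lung_count(vol, lung_center_mm)
    seg = segment_three_classes(vol, lung)
    vct = build_virtual_ct(seg, variant)
    mu = hu_to_mu(vct.hu, mu_water_cm1=mu_water_cm1, bone_slope=bone_slope)
    mu.meta.update(bsac_variant=variant, lung_reference=lung.value)
    provenance = {
        "seg_recon": vol, "lung": lung, "segmentation": seg,
        "virtual_ct": vct, "condition": cond,
    }
    return mu, provenance
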