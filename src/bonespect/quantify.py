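"""SUV quantitation: calibration factor, SUV maps, lesion metrics, TBU.

The calibration factor (CF, Bq/cps) converts reconstructed count density
into activity concentration.  It is measured on a uniform cylinder by

    CF = true concentration / mean(count density / scan duration)

over five circular ROIs (central slice and slices +/-1 and +/-2 cm).  SUV
is then

    SUV = CF x count density x (1 / scan duration) x body weight / injected activity

with scan duration the total acquisition time contributing to a voxel
(n_views x per-view time under parallel geometry).  The B-SAC conditions
use the CF measured under UAC because the calibration solution contains no
attenuating medium that a segmented map could represent.

Lesion metrics: SUVmax over a search region, SUVpeak (mean in a 1-cc
sphere centred on the hottest voxel), and MTV as the 26-connected
component of supra-threshold voxels (>= 50/55/60 % of SUVmax) containing
the hottest voxel.  Total bone uptake is TBU = sum over lesions of
MTV x SUVmean (grams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid, sphere_mask

#: radius of the 1-cc SUVpeak sphere: (3 * 1000 mm^3 / 4 pi)^(1/3)
SUVPEAK_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

MTV_THRESHOLDS = (0.50, 0.55, 0.60)

TC99M_HALF_LIFE_H = 6.0067


class PairingError(ValueError):
    """Raised when a lookup or pairing cannot be satisfied."""


@dataclass
class AcquisitionMeta:
    """Everything the SUV equation needs about the acquisition."""

    injected_bq: float
    body_weight_g: float
    duration_s: float
    interval_s: float = 0.0            # injection-to-scan, informational
    true_conc_bq_ml: float | None = None

    def __post_init__(self) -> None:
        if self.injected_bq <= 0 or self.body_weight_g <= 0 or self.duration_s <= 0:
            raise ValueError("injected activity, body weight and duration must be > 0")

    def decay_corrected_activity(self) -> float:
        """Injected activity decayed over the injection-to-scan interval."""
        lam = np.log(2.0) / (TC99M_HALF_LIFE_H * 3600.0)
        return self.injected_bq * np.exp(-lam * self.interval_s)


@dataclass(frozen=True)
class CalibrationFactor:
    value_bq_per_cps: float
    measured_under: str
    applies_to: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.value_bq_per_cps <= 0:
            raise ValueError("calibration factor must be positive")


#: clinical reference magnitudes (Bq/cps) from a vendor SPECT/CT system --
#: documentation only, not used in any computation
CLINICAL_CF_REFERENCE = {"CTAC": 4148.7, "UAC": 3098.1,
                         "AC_MINUS": 10_299.3, "NC": 32_667.6}


@dataclass
class LesionQuant:
    """Per-lesion metrics for one reconstruction condition."""

    lesion_id: int
    condition: str
    suv_max: float
    suv_peak: float
    max_voxel: tuple[int, int, int]
    # per MTV threshold fraction: (mtv_cc, suv_mean)
    mtv_cc: dict[float, float] = field(default_factory=dict)
    suv_mean: dict[float, float] = field(default_factory=dict)
    members: dict[float, np.ndarray] = field(default_factory=dict)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def compute_cf(recon_cylinder: VoxelGrid, meta: AcquisitionMeta,
               roi_radius_mm: float = 30.0,
               slice_offsets_cm: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0),
               condition: str = "",
               applies_to: tuple[str, ...] = ()) -> CalibrationFactor:
    """Calibration factor from a reconstructed uniform cylinder.

    Circular ROIs are centred in-plane on the phantom axis at the central
    slice and at the given axial offsets; CF is the true concentration
    divided by the mean ROI count density per scan duration.
    """
    if meta.true_conc_bq_ml is None:
        raise ValueError("meta must carry the phantom's true concentration")
    nx, ny, nz = recon_cylinder.shape
    sx, _, sz = recon_cylinder.spacing
    xs, ys, _ = recon_cylinder.world_coords()
    roi2d = (xs[:, None] ** 2 + ys[None, :] ** 2) <= roi_radius_mm ** 2

    densities = []
    for off_cm in slice_offsets_cm:
        z_idx = int(round(off_cm * 10.0 / sz + (nz - 1) / 2.0))
        if not 0 <= z_idx < nz:
            raise ValueError(f"slice offset {off_cm} cm falls outside the volume")
        densities.append(float(recon_cylinder.data[:, :, z_idx][roi2d].mean()))
    mean_rate = np.mean(densities) / meta.duration_s  # cps per cc
    cf = meta.true_conc_bq_ml / mean_rate
    return CalibrationFactor(float(cf), condition, tuple(applies_to) or (condition,))


def cf_for_condition(cf_table: dict[str, CalibrationFactor],
                     condition: str) -> CalibrationFactor:
    """CF lookup with the B-SAC -> UAC substitution.

    The B-SAC variants use the UAC-measured factor: the calibration
    cylinder contains no bone or air compartment, so a segmented map has
    nothing to represent and the uniform correction is the matching
    measurement condition.
    """
    key = "UAC" if condition in ("BSAC_N", "BSAC_M") else condition
    try:
        return cf_table[key]
    except KeyError:
        raise PairingError(
            f"no calibration factor for condition {condition!r} (lookup key "
            f"{key!r}); available: {sorted(cf_table)}")


# --------------------------------------------------------------------------
# SUV
# --------------------------------------------------------------------------

def suv_map(volume: VoxelGrid, cf: CalibrationFactor, meta: AcquisitionMeta,
            decay_correct: bool = False) -> VoxelGrid:
    """Voxelwise SUV from a count-density reconstruction.

    ``SUV = CF * density * (1/duration) * weight / injected``.  The printed
    equation carries no decay term; ``decay_correct=True`` optionally decays
    the injected activity over the injection-to-scan interval.
    """
    cond = volume.meta.get("condition")
    if cond is not None and cond not in cf.applies_to:
        raise PairingError(
            f"calibration factor measured under {cf.measured_under!r} applies to "
            f"{cf.applies_to}, not to a {cond!r} reconstruction")
    injected = meta.decay_corrected_activity() if decay_correct else meta.injected_bq
    suv = (cf.value_bq_per_cps * volume.data / meta.duration_s *
           meta.body_weight_g / injected)
    return volume.like(suv, kind="suv",
                       meta=dict(volume.meta, cf_bq_per_cps=cf.value_bq_per_cps))


# --------------------------------------------------------------------------
# lesion delineation
# --------------------------------------------------------------------------

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def delineate_mtv(suv: VoxelGrid, seed_mm: tuple[float, float, float],
                  fractions: tuple[float, ...] = MTV_THRESHOLDS,
                  search_radius_mm: float = 50.0,
                  lesion_id: int = 0, condition: str = "") -> LesionQuant:
    """Percent-of-SUVmax lesion delineation around a seed point.

    SUVmax is the maximum inside a ball around the seed; for each fraction
    the lesion is the 26-connected component of voxels with
    ``SUV >= fraction * SUVmax`` (inclusive) containing the hottest voxel,
    restricted to the search region.  Ties at the maximum break toward the
    lowest linear index.
    """
    region = sphere_mask(suv, seed_mm, search_radius_mm)
    if not region.any():
        raise ValueError("search region contains no voxels")
    vals = np.where(region, suv.data, -np.inf)
    suv_max = float(vals.max())
    if not suv_max > 0:
        raise ValueError("degenerate lesion: no positive SUV in search region")
    max_voxel = tuple(int(i) for i in np.unravel_index(int(np.argmax(vals)), vals.shape))

    quant = LesionQuant(lesion_id, condition, suv_max=suv_max, suv_peak=np.nan,
                        max_voxel=max_voxel)  # type: ignore[arg-type]
    v_cc = suv.voxel_volume_cc
    for frac in fractions:
        above = region & (suv.data >= frac * suv_max)
        labels, _ = ndimage.label(above, structure=_CONN26)
        members = labels == labels[max_voxel]
        quant.members[frac] = members
        quant.mtv_cc[frac] = float(members.sum()) * v_cc
        quant.suv_mean[frac] = float(suv.data[members].mean())
    quant.suv_peak = suv_peak(suv, max_voxel)
    return quant


def suv_peak(suv: VoxelGrid, max_voxel: tuple[int, int, int]) -> float:
    """Mean SUV in a 1-cc sphere centred on the hottest voxel.

    The sphere radius is ``(3*1000/4pi)^(1/3) = 6.2035 mm``; at the volume
    edge only in-bounds voxels enter the mean.
    """
    xs, ys, zs = suv.world_coords()
    center = (float(xs[max_voxel[0]]), float(ys[max_voxel[1]]),
              float(zs[max_voxel[2]]))
    member = sphere_mask(suv, center, SUVPEAK_RADIUS_MM)
    return float(suv.data[member].mean())


def total_bone_uptake(lesions: list[LesionQuant], threshold: float) -> float:
    """TBU (grams) = sum over lesions of MTV (cc) x SUVmean at one threshold."""
    total = 0.0
    for les in lesions:
        if threshold not in les.mtv_cc:
            raise ValueError(
                f"lesion {les.lesion_id} not quantified at threshold {threshold}")
        total += les.mtv_cc[threshold] * les.suv_mean[threshold]
    return total


def quantify_lesions(suv: VoxelGrid, seeds_mm: list[tuple[float, float, float]],
                     condition: str = "",
                     fractions: tuple[float, ...] = MTV_THRESHOLDS,
                     search_radius_mm: float = 50.0) -> list[LesionQuant]:
    """Delineate and quantify every seeded lesion on one SUV map."""
    return [delineate_mtv(suv, seed, fractions, search_radius_mm,
                          lesion_id=i, condition=condition)
            for i, seed in enumerate(seeds_mm)]


def quant_table(lesions: list[LesionQuant]) -> pd.DataFrame:
    """Flatten lesion metrics into the canonical long-format table."""
    rows = []
    for les in lesions:
        row = {"lesion_id": les.lesion_id, "condition": les.condition,
               "suv_max": les.suv_max, "suv_peak": les.suv_peak}
        for frac in sorted(les.mtv_cc):
            pct = int(round(frac * 100))
            row[f"mtv{pct}"] = les.mtv_cc[frac]
            row[f"suv_mean{pct}"] = les.suv_mean[frac]
        rows.append(row)
    return pd.DataFrame(rows)
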