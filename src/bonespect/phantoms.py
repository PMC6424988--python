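"""Digital phantoms for quantitative bone-SPECT simulation.

The generator emulates the imaging situation the segmentation method assumes:
a thorax where the skeleton carries high tracer uptake, soft tissue low
uptake, and lungs/background near-zero uptake, with focal bone lesions of
the highest uptake and elevated CT number.  It also builds the uniform
cylinder used to measure calibration factors (160 mm diameter x 150 mm
height, the standard quantitation phantom).

Each phantom is a pair of co-registered grids -- an activity map (Bq/mL)
and a CT-number map (HU) -- plus per-role masks and a truth table of lesion
concentrations, so that downstream SUV estimates can be scored against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import VoxelGrid

# --------------------------------------------------------------------------
# constants defining the simulated study conditions
# --------------------------------------------------------------------------

#: grid presets: (shape, spacing mm).  The clinical preset matches a 128x128
#: acquisition matrix at 4.42 mm; the fast preset keeps the same field of
#: view at half the matrix for desk-scale tests.
PRESETS: dict[str, tuple[tuple[int, int, int], tuple[float, float, float]]] = {
    "clinical": ((128, 128, 40), (4.42, 4.42, 4.42)),
    "fast": ((64, 64, 32), (6.0, 6.0, 6.0)),
}

#: nominal injected activity (Bq) and body weight (g) of the simulated
#: subject: 740 MBq Tc-99m HMDP in a 70 kg adult.
DEFAULT_INJECTED_BQ = 740e6
DEFAULT_BODY_WEIGHT_G = 70_000.0

#: default tissue values.  SUV 1 corresponds to the whole-body average
#: concentration injected/weight; HU values straddle the virtual-CT
#: replacement constants so that CT-based and emission-segmented attenuation
#: maps differ measurably.
TISSUE_SUV = {"body": 0.8, "lung": 0.08, "vertebra": 4.0, "rib": 4.0}
TISSUE_HU = {"body": 40.0, "lung": -800.0, "vertebra": 300.0, "rib": 300.0,
             "lesion": 600.0, "bladder": 40.0}
AIR_HU = -1000.0

BONE_ROLES = ("vertebra", "rib")


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is internally inconsistent."""


def suv_to_conc(suv: float, injected_bq: float = DEFAULT_INJECTED_BQ,
                body_weight_g: float = DEFAULT_BODY_WEIGHT_G) -> float:
    """Convert a nominal SUV into an activity concentration (Bq/mL).

    Tissue density is taken as 1 g/mL so Bq/g and Bq/mL coincide.
    """
    return suv * injected_bq / body_weight_g


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Primitive:
    """One geometric building block of a phantom.

    ``size_mm`` is interpreted per kind: semi-axes for an ellipsoid,
    ``(radius, half_height)`` for a z-axis cylinder, half-extents for a box.
    Primitives are painted in list order; later ones overwrite earlier ones.
    """

    kind: str                     # 'ellipsoid' | 'cylinder' | 'box'
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, ...]
    activity_bq_ml: float
    hu: float
    role: str                     # body | lung | vertebra | rib | lesion | bladder
    extraosseous: bool = False    # lesions only: allowed outside bone

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        xs, ys, zs = grid.world_coords()
        dx = (xs - self.center_mm[0])[:, None, None]
        dy = (ys - self.center_mm[1])[None, :, None]
        dz = (zs - self.center_mm[2])[None, None, :]
        if self.kind == "ellipsoid":
            a, b, c = self.size_mm
            return (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
        if self.kind == "cylinder":
            r, hh = self.size_mm
            return (dx ** 2 + dy ** 2 <= r ** 2) & (np.abs(dz) <= hh)
        if self.kind == "ellcyl":
            a, b, hh = self.size_mm
            return ((dx / a) ** 2 + (dy / b) ** 2 <= 1.0) & (np.abs(dz) <= hh)
        if self.kind == "box":
            a, b, c = self.size_mm
            return (np.abs(dx) <= a) & (np.abs(dy) <= b) & (np.abs(dz) <= c)
        raise PhantomSpecError(f"unknown primitive kind {self.kind!r}")


@dataclass
class PhantomSpec:
    """Declarative phantom description: grid geometry plus ordered primitives."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    primitives: list[Primitive]
    seed: int = 0
    injected_bq: float = DEFAULT_INJECTED_BQ
    body_weight_g: float = DEFAULT_BODY_WEIGHT_G


@dataclass
class PhantomTruth:
    """Ground truth: activity + CT grids, per-role ownership masks, lesion table.

    ``masks`` assign each voxel to the role of the last primitive covering
    it (so they are pairwise disjoint); ``body_support`` is every non-air
    voxel outside the lungs, so ``body_support | masks['lung']`` is exactly
    the non-air support.
    """

    activity: VoxelGrid
    ct: VoxelGrid
    masks: dict[str, np.ndarray]
    lesions: pd.DataFrame
    spec: PhantomSpec | None = None

    @property
    def body_support(self) -> np.ndarray:
        support = self.ct.data > AIR_HU
        lung = self.masks.get("lung")
        if lung is not None:
            support = support & ~lung
        return support

    @property
    def bone_mask(self) -> np.ndarray:
        out = np.zeros(self.ct.shape, dtype=bool)
        for role in BONE_ROLES:
            if role in self.masks:
                out |= self.masks[role]
        return out


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def _paint(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize a spec: paint primitives in order, collect ownership masks."""
    grid = VoxelGrid(np.zeros(spec.shape), spec.spacing, "activity")
    act = np.zeros(spec.shape, dtype=float)
    ct = np.full(spec.shape, AIR_HU, dtype=float)
    owner = np.full(spec.shape, -1, dtype=int)

    for i, prim in enumerate(spec.primitives):
        m = prim.mask(grid)
        act[m] = prim.activity_bq_ml
        ct[m] = prim.hu
        owner[m] = i

    masks: dict[str, np.ndarray] = {}
    for i, prim in enumerate(spec.primitives):
        m = owner == i
        masks[prim.role] = masks.get(prim.role, np.zeros(spec.shape, bool)) | m

    lesion_rows = []
    for i, prim in enumerate(spec.primitives):
        if prim.role != "lesion":
            continue
        m = owner == i
        lesion_rows.append({
            "lesion_id": len(lesion_rows),
            "center_x_mm": prim.center_mm[0],
            "center_y_mm": prim.center_mm[1],
            "center_z_mm": prim.center_mm[2],
            "diameter_mm": 2.0 * prim.size_mm[0],
            "activity_bq_ml": prim.activity_bq_ml,
            "suv": prim.activity_bq_ml * spec.body_weight_g / spec.injected_bq,
            "voxel_volume_cc": float(m.sum()) * grid.voxel_volume_cc,
        })
    lesions = pd.DataFrame(lesion_rows, columns=[
        "lesion_id", "center_x_mm", "center_y_mm", "center_z_mm",
        "diameter_mm", "activity_bq_ml", "suv", "voxel_volume_cc"])

    return PhantomTruth(
        activity=VoxelGrid(act, spec.spacing, "activity",
                           {"injected_bq": spec.injected_bq,
                            "body_weight_g": spec.body_weight_g}),
        ct=VoxelGrid(ct, spec.spacing, "hu"),
        masks=masks, lesions=lesions, spec=spec)


def rasterize(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize any spec without thorax-specific validation."""
    return _paint(spec)


def _validate_thorax(spec: PhantomSpec) -> None:
    roles = {p.role for p in spec.primitives}
    for needed in ("lung", "body"):
        if needed not in roles:
            raise PhantomSpecError(f"thorax spec needs a {needed} primitive")
    if not roles.intersection(BONE_ROLES):
        raise PhantomSpecError("thorax spec needs a bone primitive (vertebra/rib)")
    grid = VoxelGrid(np.zeros(spec.shape), spec.spacing, "activity")
    lungs = [p for p in spec.primitives if p.role == "lung"]
    bones = [p for p in spec.primitives if p.role in BONE_ROLES]
    for lu in lungs:
        lm = lu.mask(grid)
        for bo in bones:
            if np.any(lm & bo.mask(grid)):
                raise PhantomSpecError("lung and bone primitives overlap")


def _check_lesions_in_bone(spec: PhantomSpec, truth: PhantomTruth) -> None:
    grid = truth.activity
    bone = np.zeros(spec.shape, dtype=bool)
    for p in spec.primitives:
        if p.role in BONE_ROLES:
            bone |= p.mask(grid)
    for p in spec.primitives:
        if p.role == "lesion" and not p.extraosseous:
            m = p.mask(grid)
            if np.any(m & ~bone):
                raise PhantomSpecError(
                    f"lesion at {p.center_mm} extends outside bone "
                    "(flag extraosseous=True to allow)")


def make_thorax_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize a thorax spec into ground-truth activity/CT grids.

    Validates the three-compartment premise the emission segmentation rests
    on (lungs, soft tissue, bone present; lungs and bone disjoint; lesions
    inside bone unless flagged extraosseous).
    """
    _validate_thorax(spec)
    truth = _paint(spec)
    _check_lesions_in_bone(spec, truth)
    return truth


def make_cylinder_phantom(diameter_mm: float = 160.0, height_mm: float = 150.0,
                          activity_conc: float = 8300.0,
                          shape: tuple[int, int, int] | None = None,
                          spacing: tuple[float, float, float] | None = None,
                          preset: str = "fast") -> PhantomTruth:
    """Uniform water cylinder for calibration-factor measurement.

    Default dimensions are the standard quantitation phantom (160 mm
    diameter, 150 mm height); the default concentration corresponds to
    ~25 MBq of Tc-99m solution distributed over its ~3 L volume.
    """
    if shape is None or spacing is None:
        shape, spacing = PRESETS[preset]
    fov = (shape[0] * spacing[0], shape[1] * spacing[1], shape[2] * spacing[2])
    if diameter_mm > fov[0] or diameter_mm > fov[1] or height_mm > fov[2]:
        raise PhantomSpecError(
            f"cylinder {diameter_mm} x {height_mm} mm does not fit the "
            f"{fov[0]:.0f} x {fov[1]:.0f} x {fov[2]:.0f} mm grid")
    prim = Primitive("cylinder", (0.0, 0.0, 0.0),
                     (diameter_mm / 2.0, height_mm / 2.0),
                     activity_bq_ml=activity_conc, hu=0.0, role="body")
    spec = PhantomSpec(shape, spacing, [prim])
    truth = _paint(spec)
    truth.activity.meta["true_conc_bq_ml"] = activity_conc
    return truth


def default_thorax_spec(preset: str = "fast", seed: int = 0,
                        lesion_suvs: Sequence[float] = (15.0, 20.0, 12.0),
                        lesion_diameters_mm: Sequence[float] = (32.0, 26.0, 20.0),
                        injected_bq: float = DEFAULT_INJECTED_BQ,
                        body_weight_g: float = DEFAULT_BODY_WEIGHT_G,
                        ) -> PhantomSpec:
    """Reference thorax: elliptical body, two lungs, posterior spine, lesions.

    Lesions are spheres centred on the vertebral column at fixed axial
    stations; sizes/uptakes default to a representative mix (one >=30 mm
    lesion for partial-volume checks).
    """
    shape, spacing = PRESETS[preset]
    zlen = shape[2] * spacing[2]

    def conc(suv: float) -> float:
        return suv_to_conc(suv, injected_bq, body_weight_g)

    # body: elliptical cylinder spanning the full axial extent
    prims = [
        Primitive("ellcyl", (0.0, 0.0, 0.0), (160.0, 110.0, zlen),
                  conc(TISSUE_SUV["body"]), TISSUE_HU["body"], "body"),
        Primitive("ellipsoid", (-68.0, 12.0, 0.0), (48.0, 62.0, 0.42 * zlen),
                  conc(TISSUE_SUV["lung"]), TISSUE_HU["lung"], "lung"),
        Primitive("ellipsoid", (68.0, 12.0, 0.0), (48.0, 62.0, 0.42 * zlen),
                  conc(TISSUE_SUV["lung"]), TISSUE_HU["lung"], "lung"),
        Primitive("cylinder", (0.0, -70.0, 0.0), (20.0, 0.46 * zlen),
                  conc(TISSUE_SUV["vertebra"]), TISSUE_HU["vertebra"], "vertebra"),
    ]
    stations = np.linspace(-0.3, 0.3, max(len(lesion_suvs), 1)) * zlen
    for suv, dia, z in zip(lesion_suvs, lesion_diameters_mm, stations):
        prims.append(Primitive("ellipsoid", (0.0, -70.0, float(z)),
                               (dia / 2.0,) * 3, conc(suv),
                               TISSUE_HU["lesion"], "lesion"))
    return PhantomSpec(shape, spacing, prims, seed=seed,
                       injected_bq=injected_bq, body_weight_g=body_weight_g)


def refine_spec(spec: PhantomSpec, factor: int = 2) -> PhantomSpec:
    """Same physical phantom on a ``factor``-times finer grid.

    Primitives are defined in world mm, so rasterizing the identical spec
    at finer spacing yields the same anatomy; simulation uses the fine
    grid while reconstruction stays at the acquisition grid, so the data
    are never generated with the reconstruction's own discretization.
    """
    shape = tuple(n * factor for n in spec.shape)
    spacing = tuple(s / factor for s in spec.spacing)
    return replace(spec, shape=shape, spacing=spacing)


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON/YAML-serialisable form of a phantom spec."""
    return {
        "shape": list(spec.shape), "spacing": list(spec.spacing),
        "seed": spec.seed, "injected_bq": spec.injected_bq,
        "body_weight_g": spec.body_weight_g,
        "primitives": [
            {"kind": p.kind, "center_mm": list(p.center_mm),
             "size_mm": list(p.size_mm), "activity_bq_ml": p.activity_bq_ml,
             "hu": p.hu, "role": p.role, "extraosseous": p.extraosseous}
            for p in spec.primitives],
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    prims = [Primitive(p["kind"], tuple(p["center_mm"]), tuple(p["size_mm"]),
                       p["activity_bq_ml"], p["hu"], p["role"],
                       p.get("extraosseous", False))
             for p in d["primitives"]]
    return PhantomSpec(tuple(d["shape"]), tuple(d["spacing"]), prims,
                       seed=d.get("seed", 0),
                       injected_bq=d.get("injected_bq", DEFAULT_INJECTED_BQ),
                       body_weight_g=d.get("body_weight_g", DEFAULT_BODY_WEIGHT_G))


def make_cohort(n_phantoms: int, lesion_count_range: tuple[int, int] = (4, 4),
                suv_range: tuple[float, float] = (8.0, 25.0),
                seed: int = 0, preset: str = "fast",
                diameter_range_mm: tuple[float, float] = (18.0, 29.0),
                jitter_mm: float = 4.0,
                max_attempts: int = 1000) -> list[PhantomTruth]:
    """Simulated patient cohort with randomly placed spinal lesions.

    Lesion concentrations are drawn uniformly from ``suv_range`` (converted
    to Bq/mL) and diameters from ``diameter_range_mm``.  Lesions sit on the
    vertebral column at stratified axial stations with a small random
    jitter, which keeps every lesion fully inside bone and far enough from
    its neighbours that each can be delineated in its own search region.
    Placement rejection-samples within these constraints; exceeding
    ``max_attempts`` is an error.
    """
    if n_phantoms < 1:
        raise ValueError("n_phantoms must be >= 1")
    lo, hi = lesion_count_range
    if lo < 1 or hi < lo:
        raise ValueError(f"bad lesion_count_range {lesion_count_range}")
    if suv_range[1] < suv_range[0] or suv_range[0] <= 0:
        raise ValueError(f"bad suv_range {suv_range}")
    max_r = diameter_range_mm[1] / 2.0

    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_phantoms):
        base = default_thorax_spec(preset, lesion_suvs=(), lesion_diameters_mm=())
        spine = next(p for p in base.primitives if p.role == "vertebra")
        z_max = spine.size_mm[1] - max_r - jitter_mm - 2.0
        if z_max <= 0:
            raise PhantomSpecError("spine too short for the requested lesion sizes")
        n_lesions = int(rng.integers(lo, hi + 1))
        stations = (np.linspace(-z_max, z_max, n_lesions) if n_lesions > 1
                    else np.array([0.0]))
        placed: list[Primitive] = []
        for st in stations:
            for attempt in range(max_attempts):
                suv = float(rng.uniform(*suv_range))
                dia = float(rng.uniform(*diameter_range_mm))
                r = dia / 2.0
                z = float(st + rng.uniform(-jitter_mm, jitter_mm))
                if r > spine.size_mm[0] or abs(z) + r > spine.size_mm[1]:
                    continue
                if any(abs(z - p.center_mm[2]) < (r + p.size_mm[0] + 6.0)
                       for p in placed):
                    continue
                placed.append(Primitive(
                    "ellipsoid", (0.0, -70.0, z), (r,) * 3,
                    suv_to_conc(suv, base.injected_bq, base.body_weight_g),
                    TISSUE_HU["lesion"], "lesion"))
                break
            else:
                raise PhantomSpecError(
                    f"could not place a lesion near station {st:.0f} mm in "
                    f"{max_attempts} attempts")
        spec = replace(base, primitives=base.primitives + placed,
                       seed=int(rng.integers(0, 2**31 - 1)))
        cohort.append(make_thorax_phantom(spec))
    return cohort
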