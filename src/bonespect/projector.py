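"""Parallel-beam SPECT forward model.

The projector maps a 3-D emission volume to per-view sinogram counts,
slice by slice, with three physical effects:

* photon attenuation -- each voxel's contribution is weighted by
  ``exp(-integral of mu from voxel to detector)`` along the projection ray;
* distance-dependent collimator blur -- a Gaussian in the detector plane
  (bin and axial directions) whose FWHM grows linearly with
  voxel-to-detector distance;
* counting statistics -- optional Poisson sampling of expected counts.

Rotation is implemented as a per-view sparse bilinear-interpolation
operator whose columns are normalized so every in-field voxel's emission is
exactly conserved per view; its stored transpose gives an exact adjoint,
which OSEM uses for backprojection.  A dual-energy scatter window is
emulated as a broad, renormalized blur of the primary sinogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter

from .grid import VoxelGrid

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry and detector model.

    Defaults follow a clinical bone-SPECT protocol: 60 views over 360
    degrees at 12 s/view, photopeak window 141 keV +/- 10 % with a 120 keV
    +/- 5 % scatter window.  ``sensitivity_cps_per_bq`` is the system-level
    detection efficiency; the absolute value is immaterial for SUVs because
    the calibration factor absorbs it.
    """

    n_views: int = 60
    arc_deg: float = 360.0
    t_view_s: float = 12.0
    detector_radius_mm: float = 250.0
    sensitivity_cps_per_bq: float = 1.0
    psf_fwhm0_mm: float = 3.0
    psf_slope: float = 0.02            # mm FWHM per mm distance
    main_window_kev: tuple[float, float] = (126.9, 155.1)   # 141 keV +/- 10 %
    sub_window_kev: tuple[float, float] = (114.0, 126.0)    # 120 keV +/- 5 %

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * self.arc_deg / self.n_views

    @property
    def duration_total_s(self) -> float:
        """Total acquisition time contributing to each voxel (all views)."""
        return self.n_views * self.t_view_s

    @property
    def main_window_width_kev(self) -> float:
        return self.main_window_kev[1] - self.main_window_kev[0]

    @property
    def sub_window_width_kev(self) -> float:
        return self.sub_window_kev[1] - self.sub_window_kev[0]


@dataclass
class Sinogram:
    """Per-(view, bin, slice) counts for the main (and optional sub) window."""

    main: np.ndarray                   # (n_views, n_bins, n_slices)
    geometry: Geometry
    spacing: tuple[float, float, float]  # (bin, bin, slice) mm, = voxel spacing
    sub: np.ndarray | None = None
    kind: str = "expected"             # 'expected' | 'sampled'
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.main = np.asarray(self.main, dtype=float)
        if self.main.ndim != 3:
            raise ValueError("sinogram must be (views, bins, slices)")
        if np.any(self.main < 0):
            raise ValueError("sinogram counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.main.shape  # type: ignore[return-value]


# --------------------------------------------------------------------------
# HU -> mu conversion
# --------------------------------------------------------------------------

def hu_to_mu(hu_grid: VoxelGrid, mu_water_cm1: float = 0.151,
             bone_slope: float = 0.5) -> VoxelGrid:
    """Convert CT numbers to linear attenuation coefficients at ~140 keV.

    Piecewise-linear, anchored at air (-1000 HU -> 0) and water (0 HU ->
    ``mu_water_cm1``); above water the slope is reduced by ``bone_slope``
    because bone attenuates less per HU at SPECT energies than the
    water-scaled extrapolation.  Shape and spacing are preserved exactly
    (no resampling).
    """
    hu = np.asarray(hu_grid.data, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU grid contains non-finite values")
    if np.any(hu < -1000.0):
        warnings.warn("HU values below -1000 clipped to -1000", stacklevel=2)
        hu = np.clip(hu, -1000.0, None)
    mu = np.where(
        hu <= 0.0,
        mu_water_cm1 * (1.0 + hu / 1000.0),
        mu_water_cm1 * (1.0 + bone_slope * hu / 1000.0),
    )
    return hu_grid.like(mu, kind="mu",
                        meta={"mu_water_cm1": mu_water_cm1, "bone_slope": bone_slope})


# --------------------------------------------------------------------------
# rotation operators
# --------------------------------------------------------------------------

def rotation_matrix(shape2d: tuple[int, int], angle_deg: float,
                    conserve: bool = True) -> sparse.csr_matrix:
    """Sparse bilinear in-plane rotation operator (gather form).

    Maps a flattened ``(nx, ny)`` image to the frame rotated by
    ``angle_deg`` about the grid centre.  With ``conserve`` the columns are
    normalized so each source voxel whose image lands in-frame contributes
    exactly its full value (emission conservation per view).
    """
    nx, ny = shape2d
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ti, tj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    tx, ty = ti.ravel() - cx, tj.ravel() - cy
    sx = c * tx - s * ty + cx
    sy = s * tx + c * ty + cy
    i0 = np.floor(sx).astype(int)
    j0 = np.floor(sy).astype(int)
    fx, fy = sx - i0, sy - j0

    rows, cols, vals = [], [], []
    target = np.arange(nx * ny)
    for di, dj, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        ii, jj = i0 + di, j0 + dj
        ok = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny) & (w > 0)
        rows.append(target[ok])
        cols.append(ii[ok] * ny + jj[ok])
        vals.append(w[ok])
    mat = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny))
    if conserve:
        colsum = np.asarray(mat.sum(axis=0)).ravel()
        scale = np.where(colsum > 1e-12, 1.0 / np.maximum(colsum, 1e-12), 0.0)
        mat = mat @ sparse.diags(scale)
    return mat.tocsr()


class RotationSet:
    """Per-view rotation operators for one set of angles.

    Two flavours are exposed: the emission-conserving operator (column-
    normalized; what the projector and its exact adjoint use for counts)
    and a plain bilinear interpolation (what value fields -- mu-maps,
    masks -- must use, since renormalization distorts pointwise values).
    The interpolation matrices are built lazily.
    """

    def __init__(self, shape2d: tuple[int, int], angles_deg: np.ndarray):
        self.shape2d = shape2d
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self.mats = [rotation_matrix(shape2d, a) for a in self.angles_deg]
        self.mats_t = [m.T.tocsr() for m in self.mats]
        self._imats: list[sparse.csr_matrix] | None = None

    def _apply(self, mat: sparse.csr_matrix, vol: np.ndarray) -> np.ndarray:
        nx, ny = self.shape2d
        nz = vol.shape[2]
        return (mat @ vol.reshape(nx * ny, nz)).reshape(nx, ny, nz)

    def rotate(self, vol: np.ndarray, view: int) -> np.ndarray:
        """Emission-conserving rotation (counts)."""
        return self._apply(self.mats[view], vol)

    def rotate_adjoint(self, vol: np.ndarray, view: int) -> np.ndarray:
        """Exact transpose of :meth:`rotate`."""
        return self._apply(self.mats_t[view], vol)

    def rotate_interp(self, vol: np.ndarray, view: int) -> np.ndarray:
        """Plain bilinear interpolation rotation (value fields)."""
        if self._imats is None:
            self._imats = [rotation_matrix(self.shape2d, a, conserve=False)
                           for a in self.angles_deg]
        return self._apply(self._imats[view], vol)


# --------------------------------------------------------------------------
# the projector
# --------------------------------------------------------------------------

class Projector:
    """Linear system operator for one volume geometry and acquisition.

    ``forward`` maps counts-per-voxel to per-view sinogram counts; the
    operator is strictly linear and ``adjoint`` is its exact transpose.
    Attenuation uses the per-view rotated mu-map with an exclusive
    line-integral (voxels strictly between the emitter and the detector);
    the detector sits at the +y edge of the rotated frame.
    """

    def __init__(self, shape: tuple[int, int, int],
                 spacing: tuple[float, float, float],
                 geometry: Geometry,
                 mu: VoxelGrid | None = None,
                 psf: bool = False,
                 rotations: RotationSet | None = None,
                 cache_attenuation: bool = True):
        self.shape = tuple(shape)
        self.spacing = tuple(spacing)
        self.geometry = geometry
        self.psf = psf
        nx, ny, nz = self.shape
        self.rot = rotations or RotationSet((nx, ny), geometry.angles_deg)
        if self.rot.shape2d != (nx, ny):
            raise ValueError("rotation set shape mismatch")

        if mu is not None and mu.shape != self.shape:
            raise ValueError(
                f"mu shape {mu.shape} does not match volume shape {self.shape}")
        self._mu = mu
        self._cache_attenuation = cache_attenuation
        self._trans: list[np.ndarray | None] = [None] * geometry.n_views
        self.has_mu = mu is not None

        self._blur: tuple[np.ndarray, np.ndarray] | None = None
        if psf:
            self._blur = self._build_blur_stack()

    def _transmission(self, view: int) -> np.ndarray | None:
        """Per-voxel transmission factor toward the detector for one view.

        Attenuation counts voxels strictly between the emitter and the
        detector (at +y of the rotated frame).  Cached per view unless the
        projector was built single-pass (``cache_attenuation=False``).
        """
        if self._mu is None:
            return None
        if self._trans[view] is None:
            dl_cm = self.spacing[1] / 10.0
            mu_rot = self.rot.rotate_interp(self._mu.data, view)
            tail = np.cumsum(mu_rot[:, ::-1, :], axis=1)[:, ::-1, :] - mu_rot
            t = np.exp(-dl_cm * np.maximum(tail, 0.0))
            if not self._cache_attenuation:
                return t
            self._trans[view] = t
        return self._trans[view]

    def _sigma_per_depth(self) -> np.ndarray:
        """PSF sigma (mm) per depth plane from the linear FWHM-distance model."""
        ny = self.shape[1]
        dy = self.spacing[1]
        y_world = (np.arange(ny) - (ny - 1) / 2.0) * dy
        dist = self.geometry.detector_radius_mm - y_world
        fwhm = self.geometry.psf_fwhm0_mm + self.geometry.psf_slope * np.maximum(dist, 0.0)
        return fwhm * FWHM_TO_SIGMA

    @staticmethod
    def _blur_matrices(n: int, sigma_vox: np.ndarray) -> np.ndarray:
        """(n_depth, n, n) symmetric Gaussian blur matrices, one per depth."""
        idx = np.arange(n)
        offs = idx[:, None] - idx[None, :]
        stack = np.empty((len(sigma_vox), n, n))
        for j, s in enumerate(sigma_vox):
            if s < 1e-3:
                stack[j] = np.eye(n)
                continue
            k = np.exp(-0.5 * (offs / s) ** 2)
            k[np.abs(offs) > 4.0 * s + 1.0] = 0.0
            stack[j] = k / k[n // 2].sum()
        return stack

    def _build_blur_stack(self) -> tuple[np.ndarray, np.ndarray]:
        """Detector-plane PSF: isotropic blur over bins and slices per depth."""
        nx, _, nz = self.shape
        sig = self._sigma_per_depth()
        return (self._blur_matrices(nx, sig / self.spacing[0]),
                self._blur_matrices(nz, sig / self.spacing[2]))

    def forward(self, vol: np.ndarray,
                views: Sequence[int] | None = None) -> np.ndarray:
        """Project counts-per-voxel to (len(views), n_bins, n_slices) counts."""
        vol = np.asarray(vol, dtype=float)
        if vol.shape != self.shape:
            raise ValueError(f"volume shape {vol.shape} != projector shape {self.shape}")
        views = list(range(self.geometry.n_views)) if views is None else list(views)
        out = np.empty((len(views), self.shape[0], self.shape[2]))
        for k, v in enumerate(views):
            w = self.rot.rotate(vol, v)
            trans = self._transmission(v)
            if trans is not None:
                w = w * trans
            if self._blur is not None:
                # per depth j: Bx[j] @ w[:, j, :] @ Bz[j], then sum over j
                bx, bz = self._blur
                t = np.matmul(bx, w.transpose(1, 0, 2))   # (j, b, z)
                out[k] = np.matmul(t, bz).sum(axis=0)
            else:
                out[k] = w.sum(axis=1)
        return out

    def adjoint(self, sino: np.ndarray,
                views: Sequence[int] | None = None) -> np.ndarray:
        """Exact transpose of :meth:`forward` for the same view subset."""
        views = list(range(self.geometry.n_views)) if views is None else list(views)
        sino = np.asarray(sino, dtype=float)
        nx, ny, nz = self.shape
        if sino.shape != (len(views), nx, nz):
            raise ValueError(f"sinogram shape {sino.shape} incompatible")
        out = np.zeros(self.shape)
        for k, v in enumerate(views):
            if self._blur is not None:
                # adjoint of (blur then depth-sum): broadcast over depth,
                # apply the symmetric blur matrices per depth plane
                bx, bz = self._blur
                bw = np.broadcast_to(sino[k][None, :, :], (ny, nx, nz))
                w = np.matmul(np.matmul(bx, bw), bz).transpose(1, 0, 2)
            else:
                w = np.broadcast_to(sino[k][:, None, :], (nx, ny, nz)).copy()
            trans = self._transmission(v)
            if trans is not None:
                w = w * trans
            out += self.rot.rotate_adjoint(w, v)
        return out


# --------------------------------------------------------------------------
# simulation front-ends
# --------------------------------------------------------------------------

def forward_project(activity: VoxelGrid, mu: VoxelGrid | None,
                    geometry: Geometry, psf_enabled: bool = False,
                    projector: Projector | None = None) -> Sinogram:
    """Expected-count sinogram of an activity map (Bq/mL).

    Expected counts per bin are the attenuated ray sum of
    ``activity * voxel_volume * per-view duration * sensitivity``.
    """
    if mu is not None and (mu.shape != activity.shape or
                           mu.spacing != activity.spacing):
        raise ValueError("activity and mu grids must share shape and spacing")
    proj = projector or Projector(activity.shape, activity.spacing, geometry,
                                  mu=mu, psf=psf_enabled)
    scale = (activity.voxel_volume_cc * geometry.t_view_s *
             geometry.sensitivity_cps_per_bq)
    counts = proj.forward(activity.data * scale)
    return Sinogram(counts, geometry, activity.spacing, kind="expected",
                    meta={"psf": psf_enabled, "attenuated": mu is not None})


def rebin_sinogram(sino: Sinogram, factor: int = 2) -> Sinogram:
    """Sum ``factor x factor`` blocks of (bin, slice) into coarser detector bins.

    Counts are conserved exactly.  Used when the data are simulated on a
    finer grid than the reconstruction models, so the inverse problem is
    never solved with the discretization that generated the data.
    """
    nv, nb, ns = sino.main.shape
    if nb % factor or ns % factor:
        raise ValueError(f"sinogram {nb}x{ns} not divisible by factor {factor}")

    def block(a: np.ndarray) -> np.ndarray:
        return a.reshape(nv, nb // factor, factor, ns // factor, factor).sum(axis=(2, 4))

    spacing = (sino.spacing[0] * factor, sino.spacing[1] * factor,
               sino.spacing[2] * factor)
    return Sinogram(block(sino.main), sino.geometry, spacing,
                    sub=block(sino.sub) if sino.sub is not None else None,
                    kind=sino.kind, meta=dict(sino.meta, rebin_factor=factor))


def simulate_scatter_window(primary: Sinogram, scatter_fraction: float = 0.3,
                            scatter_blur_fwhm_mm: float = 60.0) -> Sinogram:
    """Add a scatter field to the photopeak and emit the sub-window sinogram.

    The scatter field is a broad Gaussian blur of the primary counts scaled
    to ``scatter_fraction`` of their total; the same field is added to the
    main window (so dual-energy-window correction has a real component to
    remove) and returned as the sub window.
    """
    if not 0.0 <= scatter_fraction < 1.0:
        raise ValueError(f"scatter_fraction must be in [0, 1), got {scatter_fraction}")
    if scatter_fraction == 0.0:
        return Sinogram(primary.main.copy(), primary.geometry, primary.spacing,
                        sub=np.zeros_like(primary.main), kind=primary.kind,
                        meta=dict(primary.meta, scatter_fraction=0.0))
    sig_bin = scatter_blur_fwhm_mm * FWHM_TO_SIGMA / primary.spacing[0]
    sig_sl = scatter_blur_fwhm_mm * FWHM_TO_SIGMA / primary.spacing[2]
    blurred = gaussian_filter(primary.main, sigma=(0.0, sig_bin, sig_sl),
                              mode="constant")
    total = blurred.sum()
    if total > 0:
        blurred *= primary.main.sum() / total  # renormalize edge losses
    field = scatter_fraction * blurred
    return Sinogram(primary.main + field, primary.geometry, primary.spacing,
                    sub=field, kind=primary.kind,
                    meta=dict(primary.meta, scatter_fraction=scatter_fraction,
                              scatter_blur_fwhm_mm=scatter_blur_fwhm_mm))


def add_poisson(sino: Sinogram, seed: int) -> Sinogram:
    """Independent Poisson draw of every bin (main and sub windows)."""
    if np.any(~np.isfinite(sino.main)) or np.any(sino.main < 0):
        raise ValueError("expected counts must be finite and non-negative")
    rng = np.random.default_rng(seed)
    main = rng.poisson(sino.main).astype(float)
    sub = None
    if sino.sub is not None:
        sub = rng.poisson(sino.sub).astype(float)
    return Sinogram(main, sino.geometry, sino.spacing, sub=sub, kind="sampled",
                    meta=dict(sino.meta, noise_seed=seed))
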