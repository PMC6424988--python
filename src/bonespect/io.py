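"""Volume and sinogram I/O plus run provenance.

NIfTI-1 is the canonical volume format: RAS+ diagonal affine in mm with
the origin at the grid centre, values stored as float32.  Sinograms are
stored as ``.npz`` arrays with a JSON sidecar for the acquisition
geometry.  Every numeric output can be stamped with the SHA-256 hash of
the generating configuration so a run can be replayed bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

from .grid import VoxelGrid
from .projector import Geometry, Sinogram


class FormatError(ValueError):
    """Raised when a file is not in the expected format."""


def _affine(shape: tuple[int, int, int],
            spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    for i in range(3):
        aff[i, 3] = -(shape[i] - 1) / 2.0 * spacing[i]
    return aff


def write_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a grid as float32 NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(grid.data.astype(np.float32),
                          _affine(grid.shape, grid.spacing))
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = f"bonespect:{grid.kind}"[:79].encode()
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, kind: str = "activity") -> VoxelGrid:
    """Read a NIfTI volume; spacing comes from the affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types on bad input
        raise FormatError(f"{path} is not readable as NIfTI: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"{path} is {type(img).__name__}, expected NIfTI")
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise FormatError(f"{path} has {data.ndim} dimensions, expected 3")
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    descrip = img.header["descrip"].tobytes().decode(errors="ignore")
    if descrip.startswith("bonespect:"):
        kind = descrip.split(":", 1)[1].split("\x00")[0] or kind
    return VoxelGrid(data, spacing, kind)


def write_sinogram(sino: Sinogram, path: str | Path) -> Path:
    """Write sinogram arrays (.npz) plus a JSON geometry sidecar."""
    path = Path(path)
    arrays = {"main": sino.main}
    if sino.sub is not None:
        arrays["sub"] = sino.sub
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "geometry": dataclasses.asdict(sino.geometry),
        "spacing": list(sino.spacing),
        "kind": sino.kind,
        "meta": {k: v for k, v in sino.meta.items()
                 if isinstance(v, (int, float, str, bool, list))},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    npz = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    geo_kw = dict(sidecar["geometry"])
    for key in ("main_window_kev", "sub_window_kev"):
        geo_kw[key] = tuple(geo_kw[key])
    geo = Geometry(**geo_kw)
    return Sinogram(npz["main"], geo, tuple(sidecar["spacing"]),
                    sub=npz["sub"] if "sub" in npz else None,
                    kind=sidecar["kind"], meta=sidecar.get("meta", {}))


def config_hash(config: dict[str, Any]) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def volume_checksum(grid: VoxelGrid) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(grid.data.astype(np.float64)).tobytes())
    h.update(repr(grid.spacing).encode())
    return h.hexdigest()[:16]
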