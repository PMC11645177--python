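"""NIfTI-1 + JSON-sidecar I/O for images, masks and relaxation maps.

Volumes are written as uncompressed little-endian NIfTI-1 (deterministic
bytes for a given array, which the run manifest hashes rely on); units and
acquisition parameters live in JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import nibabel as nib
import numpy as np

from .acquisition import AcquisitionParams
from .relaxometry import RelaxationMap
from .synthetic import MultiEchoImage

__all__ = [
    "save_multi_echo",
    "load_multi_echo",
    "save_relaxation_map",
    "load_relaxation_map",
    "save_mask",
    "load_mask",
]

PathLike = Union[str, Path]


def _affine(params: AcquisitionParams) -> np.ndarray:
    dx, dy, dz = params.voxel_size
    return np.diag([dx, dy, dz, 1.0])


def _save_nifti(data: np.ndarray, affine: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def save_multi_echo(image: MultiEchoImage, out_dir: PathLike, stem: str = "frame") -> Path:
    """Write one multi-echo image: per-echo 3D volumes, a 4D volume, and a
    JSON sidecar.  Returns the sidecar path (the handle for loading)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = image.data
    if data.ndim == 3:  # 2D grid + echo axis -> promote to single slice
        data = data[:, :, None, :]
    aff = _affine(image.params)
    echo_files: List[str] = []
    for e in range(image.n_echoes):
        name = f"{stem}_echo{e:02d}.nii"
        _save_nifti(data[..., e], aff, out_dir / name)
        echo_files.append(name)
    _save_nifti(data, aff, out_dir / f"{stem}_4d.nii")
    sidecar = {
        "format": "ferromap.multi_echo",
        "params": image.params.to_dict(),
        "frame_time_min": image.frame_time,
        "echo_files": echo_files,
        "file_4d": f"{stem}_4d.nii",
        "grid_shape": list(image.grid_shape),
    }
    side = out_dir / f"{stem}.json"
    side.write_text(json.dumps(sidecar, indent=2) + "\n")
    return side


def load_multi_echo(sidecar_path: PathLike) -> MultiEchoImage:
    side = Path(sidecar_path)
    meta = json.loads(side.read_text())
    if meta.get("format") != "ferromap.multi_echo":
        raise ValueError(f"{side} is not a multi-echo sidecar")
    params = AcquisitionParams.from_dict(meta["params"])
    vol = np.asarray(nib.load(str(side.parent / meta["file_4d"])).dataobj, dtype=float)
    grid = tuple(meta["grid_shape"])
    data = vol.reshape(grid + (params.n_echoes,))
    return MultiEchoImage(data=data, params=params, frame_time=meta.get("frame_time_min"))


def save_relaxation_map(
    rmap: RelaxationMap,
    out_dir: PathLike,
    stem: str = "map",
    provenance: Optional[Dict[str, object]] = None,
) -> Path:
    """Write values/mask/n-echoes volumes plus a JSON provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(rmap.source_params)

    def vol(a: np.ndarray) -> np.ndarray:
        return a[:, :, None] if a.ndim == 2 else a

    _save_nifti(vol(rmap.values), aff, out_dir / f"{stem}_values.nii")
    _save_nifti(vol(rmap.valid_mask.astype(np.uint8)), aff, out_dir / f"{stem}_mask.nii")
    _save_nifti(vol(rmap.n_echoes_used.astype(np.int16)), aff, out_dir / f"{stem}_nechoes.nii")
    _save_nifti(vol(rmap.invalid_reason.astype(np.uint8)), aff, out_dir / f"{stem}_reason.nii")
    _save_nifti(vol(rmap.s0), aff, out_dir / f"{stem}_s0.nii")
    sidecar = {
        "format": "ferromap.relaxation_map",
        "kind": rmap.kind,
        "units": "s^-1",
        "params": rmap.source_params.to_dict(),
        "frame_time_min": rmap.frame_time,
        "grid_shape": list(rmap.shape),
        "n_valid": rmap.n_valid,
        "provenance": provenance or {},
        "files": {
            "values": f"{stem}_values.nii",
            "mask": f"{stem}_mask.nii",
            "n_echoes": f"{stem}_nechoes.nii",
            "reason": f"{stem}_reason.nii",
            "s0": f"{stem}_s0.nii",
        },
    }
    side = out_dir / f"{stem}.json"
    side.write_text(json.dumps(sidecar, indent=2) + "\n")
    return side


def load_relaxation_map(sidecar_path: PathLike) -> RelaxationMap:
    side = Path(sidecar_path)
    meta = json.loads(side.read_text())
    if meta.get("format") != "ferromap.relaxation_map":
        raise ValueError(f"{side} is not a relaxation-map sidecar")
    grid = tuple(meta["grid_shape"])

    def arr(key: str, dtype) -> np.ndarray:
        a = np.asarray(nib.load(str(side.parent / meta["files"][key])).dataobj)
        return a.reshape(grid).astype(dtype)

    return RelaxationMap(
        values=arr("values", float),
        s0=arr("s0", float),
        valid_mask=arr("mask", bool),
        kind=meta["kind"],
        n_echoes_used=arr("n_echoes", np.int16),
        source_params=AcquisitionParams.from_dict(meta["params"]),
        invalid_reason=arr("reason", np.uint8),
        frame_time=meta.get("frame_time_min"),
    )


def save_mask(mask: np.ndarray, path: PathLike, params: Optional[AcquisitionParams] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(params) if params is not None else np.eye(4)
    m = np.asarray(mask, dtype=np.uint8)
    if m.ndim == 2:
        m = m[:, :, None]
    nib.save(nib.Nifti1Image(m, aff), str(path))
    return path


def load_mask(path: PathLike, grid_shape=None) -> np.ndarray:
    a = np.asarray(nib.load(str(path)).dataobj)
    m = a > 0
    if grid_shape is not None:
        m = m.reshape(tuple(grid_shape))
    return m
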