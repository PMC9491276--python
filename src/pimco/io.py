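"""NIfTI input/output and JSON provenance sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .coupling import CouplingImage, ModalityStack

__all__ = [
    "load_stack",
    "save_volume",
    "load_volume",
    "save_coupling",
    "load_coupling",
    "write_sidecar",
]


def load_volume(path) -> tuple[np.ndarray, nib.Nifti1Image]:
    """Load a 3-D NIfTI volume; returns the float array and the image object."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return data, img


def load_stack(modality_paths, mask_path, modality_names=None) -> tuple[ModalityStack, nib.Nifti1Image]:
    """Load m modality volumes and a 0/1 mask sharing one grid.

    Voxel dimensions are taken from the mask header; all volumes must match
    the mask grid exactly.  Returns the stack and the reference NIfTI image
    (for writing outputs on the same affine).
    """
    mask_data, mask_img = load_volume(mask_path)
    mask = mask_data > 0.5
    vols = []
    for p in modality_paths:
        data, img = load_volume(p)
        if data.shape != mask.shape:
            raise ValueError(f"{p}: grid {data.shape} does not match mask {mask.shape}")
        vols.append(data)
    zooms = mask_img.header.get_zooms()[:3]
    names = list(modality_names) if modality_names else [Path(p).name.split(".")[0] for p in modality_paths]
    stack = ModalityStack(
        volumes=np.stack(vols),
        mask=mask,
        voxel_dims_mm=tuple(float(z) for z in zooms),
        modality_names=names,
    )
    return stack, mask_img


def save_volume(data: np.ndarray, path, like: nib.Nifti1Image | None = None, voxel_dims_mm=None):
    """Write a 3-D array as NIfTI, copying affine/header from ``like`` if given."""
    data = np.asarray(data)
    if like is not None:
        img = nib.Nifti1Image(data.astype(np.float32), like.affine, like.header)
    else:
        affine = np.diag(list(voxel_dims_mm or (1.0, 1.0, 1.0)) + [1.0])
        img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))


def write_sidecar(path, payload: dict):
    """Write a JSON sidecar with the software version added."""
    payload = dict(payload)
    payload.setdefault("software", f"pimco {__version__}")
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_coupling(img: CouplingImage, path, like: nib.Nifti1Image | None = None, voxel_dims_mm=None):
    """Write a coupling image (NaN = missing) plus its JSON sidecar."""
    path = Path(path)
    save_volume(img.coupling, path, like=like, voxel_dims_mm=voxel_dims_mm)
    sidecar = path.with_name(path.name.split(".")[0] + ".json")
    write_sidecar(sidecar, img.provenance)
    return sidecar


def load_coupling(path) -> CouplingImage:
    """Load a coupling NIfTI written by :func:`save_coupling`."""
    data, img = load_volume(path)
    sidecar = Path(path).with_name(Path(path).name.split(".")[0] + ".json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return CouplingImage(
        coupling=data,
        mask=np.isfinite(data),
        n_modalities=int(provenance.get("n_modalities", 0)),
        fwhm_mm=float(provenance.get("fwhm_mm", float("nan"))),
        provenance=provenance,
    )
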