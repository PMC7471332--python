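"""NIfTI-1 volume I/O and run manifests."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .volume import ImageVolume

__all__ = ["read_volume", "write_volume", "VolumeReadError", "file_sha256", "write_json"]


class VolumeReadError(RuntimeError):
    """Raised when a file cannot be parsed as a 3D NIfTI volume."""


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), float32, RAS affine.

    The affine is diagonal in the voxel size with the first voxel center at
    half a voxel from the origin; data round-trips bit-exactly for float32.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.data, dtype=np.float32)
    img = nib.Nifti1Image(data, vol.affine())
    img.header.set_zooms(vol.voxel_size)
    if vol.units:
        img.header["descrip"] = vol.units.encode()[:79]
    nib.save(img, str(path))
    return path


def write_labels(labels: np.ndarray, voxel_size, path: str | Path) -> Path:
    """Write an integer label volume as NIfTI-1 (int16)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = np.diag([*voxel_size, 1.0])
    aff[:3, 3] = [0.5 * v for v in voxel_size]
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), aff)
    img.header.set_zooms(voxel_size)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, expect_units: str | None = None) -> ImageVolume:
    """Read a 3D NIfTI volume (plain or gzipped)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeReadError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim != 3:
        raise VolumeReadError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    units = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    if expect_units and units and units != expect_units:
        warnings.warn(f"{path}: units {units!r} differ from expected {expect_units!r}")
    return ImageVolume(np.asarray(data, dtype=float), zooms, units=units)


def read_labels(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise VolumeReadError(f"cannot read {path} as NIfTI: {exc}") from exc
    return np.asarray(np.rint(data), dtype=np.int32)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
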