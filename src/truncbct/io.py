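"""File formats: sinograms as HDF5, volumes as MetaImage/NIfTI, geometry as YAML."""

from __future__ import annotations

import h5py
import numpy as np
import SimpleITK as sitk
import yaml

from .geometry import SystemGeometry, build_geometry, geometry_to_config
from .projector import Sinogram
from .recon_fdk import ReconVolume

__all__ = [
    "save_sinogram", "load_sinogram",
    "save_volume", "load_volume",
    "save_geometry", "load_geometry",
]


def save_sinogram(sino: Sinogram, path) -> None:
    """HDF5 layout: /data, /mask datasets; geometry keys and domain as attributes."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=sino.data, compression="gzip")
        fh.create_dataset("mask", data=sino.validity_mask, compression="gzip")
        fh.attrs["domain"] = sino.domain
        if sino.i0 is not None:
            fh.attrs["i0"] = sino.i0
        for key, value in geometry_to_config(sino.geometry).items():
            fh.attrs[key] = value


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        mask = fh["mask"][()].astype(bool)
        attrs = dict(fh.attrs)
    domain = attrs.pop("domain", "line_integral")
    i0 = attrs.pop("i0", None)
    geom = build_geometry(attrs)
    return Sinogram(data=data, geometry=geom, validity_mask=mask,
                    domain=str(domain), i0=float(i0) if i0 is not None else None)


def save_volume(vol: ReconVolume | np.ndarray, path, voxel_size_mm: float | None = None):
    """Write a volume/slice as MetaImage (.mhd/.raw) or NIfTI by extension."""
    if isinstance(vol, ReconVolume):
        arr, vox = vol.values, vol.voxel_size
    else:
        arr, vox = np.asarray(vol), voxel_size_mm or 1.0
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float32))
    img.SetSpacing((vox,) * img.GetDimension())
    sitk.WriteImage(img, str(path))


def load_volume(path) -> tuple[np.ndarray, float]:
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img), float(img.GetSpacing()[0])


def save_geometry(geom: SystemGeometry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(geometry_to_config(geom), fh, sort_keys=False)


def load_geometry(path) -> SystemGeometry:
    with open(path) as fh:
        return build_geometry(yaml.safe_load(fh))
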