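"""NIfTI-backed container for masked 4D BOLD series."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class VolumeSeries:
    """4D BOLD data (x, y, z, t) with repetition time, brain mask and affine."""

    data: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial dims of data")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_vols(self) -> int:
        return self.data.shape[3]

    def masked(self) -> np.ndarray:
        """Time x voxel matrix of in-mask time series."""
        return self.data[self.mask].T


def write_nifti(vol: VolumeSeries, path, mask_path=None) -> None:
    img = nib.Nifti1Image(vol.data, vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine), str(mask_path))


def read_nifti(path, mask_path=None) -> VolumeSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    tr = float(img.header.get_zooms()[3])
    if mask_path is not None:
        mask = np.asanyarray(nib.load(str(mask_path)).dataobj).astype(bool)
        if mask.shape != data.shape[:3]:
            raise ValueError("mask spatial dims do not match the 4D volume")
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return VolumeSeries(data=data, tr=tr, mask=mask, affine=img.affine)


def write_mask(mask: np.ndarray, path, affine=None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8),
                             np.eye(4) if affine is None else affine), str(path))


def read_mask(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(bool)
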