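"""Thin NIfTI helpers: volumes, masks and 4D BOLD via nibabel."""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .bold import BoldSeries
from .grid import VolumeGrid

__all__ = ["load_volume", "load_mask", "load_bold", "save_volume", "save_bold"]


def load_volume(path):
    """Load a 3D (or squeezable) NIfTI volume; returns (data, grid)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D volume")
    return data, VolumeGrid.from_img(img)


def load_mask(path, grid: VolumeGrid | None = None) -> np.ndarray:
    data, g = load_volume(path)
    if grid is not None and g.dims != grid.dims:
        raise ValueError(f"mask grid {g.dims} does not match {grid.dims}")
    return data > 0


def load_bold(path, tr: float | None = None) -> BoldSeries:
    """Load 4D BOLD; TR from the NIfTI header zooms unless given."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D series")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
        if tr <= 0:
            raise ValueError(f"{path} has no TR in its header; pass tr explicitly")
    return BoldSeries(data, tr, VolumeGrid.from_img(img))


def save_volume(data: np.ndarray, grid: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), grid.affine), str(path))


def save_bold(b: BoldSeries, path) -> None:
    img = nib.Nifti1Image(b.data, b.grid.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = b.tr
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
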