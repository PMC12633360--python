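"""Volume grids and world<->voxel coordinate mapping.

A :class:`VolumeGrid` pairs integer array dimensions with a 4x4 affine that
maps 0-based voxel indices to world coordinates in millimetres (the NIfTI
convention).  Streamline vertices live in world mm; everything voxel-based
(masks, BOLD arrays, density maps) is indexed through this grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "world_to_voxel", "voxel_centers"]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D sampling grid: dimensions plus voxel-index -> world-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.linalg.det(aff[:3, :3]) < 0:
            warnings.warn(
                "grid affine is left-handed; TCK world coordinates are assumed "
                "to share the same frame, no re-orientation is applied",
                stacklevel=2,
            )
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge length of a voxel along each axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @classmethod
    def isotropic(cls, dims, voxel_mm: float = 2.0, origin=(0.0, 0.0, 0.0)) -> "VolumeGrid":
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        aff[:3, 3] = origin
        return cls(tuple(dims), aff)

    @classmethod
    def from_img(cls, img) -> "VolumeGrid":
        """Build from a nibabel spatial image (first three dims)."""
        return cls(tuple(img.shape[:3]), np.asarray(img.affine))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # ties go away from zero, so a point on a voxel-face boundary belongs to
    # the higher-magnitude index; deterministic, unlike banker's rounding
    return np.trunc(x + np.copysign(0.5, x))


def world_to_voxel(points, grid: VolumeGrid):
    """Map world-mm points to nearest 0-based voxel indices.

    Parameters
    ----------
    points : array-like, shape (n, 3) or (3,)
        Positions in world millimetres.
    grid : VolumeGrid

    Returns
    -------
    indices : int ndarray, shape (n, 3)
        Nearest voxel index per point (half-away-from-zero rounding).
    in_fov : bool ndarray, shape (n,)
        False where the index falls outside ``[0, dims)`` on any axis.
        Out-of-FOV points are flagged, never clamped.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 3:
        raise ValueError("points must have 3 components")
    inv = grid.inverse_affine
    cont = pts @ inv[:3, :3].T + inv[:3, 3]
    idx = _round_half_away(cont).astype(np.int64)
    dims = np.asarray(grid.dims)
    in_fov = np.all((idx >= 0) & (idx < dims), axis=1)
    return idx, in_fov


def voxel_centers(indices, grid: VolumeGrid) -> np.ndarray:
    """World-mm centre of each 0-based voxel index (inverse of rounding map)."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    return idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
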