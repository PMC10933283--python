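"""Voxel masks: sphere ROIs, circuit-neighborhood exclusion, feature
extraction, and top-fraction voxel selection for the extended circuit.

A :class:`VoxelMask` stores a strictly increasing list of linear (C-order)
voxel indices on a fixed grid; that ordering is the feature-space contract
decoders rely on when they are reapplied to external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .atlas import RegionAtlas
from .datasets import BetaMapSet, FeatureMatrix


@dataclass
class VoxelMask:
    indices: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("voxel index list must be strictly increasing")
        if self.indices.size and (self.indices[0] < 0 or
                                  self.indices[-1] >= int(np.prod(self.grid_shape))):
            raise ValueError("voxel index outside grid")

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    def volume(self) -> np.ndarray:
        vol = np.zeros(int(np.prod(self.grid_shape)), dtype=bool)
        vol[self.indices] = True
        return vol.reshape(self.grid_shape)

    @classmethod
    def from_volume(cls, volume: np.ndarray, affine: np.ndarray | None = None) -> "VoxelMask":
        volume = np.asarray(volume)
        return cls(np.flatnonzero(volume.ravel() != 0), volume.shape, affine)

    @classmethod
    def from_regions(cls, atlas: RegionAtlas, region_ids=None) -> "VoxelMask":
        ids = list(region_ids) if region_ids is not None else atlas.region_ids
        mask = np.isin(atlas.labels, ids)
        return cls.from_volume(mask, atlas.affine)

    def union(self, other: "VoxelMask") -> "VoxelMask":
        self._check_grid(other)
        return VoxelMask(np.union1d(self.indices, other.indices), self.grid_shape, self.affine)

    def mm_coordinates(self) -> np.ndarray:
        """(k, 3) mm coordinates of the voxel centers."""
        ijk = np.stack(np.unravel_index(self.indices, self.grid_shape), axis=1)
        hom = np.column_stack([ijk, np.ones(len(ijk))])
        return (hom @ self.affine.T)[:, :3]

    def _check_grid(self, other) -> None:
        if tuple(self.grid_shape) != tuple(other.grid_shape):
            raise ValueError("masks live on different grids")


def make_sphere_mask(center_mm, radius_mm: float, grid_shape, affine) -> VoxelMask:
    """Every voxel whose center lies within ``radius_mm`` of ``center_mm``."""
    center_mm = np.asarray(center_mm, dtype=float)
    inv = np.linalg.inv(affine)
    center_vox = (inv @ np.append(center_mm, 1.0))[:3]
    if np.any(center_vox < -0.5) or np.any(center_vox > np.asarray(grid_shape) - 0.5):
        raise ValueError(f"sphere center {center_mm} mm falls outside the grid")
    grids = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    ijk = np.stack([g.ravel() for g in grids], axis=1)
    centers = (np.column_stack([ijk, np.ones(len(ijk))]) @ affine.T)[:, :3]
    d2 = ((centers - center_mm) ** 2).sum(axis=1)
    inside = d2 <= radius_mm**2 + 1e-9
    # the voxel containing the center always belongs to the sphere, even when
    # the radius is smaller than the distance to the nearest voxel center
    containing = np.ravel_multi_index(
        tuple(int(round(v)) for v in np.clip(center_vox, 0, np.asarray(grid_shape) - 1)),
        grid_shape,
    )
    inside[containing] = True
    return VoxelMask(np.flatnonzero(inside), tuple(grid_shape), affine)


def exclude_with_neighborhood(
    base: VoxelMask, exclude: VoxelMask, radius_voxels: float = 3
) -> VoxelMask:
    """Remove from ``base`` all voxels within ``radius_voxels`` (Euclidean,
    voxel units) of any excluded voxel.

    This implements the whole-brain-minus-circuit feature construction: the
    threat-circuit voxels and a 3-voxel neighborhood around them are dropped
    so circuit signal cannot leak into the 'beyond the circuit' decoder.
    """
    base._check_grid(exclude)
    r = int(np.floor(radius_voxels))
    g = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(g, g, g, indexing="ij")
    ball = dx**2 + dy**2 + dz**2 <= radius_voxels**2 + 1e-12
    dilated = ndimage.binary_dilation(exclude.volume(), structure=ball)
    keep = base.volume() & ~dilated
    return VoxelMask.from_volume(keep, base.affine)


def extract_features(betas: BetaMapSet, selector) -> FeatureMatrix:
    """Concatenate masked voxels into feature vectors.

    ``selector`` is a :class:`VoxelMask`, a :class:`RegionAtlas` (all its
    regions), or ``(atlas, region_ids)``. Column order follows the stored
    strictly increasing voxel order, making extraction bit-stable and
    invertible (see :func:`scatter_features`). For atlas selectors with an
    explicit region list, columns are grouped region by region so regional
    weight slices stay contiguous.
    """
    if betas.grid_shape is None:
        raise ValueError("feature extraction requires a grid-backed dataset")
    if isinstance(selector, VoxelMask):
        if tuple(selector.grid_shape) != tuple(betas.grid_shape):
            raise ValueError("mask and dataset live on different grids")
        cols = selector.indices
    elif isinstance(selector, RegionAtlas):
        cols = VoxelMask.from_regions(selector).indices
    else:
        atl, region_ids = selector
        cols = np.concatenate([atl.voxel_indices_of(r) for r in region_ids])
    if cols.size == 0:
        raise ValueError("empty voxel selector")
    return FeatureMatrix(
        X=betas.values[:, :, cols],
        participants=list(betas.participants),
        conditions=list(betas.conditions),
        voxel_indices=np.asarray(cols),
        grid_shape=betas.grid_shape,
        site=betas.site,
    )


def scatter_features(features: FeatureMatrix, fill: float = 0.0) -> np.ndarray:
    """Scatter features back onto the full grid: (N, C, V_grid) array."""
    n, c, _ = features.X.shape
    v = int(np.prod(features.grid_shape))
    out = np.full((n, c, v), fill)
    out[:, :, features.voxel_indices] = features.X
    return out


def select_top_voxels(
    p_values: np.ndarray, base_mask: VoxelMask, fraction: float = 0.10
) -> VoxelMask:
    """Top-fraction voxels by mean ``-log(p)`` across scored trial-blocks.

    ``p_values`` is (n_blocks, k) aligned with ``base_mask.indices``; the
    canonical use scores the 7 robust trial-blocks. Returns the
    ``ceil(fraction * k)`` voxels with the largest mean natural-log
    contribution score; ties break toward the lower voxel index.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 2 or p.shape[1] != base_mask.n_voxels:
        raise ValueError("p_values must be (n_blocks, n_mask_voxels)")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; a zero signals an upstream floor violation")
    score = -np.log(p).mean(axis=0)
    k = int(np.ceil(fraction * base_mask.n_voxels))
    # stable sort on (-score, index): equal scores keep lower index first
    order = np.argsort(-score, kind="stable")[:k]
    return VoxelMask(np.sort(base_mask.indices[order]), base_mask.grid_shape, base_mask.affine)
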