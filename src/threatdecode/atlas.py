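"""Labeled region atlases on a voxel grid.

A :class:`RegionAtlas` couples an integer label volume (0 = background) with
a voxel-to-mm affine and a region table recording each region's size, whether
it belongs to the a-priori threat circuit or the extended set, and (when
known) its coding community. Real atlases are consumed from NIfTI + TSV;
:func:`generate_synthetic_atlas` builds a synthetic stand-in with disjoint
compact regions for fully self-contained analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

THREAT_CIRCUIT_SET = "threat_circuit"
EXTENDED_SET = "extended"


def default_affine(shape: tuple[int, int, int], voxel_size_mm: float = 2.0) -> np.ndarray:
    """Isotropic affine with the mm origin at the grid center (2 mm default)."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    return aff


@dataclass(frozen=True)
class Region:
    id: int
    name: str
    size: int                  # v_i, voxel count
    set: str                   # threat_circuit | extended
    community: str | None = None


@dataclass
class RegionAtlas:
    """Integer label volume plus region metadata and voxel<->mm geometry."""

    labels: np.ndarray
    affine: np.ndarray
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids) or any(i <= 0 for i in ids):
            raise ValueError("region ids must be positive and unique")
        for r in self.regions:
            n = int((self.labels == r.id).sum())
            if n != r.size:
                raise ValueError(f"region {r.id}: table size {r.size} != label count {n}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.labels.size)

    @property
    def region_ids(self) -> list[int]:
        return [r.id for r in self.regions]

    def region(self, region_id: int) -> Region:
        for r in self.regions:
            if r.id == region_id:
                return r
        raise KeyError(f"no region with id {region_id}")

    def voxel_indices_of(self, region_id: int) -> np.ndarray:
        """Strictly increasing linear (C-order) indices of one region."""
        idx = np.flatnonzero(self.labels.ravel() == region_id)
        if idx.size == 0:
            raise KeyError(f"region {region_id} absent from label volume")
        return idx

    def regions_in_set(self, which: str) -> list[Region]:
        return [r for r in self.regions if r.set == which]

    def region_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.id, r.name, r.size, r.set, r.community or "") for r in self.regions],
            columns=["id", "name", "size", "set", "community"],
        )

    # ------------------------------------------------------------------ I/O
    def save(self, nifti_path, table_path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), self.affine), str(nifti_path))
        self.region_table().to_csv(table_path, sep="\t", index=False)

    @classmethod
    def load(cls, nifti_path, table_path) -> "RegionAtlas":
        img = nib.load(str(nifti_path))
        table = pd.read_csv(table_path, sep="\t", keep_default_na=False)
        regions = [
            Region(int(row["id"]), str(row["name"]), int(row["size"]),
                   str(row["set"]), str(row["community"]) or None)
            for _, row in table.iterrows()
        ]
        return cls(np.asarray(img.dataobj).astype(int), img.affine, regions)


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    g = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(g, g, g, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2 + 1e-12
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def generate_synthetic_atlas(
    grid_shape: tuple[int, int, int],
    n_circuit: int,
    n_extended: int,
    seed: int,
    region_radius_voxels: float = 1.5,
    voxel_size_mm: float = 2.0,
) -> RegionAtlas:
    """Place ``n_circuit + n_extended`` disjoint spherical regions at random.

    Regions are labeled 1..n with the threat-circuit regions first. Placement
    is greedy with rejection; a grid too small to host all regions raises.
    Deterministic for a fixed seed.
    """
    shape = tuple(int(s) for s in grid_shape)
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    offsets = _ball_offsets(region_radius_voxels)
    n_total = n_circuit + n_extended
    regions: list[Region] = []

    for rid in range(1, n_total + 1):
        placed = False
        for _ in range(2000):
            center = np.array([rng.integers(0, s) for s in shape])
            vox = center + offsets
            inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
            vox = vox[inside]
            if vox.shape[0] == 0 or labels[tuple(vox.T)].any():
                continue
            labels[tuple(vox.T)] = rid
            which = THREAT_CIRCUIT_SET if rid <= n_circuit else EXTENDED_SET
            prefix = "circuit" if rid <= n_circuit else "ext"
            regions.append(Region(rid, f"{prefix}_{rid:02d}", int(vox.shape[0]), which))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"grid {shape} too small to place region {rid} of {n_total} "
                f"(radius {region_radius_voxels} voxels)"
            )
    return RegionAtlas(labels, default_affine(shape, voxel_size_mm), regions)
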