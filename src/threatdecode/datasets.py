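"""The activation-map container shared by every analysis stage.

A :class:`BetaMapSet` holds GLM beta estimates as a dense
participant x condition x voxel array. Grid-backed sets carry the atlas
geometry (shape + affine) with the voxel axis enumerating the full grid in
C order, so voxel masks index columns directly; abstract sets (no geometry)
are plain feature spaces, convenient for simulation studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .conditions import Condition


@dataclass
class BetaMapSet:
    """Per-participant, per-condition voxel activation estimates."""

    values: np.ndarray                      # (N, C, V)
    participants: list[str]
    conditions: list[Condition]
    grid_shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None
    site: np.ndarray | None = None          # per-participant integer site id

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (participants, conditions, voxels)")
        n, c, v = self.values.shape
        if len(self.participants) != n or len(self.conditions) != c:
            raise ValueError("participant/condition labels do not match values shape")
        if len(set(self.conditions)) != c:
            raise ValueError("condition labels must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("beta values must be finite (no missing values)")
        if self.grid_shape is not None and int(np.prod(self.grid_shape)) != v:
            raise ValueError("grid shape does not match the voxel axis")
        if self.site is None:
            self.site = np.zeros(n, dtype=int)
        self.site = np.asarray(self.site, dtype=int)
        if self.site.shape != (n,):
            raise ValueError("site must give one id per participant")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]

    def condition_index(self, condition: Condition) -> int:
        try:
            return self.conditions.index(condition)
        except ValueError:
            raise KeyError(f"condition {condition.label} absent from dataset") from None

    def maps(self, condition: Condition) -> np.ndarray:
        """(N, V) activation maps for one condition."""
        return self.values[:, self.condition_index(condition), :]

    def subset_participants(self, index: np.ndarray) -> "BetaMapSet":
        index = np.asarray(index)
        return BetaMapSet(
            self.values[index],
            [self.participants[i] for i in index],
            list(self.conditions),
            self.grid_shape,
            self.affine,
            self.site[index],
        )

    # ------------------------------------------------------------------ I/O
    def save_nifti_dir(self, directory) -> None:
        """One 4-D NIfTI per participant (condition volumes) + sidecars."""
        if self.grid_shape is None:
            raise ValueError("only grid-backed datasets serialize to NIfTI")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "conditions.json", "w") as fh:
            json.dump([c.label for c in self.conditions], fh, indent=1)
        pd.DataFrame({"participant": self.participants, "site": self.site}).to_csv(
            directory / "participants.tsv", sep="\t", index=False
        )
        for i, pid in enumerate(self.participants):
            vol = self.values[i].T.reshape(*self.grid_shape, len(self.conditions))
            nib.save(nib.Nifti1Image(vol.astype(np.float32), self.affine),
                     str(directory / f"{pid}_betas.nii.gz"))

    @classmethod
    def load_nifti_dir(cls, directory) -> "BetaMapSet":
        directory = Path(directory)
        with open(directory / "conditions.json") as fh:
            conditions = [Condition.from_label(s) for s in json.load(fh)]
        table = pd.read_csv(directory / "participants.tsv", sep="\t")
        participants = [str(p) for p in table["participant"]]
        site = table["site"].to_numpy()
        values, affine, shape = [], None, None
        for pid in participants:
            img = nib.load(str(directory / f"{pid}_betas.nii.gz"))
            affine, shape = img.affine, img.shape[:3]
            vol = np.asarray(img.dataobj, dtype=float)
            values.append(vol.reshape(-1, vol.shape[3]).T)
        return cls(np.stack(values), participants, conditions, tuple(shape), affine, site)


@dataclass
class FeatureMatrix:
    """Masked voxel features with an invertible voxel-index record.

    ``X[p, c]`` is the feature vector of participant ``p`` under condition
    ``c``; columns follow the stored strictly increasing voxel order, which
    also defines ``feature_space_id`` — the contract that lets a decoder
    trained on one dataset score another.
    """

    X: np.ndarray                           # (N, C, k)
    participants: list[str]
    conditions: list[Condition]
    voxel_indices: np.ndarray               # (k,) linear indices, or arange for abstract sets
    grid_shape: tuple[int, int, int] | None
    site: np.ndarray | None = None

    @property
    def feature_space_id(self) -> str:
        import hashlib

        h = hashlib.sha1()
        h.update(repr(self.grid_shape).encode())
        h.update(np.ascontiguousarray(self.voxel_indices, dtype=np.int64).tobytes())
        return h.hexdigest()[:16]

    def pairs(self, contrast) -> tuple[np.ndarray, np.ndarray]:
        """(X_pos, X_neg) feature pairs for one contrast, participant-aligned."""
        ip = self.conditions.index(contrast.positive)
        im = self.conditions.index(contrast.negative)
        return self.X[:, ip, :], self.X[:, im, :]

    def rows(self) -> tuple[np.ndarray, list[tuple[str, Condition]]]:
        """Flatten to (participant, condition) rows with their labels."""
        n, c, k = self.X.shape
        labels = [(p, cond) for p in self.participants for cond in self.conditions]
        return self.X.reshape(n * c, k), labels
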