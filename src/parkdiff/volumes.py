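"""Scalar volumes and label atlases in a common space.

All maps the pipeline consumes are already spatially aligned: a
:class:`ScalarVolume` is a 3-D grid of finite reals with physical voxel
dimensions, and a :class:`LabelAtlas` is an integer parcellation of the same
grid plus a region table (label id, name, tissue class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["ScalarVolume", "LabelAtlas", "load_volume", "save_volume",
           "load_atlas", "save_atlas"]


@dataclass
class ScalarVolume:
    """A 3-D scalar map with voxel dimensions in mm."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    space_tag: str = "common"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("volume must be a non-empty 3-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def same_grid(self, other: "ScalarVolume | LabelAtlas") -> bool:
        oshape = other.values.shape if isinstance(other, ScalarVolume) else other.labels.shape
        ovox = other.voxel_size
        return self.shape == oshape and np.allclose(self.voxel_size, ovox)


@dataclass
class LabelAtlas:
    """Integer parcellation (0 = background) with a region table.

    ``regions`` has columns ``label`` (int), ``name`` (str) and
    ``tissue`` (GM or WM). Cortical grey-matter regions carry "cortical"
    in their name so a thickness-style cortical filter can select them.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    name: str = "atlas"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        ids = self.regions["label"].to_numpy()
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate label ids in region table")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(int(i) for i in ids)
        if missing:
            raise ValueError(f"voxel labels missing from region table: {sorted(missing)}")

    def region_labels(self, tissue: str | None = None, cortical_only: bool = False) -> list[int]:
        """Sorted label ids, optionally filtered by tissue class / cortical name tag."""
        tbl = self.regions
        if tissue is not None:
            tbl = tbl[tbl["tissue"] == tissue]
        if cortical_only:
            tbl = tbl[tbl["name"].str.contains("cortical") & ~tbl["name"].str.contains("subcortical")]
        return sorted(int(v) for v in tbl["label"])


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def save_volume(vol: ScalarVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.voxel_size)), str(path))


def load_volume(path: str | Path, space_tag: str = "common") -> ScalarVolume:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(np.asarray(img.get_fdata(), dtype=float), vox, space_tag)


def save_atlas(atlas: LabelAtlas, nifti_path: str | Path, table_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size)),
             str(nifti_path))
    atlas.regions.to_csv(table_path, index=False, columns=["label", "name", "tissue"])


def load_atlas(nifti_path: str | Path, table_path: str | Path, name: str = "atlas") -> LabelAtlas:
    img = nib.load(str(nifti_path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = np.asarray(img.get_fdata()).round().astype(int)
    regions = pd.read_csv(table_path)
    return LabelAtlas(labels, regions, vox, name=name)
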