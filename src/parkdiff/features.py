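"""Feature extraction: atlas-ROI means, masked-voxel PCA, z-scoring.

Two extraction routes turn aligned scalar maps into a subjects x features
matrix: (i) the mean map value within each atlas region (one feature per
region, ordered by label id), and (ii) principal component analysis over the
voxels inside a mask, retaining at most N-1 components for N training
subjects. Feature normalization (z-scoring) and the PCA basis can be fit on
training subjects only and applied to held-out subjects (leakage-safe), or
fit jointly on all subjects (paper mode) for bias-comparison experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import LabelAtlas, ScalarVolume

__all__ = ["FeatureMatrix", "PCABasis", "build_mask", "extract_roi_features",
           "roi_feature_matrix", "masked_voxels", "fit_pca", "pca_project",
           "normalize_features"]

log = logging.getLogger(__name__)

MODALITY_TAGS = ("GMvol", "CT", "FA", "MD", "PC")


@dataclass
class FeatureMatrix:
    """Subjects x named features; column names are ``TAG:name``.

    The modality tag prefix (GMvol, CT, FA, MD or PC) travels with each
    column so downstream weight localization can treat FA and MD jointly.
    """

    data: pd.DataFrame                       # index = subject ids
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def modality(self, name: str) -> str:
        return name.split(":", 1)[0]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def rows(self, ids) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[list(ids)], dict(self.provenance))

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if list(other.data.index) != list(self.data.index):
            raise ValueError("subject order differs between matrices")
        prov = {**self.provenance, **other.provenance}
        return FeatureMatrix(pd.concat([self.data, other.data], axis=1), prov)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls(pd.read_csv(path, index_col="id"))


def build_mask(maps: "list[ScalarVolume] | ScalarVolume", kind: str,
               threshold: float) -> ScalarVolume:
    """Binary mask from a mean map or a template map.

    ``mean-threshold``: voxel kept iff the cross-subject mean exceeds
    ``threshold`` (strict >, the grey-matter convention at P = 0.1).
    ``template-threshold``: voxel kept iff the template value is at least
    ``threshold`` (>=, the FA-template convention at 0.2).
    """
    if kind == "mean-threshold":
        if isinstance(maps, ScalarVolume):
            maps = [maps]
        ref = maps[0]
        for m in maps[1:]:
            if not ref.same_grid(m):
                raise ValueError("maps do not share a grid")
        mean = np.mean([m.values for m in maps], axis=0)
        mask = mean > threshold
    elif kind == "template-threshold":
        if not isinstance(maps, ScalarVolume):
            raise ValueError("template-threshold expects a single template volume")
        ref = maps
        mask = maps.values >= threshold
    else:
        raise ValueError(f"unknown mask kind {kind!r}")
    if not mask.any():
        raise ValueError("no voxels survive threshold")
    return ScalarVolume(mask.astype(float), ref.voxel_size, ref.space_tag)


def extract_roi_features(map_: ScalarVolume, atlas: LabelAtlas,
                         tissue_filter: str = "GM",
                         cortical_only: bool = False) -> pd.Series:
    """Mean map value per atlas region, ordered by ascending label id."""
    if map_.shape != atlas.labels.shape:
        raise ValueError("map and atlas do not share a grid")
    labels = atlas.region_labels(tissue_filter, cortical_only=cortical_only)
    flat_lab = atlas.labels.ravel()
    flat_val = map_.values.ravel()
    counts = np.bincount(flat_lab, minlength=max(labels) + 1)
    sums = np.bincount(flat_lab, weights=flat_val, minlength=max(labels) + 1)
    out = {}
    for lbl in labels:
        if counts[lbl] == 0:
            raise ValueError(f"region {lbl} has zero voxels")
        name = atlas.regions.loc[atlas.regions["label"] == lbl, "name"].iloc[0]
        out[name] = sums[lbl] / counts[lbl]
    return pd.Series(out, dtype=float)


def roi_feature_matrix(maps: dict[str, ScalarVolume], atlas: LabelAtlas,
                       modality_tag: str, tissue_filter: str = "GM",
                       cortical_only: bool = False) -> FeatureMatrix:
    """Stack per-subject ROI features into a FeatureMatrix with tagged columns."""
    rows = {sid: extract_roi_features(v, atlas, tissue_filter, cortical_only)
            for sid, v in maps.items()}
    frame = pd.DataFrame(rows).T
    frame.columns = [f"{modality_tag}:{c}" for c in frame.columns]
    return FeatureMatrix(frame, {"method": "roi", "atlas": atlas.name,
                                 "tissue": tissue_filter})


def masked_voxels(maps: dict[str, ScalarVolume], mask: ScalarVolume) -> pd.DataFrame:
    """Per-subject vectors of the voxels inside the mask (ascending linear index)."""
    m = mask.values > 0
    rows = {}
    for sid, vol in maps.items():
        if vol.shape != m.shape:
            raise ValueError(f"map for {sid} does not match the mask grid")
        rows[sid] = vol.values[m]  # C-order traversal: fixed, reproducible
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PCABasis:
    """Training-set PCA basis over masked voxels."""

    mean: np.ndarray
    components: np.ndarray           # (n_components, n_voxels), orthonormal rows
    explained_variance: np.ndarray
    mask_id: str
    training_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained variances must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(training: pd.DataFrame, mask_id: str = "mask",
            rel_tol: float = 1e-10) -> PCABasis:
    """PCA of training subjects' masked-voxel vectors.

    Centering uses the training mean; components are covariance eigenvectors
    computed by SVD of the centered matrix (efficient when voxels greatly
    outnumber subjects). Components with (numerically) zero variance are
    dropped, so at most N-1 components survive for N training subjects.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training subjects")
    x = training.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    xc = x - mean
    # thin SVD: N x V with N << V
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (len(x) - 1)
    keep = var > rel_tol * max(var[0], 1e-300) if len(var) else np.array([], bool)
    keep &= s > 0
    return PCABasis(mean, vt[keep], var[keep], mask_id, list(training.index))


def pca_project(basis: PCABasis, vectors: pd.DataFrame) -> FeatureMatrix:
    """Project subjects onto the basis using the *training* mean and directions."""
    x = vectors.to_numpy(dtype=float)
    if x.shape[1] != basis.mean.shape[0]:
        raise ValueError("mask size differs between fit and project")
    scores = (x - basis.mean) @ basis.components.T
    cols = [f"PC:{basis.mask_id}_{i + 1:03d}" for i in range(basis.n_components)]
    frame = pd.DataFrame(scores, index=vectors.index, columns=cols)
    return FeatureMatrix(frame, {"method": "pca", "mask": basis.mask_id,
                                 "training_ids": list(basis.training_ids)})


def normalize_features(train: FeatureMatrix, *others: FeatureMatrix
                       ) -> tuple[list[FeatureMatrix], pd.DataFrame]:
    """Z-score every matrix by the training columns' mean and sample sd.

    Columns with zero training sd carry no information and are dropped from
    every matrix (logged). Returns ([train_z, *others_z], stats_table).
    """
    for o in others:
        if list(o.data.columns) != list(train.data.columns):
            raise ValueError("matrices must share columns")
    if len(train.data) < 2:
        raise ValueError("training matrix needs at least 2 rows")
    mean = train.data.mean(axis=0)
    sd = train.data.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns have zero training standard deviation")
    dropped = list(sd.index[~keep])
    if dropped:
        log.warning("dropping %d zero-variance feature(s): %s",
                    len(dropped), dropped[:5])
    stats_table = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    out = []
    for fm in (train, *others):
        z = (fm.data.loc[:, keep] - mean[keep]) / sd[keep]
        out.append(FeatureMatrix(z, {**fm.provenance, "normalized": True}))
    return out, stats_table
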