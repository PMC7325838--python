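"""Accuracy-curve summaries and anatomical localization of SVM weights.

Accuracy curves (accuracy vs number of ranked features) are condensed to
mean, maximum and inter-quartile range in percent. The weights of a linear
SVM are mapped back to atlas regions: ROI features map one-to-one, PCA
component weights are back-projected through the basis to voxel space and
averaged per region. Weights are rescaled so the most useful feature has
normalized weight 1; FA and MD can be rescaled jointly so a single top
diffusion feature carries weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import AccuracyCurve
from .features import PCABasis
from .volumes import LabelAtlas, ScalarVolume

__all__ = ["CurveSummary", "WeightMap", "summarize_curve", "best_k",
           "weight_localization", "pca_weight_localization",
           "export_weight_volume"]


@dataclass
class CurveSummary:
    """Mean/max/IQR of an accuracy curve, in percent."""

    label: str
    mean: float
    max: float
    iqr: float
    modality: str = ""
    method: str = ""
    validation: str = "cv"
    quartile_convention: str = "linear-interpolation"

    def __post_init__(self) -> None:
        if self.max < self.mean - 1e-9:
            raise ValueError("max accuracy cannot be below the mean")
        if self.iqr < 0:
            raise ValueError("IQR must be non-negative")


def summarize_curve(curve: AccuracyCurve, modality: str = "", method: str = "",
                    validation: str = "cv") -> CurveSummary:
    """Summarize per-k accuracies as mean, max and IQR in percent.

    Quartiles use linear interpolation; the convention is recorded in the
    output so summaries remain auditable.
    """
    acc = 100.0 * np.asarray(curve.accuracy, dtype=float)
    if acc.size == 0:
        raise ValueError("empty accuracy curve")
    q1, q3 = np.percentile(acc, [25, 75])  # linear interpolation
    return CurveSummary(curve.label, float(acc.mean()), float(acc.max()),
                        float(q3 - q1), modality, method, validation)


def best_k(curve: AccuracyCurve) -> int:
    """The feature count maximizing accuracy; ties resolved to the smallest k."""
    acc = np.asarray(curve.accuracy)
    return int(curve.ks[int(np.argmax(acc))])


@dataclass
class WeightMap:
    """Normalized (max = 1) per-feature weights and per-region aggregation."""

    per_feature: pd.Series              # index = feature names, values in [0, 1]
    per_region: pd.Series               # index = region names
    modalities: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.per_feature < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.isclose(self.per_feature.max(), 1.0):
            raise ValueError("maximum normalized weight must be exactly 1")


def _normalize(absw: pd.Series, joint_dti: bool) -> pd.Series:
    """Rescale |w| so each modality's top feature has weight 1; with
    ``joint_dti`` FA and MD share one rescaling (single top diffusion
    feature)."""
    tags = pd.Series([f.split(":", 1)[0] for f in absw.index], index=absw.index)
    scale_group = tags.replace({"FA": "DTI", "MD": "DTI"}) if joint_dti else tags
    out = absw.copy().astype(float)
    for g in scale_group.unique():
        sel = scale_group == g
        m = absw[sel].max()
        if m == 0:
            raise ValueError(f"all-zero weight vector for modality group {g}")
        out[sel] = absw[sel] / m
    return out


def weight_localization(weights: pd.Series, mapping: dict[str, str],
                        joint_dti: bool = False) -> WeightMap:
    """Localize ROI-feature SVM weights to atlas regions.

    ``weights`` is the linear SVM weight vector (one entry per ``TAG:name``
    feature); ``mapping`` sends each feature to its region name. Importance
    is the absolute weight, rescaled so the top feature of each modality
    (or of FA and MD jointly) is 1; a region with both an FA and an MD
    feature keeps the larger of the two.
    """
    if (weights == 0).all():
        raise ValueError("all-zero weight vector")
    missing = [f for f in weights.index if f not in mapping]
    if missing:
        raise ValueError(f"mapping does not cover features: {missing[:5]}")
    norm = _normalize(weights.abs(), joint_dti)
    regions = pd.Series({f: mapping[f] for f in norm.index})
    per_region = norm.groupby(regions).max()
    modalities = {f: f.split(":", 1)[0] for f in norm.index}
    return WeightMap(norm, per_region, modalities)


def pca_weight_localization(weights: pd.Series, basis: PCABasis,
                            atlas: LabelAtlas, mask: ScalarVolume,
                            tissue: str | None = None) -> WeightMap:
    """Localize PCA-component SVM weights to regions.

    The component weights are back-projected to voxel space
    (|sum_k w_k * component_k|) and the per-region mean absolute loading is
    taken over each region's in-mask voxels, then rescaled to a maximum of 1.
    """
    if (weights == 0).all():
        raise ValueError("all-zero weight vector")
    if len(weights) > basis.n_components:
        raise ValueError("more weights than basis components")
    w = weights.to_numpy(dtype=float)
    voxel_w = np.abs(w @ basis.components[:len(w)])
    m = mask.values > 0
    lab = atlas.labels[m]
    out = {}
    for lbl in atlas.region_labels(tissue):
        sel = lab == lbl
        if sel.any():
            name = atlas.regions.loc[atlas.regions["label"] == lbl, "name"].iloc[0]
            out[lbl] = (name, float(voxel_w[sel].mean()))
    per_region = pd.Series({name: v for name, v in out.values()})
    top = per_region.max()
    if top == 0:
        raise ValueError("all-zero back-projected weights")
    per_region = per_region / top
    per_feature = weights.abs() / weights.abs().max()
    return WeightMap(per_feature, per_region,
                     {f: "PC" for f in weights.index})


def export_weight_volume(wmap: WeightMap, atlas: LabelAtlas) -> ScalarVolume:
    """Fill each region's voxels with its normalized weight (background 0)."""
    if wmap.per_region.empty:
        raise ValueError("empty weight map")
    name_to_label = dict(zip(atlas.regions["name"], atlas.regions["label"]))
    out = np.zeros(atlas.labels.shape, dtype=float)
    for region, w in wmap.per_region.items():
        if region not in name_to_label:
            raise ValueError(f"region {region!r} not in atlas")
        out[atlas.labels == name_to_label[region]] = w
    return ScalarVolume(out, atlas.voxel_size, atlas.name)
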