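"""End-to-end orchestration: simulate -> QC -> match -> extract -> classify
-> validate -> report, driven by one YAML config.

Each stage writes its outputs to files in the run directory so stages can be
re-run independently; every artifact is tied to the run by a config hash in
the manifest. Re-running with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from . import design, qc as qcmod
from .classify import CVConfig, SVMConfig, independent_validation, leave_two_out_cv, pair_label
from .features import (FeatureMatrix, build_mask, masked_voxels,
                       roi_feature_matrix)
from .report import best_k, export_weight_volume, summarize_curve, weight_localization
from .volumes import LabelAtlas, ScalarVolume, load_atlas, load_volume, save_atlas, save_volume

__all__ = ["RunConfig", "run_pipeline", "stage_simulate", "stage_qc",
           "stage_match", "stage_extract", "stage_classify", "stage_validate",
           "stage_report", "load_config"]

log = logging.getLogger(__name__)

GROUP_PAIRS = list(combinations(coh.GROUPS, 2))


@dataclass
class RunConfig:
    """One experimental cell of the method x modality grid."""

    out_dir: str = "run"
    seed: int = 0
    n_per_group: int = 8                 # simulated subjects per group
    n_cv_per_group: int = 6              # matched cross-validation selection
    atlas_shape: tuple[int, int, int] = (24, 24, 16)
    n_gm: int = 8
    n_wm: int = 8
    n_cortical: int = 6
    effect_strength: float = 1.0
    method: str = "roi"                  # roi | pca
    modality: str = "gm"                 # gm | ct | dti | gm+dti
    mode: str = "safe"                   # safe | paper
    folds: "str | int" = "exhaustive"
    k_max: int | None = None
    svm_c: float = 1.0
    covariates: tuple[str, ...] = ("age", "sex", "t1_fwhm",
                                   "mean_abs_disp", "mean_rel_disp", "updrs3")
    gm_mask_threshold: float = 0.1
    fa_mask_threshold: float = 0.2

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "atlas_shape" in raw:
        raw["atlas_shape"] = tuple(raw["atlas_shape"])
    if "covariates" in raw:
        raw["covariates"] = tuple(raw["covariates"])
    return RunConfig(**raw)


def _dirs(config: RunConfig) -> dict[str, Path]:
    out = Path(config.out_dir)
    d = {"root": out, "maps": out / "maps", "motion": out / "motion",
         "features": out / "features", "curves": out / "curves",
         "report": out / "report"}
    for p in d.values():
        p.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(config: RunConfig) -> None:
    """Generate the synthetic cohort and write all inputs to disk."""
    d = _dirs(config)
    atlas = coh.make_fixture_atlas(config.atlas_shape, n_gm=config.n_gm,
                                   n_wm=config.n_wm, n_cortical=config.n_cortical)
    spec = coh.default_effects(atlas, strength=config.effect_strength)
    cohort = coh.generate_cohort(spec, config.n_per_group, atlas, config.seed)
    design.fill_tiv(cohort)
    save_atlas(atlas, d["root"] / "atlas.nii", d["root"] / "atlas_regions.csv")
    cohort.subject_frame().to_csv(d["root"] / "subjects.csv", index=False)
    striped_rows = []
    for sid, mod_maps in cohort.maps.items():
        for mod, vol in mod_maps.items():
            save_volume(vol, d["maps"] / f"{sid}_{mod}.nii")
    for sid, mlog in cohort.motion_logs.items():
        coh.save_motion_log(mlog, d["motion"] / f"{sid}.txt")
        for idx in sorted(mlog.striped):
            striped_rows.append({"id": sid, "volume": idx})
    pd.DataFrame(striped_rows, columns=["id", "volume"]).to_csv(
        d["motion"] / "striped.csv", index=False)


def _load_cohort_tables(config: RunConfig):
    d = _dirs(config)
    subjects = pd.read_csv(d["root"] / "subjects.csv")
    atlas = load_atlas(d["root"] / "atlas.nii", d["root"] / "atlas_regions.csv")
    return d, subjects, atlas


def stage_qc(config: RunConfig) -> None:
    """Compute motion metrics and apply the exclusion rules."""
    d, subjects, atlas = _load_cohort_tables(config)
    striped = pd.read_csv(d["motion"] / "striped.csv")
    mask = atlas.labels > 0
    qcs = []
    for _, row in subjects.iterrows():
        sid = row["id"]
        t1 = load_volume(d["maps"] / f"{sid}_t1.nii")
        stripes = striped.loc[striped["id"] == sid, "volume"].tolist()
        mlog = coh.load_motion_log(d["motion"] / f"{sid}.txt", sid, stripes)
        axes, combined = qcmod.estimate_smoothness_fwhm(t1, mask)
        a, r, _ = qcmod.displacement_metrics(mlog)
        qcs.append(qcmod.SubjectQC(sid, combined, axes, a, r,
                                   len(mlog.striped), group=row["group"]))
    report = qcmod.apply_exclusion_rules(qcs)
    report.as_frame().to_csv(d["root"] / "qc.csv", index=False)
    with open(d["root"] / "qc_summary.json", "w") as fh:
        json.dump({"cohort_stats": report.cohort_stats,
                   "n_excluded": len(report.excluded),
                   "excluded": report.excluded}, fh, indent=2)


def stage_match(config: RunConfig) -> None:
    """Select the matched equal-sized cross-validation groups."""
    d, subjects, _ = _load_cohort_tables(config)
    qc_table = pd.read_csv(d["root"] / "qc.csv")
    merged = subjects.merge(
        qc_table[["id", "t1_fwhm", "mean_abs_disp", "mean_rel_disp", "retained"]],
        on="id")
    retained = merged[merged["retained"]].drop(columns="retained")
    report = design.select_matched_groups(
        retained, config.n_cv_per_group, list(config.covariates),
        seed=config.seed)
    cv_ids = sorted(i for ids in report.selected.values() for i in ids)
    val_ids = sorted(set(retained["id"]) - set(cv_ids))
    with open(d["root"] / "match.json", "w") as fh:
        json.dump({
            "selected": report.selected,
            "validation_ids": val_ids,
            "tests": {c: {"route": t.route, "p": t.p, "statistic": t.statistic,
                          "rationale": t.rationale}
                      for c, t in report.tests.items()},
            "passed": report.passed, "alpha": report.alpha,
            "seed": report.seed}, fh, indent=2)


def _subject_maps(d: dict[str, Path], ids: list[str], modality: str
                  ) -> dict[str, ScalarVolume]:
    return {sid: load_volume(d["maps"] / f"{sid}_{modality}.nii") for sid in ids}


def _roi_features(d, atlas: LabelAtlas, ids: list[str], modality: str) -> FeatureMatrix:
    if modality == "gm":
        return roi_feature_matrix(_subject_maps(d, ids, "gm"), atlas, "GMvol", "GM")
    if modality == "ct":
        return roi_feature_matrix(_subject_maps(d, ids, "ct"), atlas, "CT", "GM",
                                  cortical_only=True)
    if modality == "dti":
        fa = roi_feature_matrix(_subject_maps(d, ids, "fa"), atlas, "FA", "WM")
        md = roi_feature_matrix(_subject_maps(d, ids, "md"), atlas, "MD", "WM")
        return fa.hstack(md)
    if modality == "gm+dti":
        return _roi_features(d, atlas, ids, "gm").hstack(
            _roi_features(d, atlas, ids, "dti"))
    raise ValueError(f"unknown modality {modality!r}")


def _voxel_features(d, atlas: LabelAtlas, cv_ids: list[str], ids: list[str],
                    config: RunConfig) -> pd.DataFrame:
    """Masked-voxel vectors for the PCA route; masks built on the CV cohort."""
    modality = config.modality
    if modality in ("gm", "ct"):
        mask = build_mask(list(_subject_maps(d, cv_ids, "gm").values()),
                          "mean-threshold", config.gm_mask_threshold)
        return masked_voxels(_subject_maps(d, ids, modality), mask)
    if modality == "dti":
        fa_maps = _subject_maps(d, cv_ids, "fa")
        template = ScalarVolume(np.mean([m.values for m in fa_maps.values()], axis=0),
                                atlas.voxel_size, atlas.name)
        mask = build_mask(template, "template-threshold", config.fa_mask_threshold)
        fa = masked_voxels(_subject_maps(d, ids, "fa"), mask)
        md = masked_voxels(_subject_maps(d, ids, "md"), mask)
        md.columns = [c + fa.shape[1] for c in md.columns]
        return pd.concat([fa, md], axis=1)
    if modality == "gm+dti":
        gm = _voxel_features(d, atlas, cv_ids, ids,
                             RunConfig(**{**asdict(config), "modality": "gm"}))
        dti = _voxel_features(d, atlas, cv_ids, ids,
                              RunConfig(**{**asdict(config), "modality": "dti"}))
        dti.columns = [c + gm.shape[1] for c in dti.columns]
        return pd.concat([gm, dti], axis=1)
    raise ValueError(f"unknown modality {modality!r}")


def stage_extract(config: RunConfig) -> None:
    """Write the feature tables for the CV and validation cohorts."""
    d, subjects, atlas = _load_cohort_tables(config)
    with open(d["root"] / "match.json") as fh:
        match = json.load(fh)
    cv_ids = sorted(i for ids in match["selected"].values() for i in ids)
    val_ids = match["validation_ids"]
    if config.method == "roi":
        feats = _roi_features(d, atlas, cv_ids + val_ids, config.modality)
        table = feats.data
    else:
        table = _voxel_features(d, atlas, cv_ids, cv_ids + val_ids, config)
        table.columns = [f"vox_{c}" for c in table.columns]
    table.loc[cv_ids].to_csv(d["features"] / "cv.csv", index_label="id")
    table.loc[val_ids].to_csv(d["features"] / "val.csv", index_label="id")
    with open(d["features"] / "provenance.json", "w") as fh:
        json.dump({"method": config.method, "modality": config.modality,
                   "atlas": atlas.name, "n_features": table.shape[1]}, fh)


def _load_features(d, which: str, method: str):
    table = pd.read_csv(d["features"] / f"{which}.csv", index_col="id")
    return FeatureMatrix(table) if method == "roi" else table


def _labels(subjects: pd.DataFrame) -> pd.Series:
    return pd.Series(subjects["group"].to_numpy(), index=subjects["id"])


def _cv_config(config: RunConfig) -> CVConfig:
    return CVConfig(method=config.method, mode=config.mode, k_max=config.k_max,
                    svm=SVMConfig(C=config.svm_c), folds=config.folds,
                    seed=config.seed)


def _pair_rows(features, labels, groups: tuple[str, str]):
    ids = [i for i in (features.subject_ids if isinstance(features, FeatureMatrix)
                       else features.index) if labels[i] in groups]
    sub = features.rows(ids) if isinstance(features, FeatureMatrix) else features.loc[ids]
    return sub, labels.loc[ids]


def stage_classify(config: RunConfig) -> None:
    """Leave-two-out CV for all six pairwise comparisons."""
    d, subjects, _ = _load_cohort_tables(config)
    labels = _labels(subjects)
    feats = _load_features(d, "cv", config.method)
    cvc = _cv_config(config)
    for g1, g2 in GROUP_PAIRS:
        sub, lab = _pair_rows(feats, labels, (g1, g2))
        curve = leave_two_out_cv(sub, lab, cvc)
        name = curve.label.replace(" ", "")
        curve.as_frame().to_csv(d["curves"] / f"cv_{name}.csv", index=False)


def stage_validate(config: RunConfig) -> None:
    """Frozen-ranking independent validation for all six comparisons."""
    d, subjects, atlas = _load_cohort_tables(config)
    labels = _labels(subjects)
    train = _load_features(d, "cv", config.method)
    val = _load_features(d, "val", config.method)
    cvc = _cv_config(config)
    for g1, g2 in GROUP_PAIRS:
        tr, _ = _pair_rows(train, labels, (g1, g2))
        te, _ = _pair_rows(val, labels, (g1, g2))
        n_te = len(te.subject_ids if isinstance(te, FeatureMatrix) else te.index)
        if n_te < 2:
            log.warning("skipping %s vs %s: %d validation subjects", g1, g2, n_te)
            continue
        curve = independent_validation(tr, te, labels, cvc)
        name = curve.label.replace(" ", "")
        curve.as_frame().to_csv(d["curves"] / f"val_{name}.csv", index=False)
        if config.method == "roi" and curve.weights:
            k = best_k(curve)
            w = curve.weights[k]
            mapping = {f: f.split(":", 1)[1] for f in w.index}
            wmap = weight_localization(w, mapping,
                                       joint_dti=config.modality in ("dti", "gm+dti"))
            save_volume(export_weight_volume(wmap, atlas),
                        d["report"] / f"weights_{name}_k{k}.nii")


def stage_report(config: RunConfig) -> pd.DataFrame:
    """Summarize every accuracy curve as mean/max/IQR in percent."""
    d = _dirs(config)
    rows = []
    for path in sorted(d["curves"].glob("*.csv")):
        frame = pd.read_csv(path)
        validation, name = path.stem.split("_", 1)
        from .classify import AccuracyCurve
        curve = AccuracyCurve(name, frame["k"].tolist(), frame["accuracy"].tolist(),
                              frame["sensitivity"].tolist(),
                              frame["specificity"].tolist(), 0, "")
        s = summarize_curve(curve, modality=config.modality,
                            method=config.method, validation=validation)
        rows.append({"comparison": name, "validation": validation,
                     "mean": s.mean, "iqr": s.iqr, "max": s.max})
    table = pd.DataFrame(rows)
    table.to_csv(d["report"] / "summary.csv", index=False)
    return table


STAGES = {"simulate": stage_simulate, "qc": stage_qc, "match": stage_match,
          "extract": stage_extract, "classify": stage_classify,
          "validate": stage_validate, "report": stage_report}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the (reproducible) run manifest."""
    d = _dirs(config)
    for name, fn in STAGES.items():
        log.info("stage %s", name)
        try:
            fn(config)
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "config_hash": config.digest(),
        "stages": list(STAGES),
        "artifacts": sorted(str(p.relative_to(d["root"]))
                            for p in d["root"].rglob("*") if p.is_file()
                            and p.name != "manifest.json"),
    }
    with open(d["root"] / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
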