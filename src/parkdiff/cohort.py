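"""Synthetic cohort generator.

Real patient MRI for parkinsonian syndromes cannot be shared, so this module
generates complete stand-in cohorts — subject tables, spatially aligned
scalar maps (grey-matter volume, cortical thickness, FA, MD, a T1-like
intensity image and native-space tissue probability maps) and per-volume
diffusion motion logs — with controllable group effects, motion levels and
striping artefacts. Every downstream stage (QC, matching, feature
extraction, classification) is testable against known ground truth.

Maps are produced directly on a small common grid; inter-subject
registration is assumed to have happened upstream. Group effects are applied
region-wise on a label atlas (multiplicative for GM volume and thickness,
additive for FA and MD), then i.i.d. voxel noise is added. Per-subject head
motion is drawn per group, recorded in the motion log, and coupled linearly
into extra Gaussian smoothing of the T1-like image so that the smoothness
metric behaves as a motion proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from ._streams import stream
from .volumes import LabelAtlas, ScalarVolume

__all__ = [
    "GROUPS", "PATIENT_GROUPS", "SubjectRecord", "MotionLog", "EffectSpec",
    "GroupMotion", "Cohort", "make_fixture_atlas", "synth_motion_log",
    "generate_cohort", "default_effects", "expected_mean_abs_displacement",
    "save_motion_log", "load_motion_log",
]

GROUPS = ("Control", "PD", "PSP-RS", "CBS")
PATIENT_GROUPS = ("PD", "PSP-RS", "CBS")

# E||e|| for e ~ N(0, s^2 I_3) is s * 2*sqrt(2/pi) (chi distribution, 3 dof)
_CHI3_MEAN = 2.0 * math.sqrt(2.0 / math.pi)


@dataclass
class SubjectRecord:
    """One participant: demographics, clinical scores and group label."""

    id: str
    group: str
    age: float
    sex: str                      # "F" or "M"
    updrs3: int | None = None     # motor score; patients only
    mmse: int = 30
    tiv: float | None = None      # mm^3; filled from tissue maps by cohort_design

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if (self.updrs3 is None) != (self.group == "Control"):
            raise ValueError("updrs3 must be present iff the subject is a patient")
        if self.updrs3 is not None and self.updrs3 < 0:
            raise ValueError("updrs3 must be non-negative")
        if not 0 <= self.mmse <= 30:
            raise ValueError("mmse must be in [0, 30]")


@dataclass
class MotionLog:
    """Per-DWI-volume affine transforms plus striping flags for one subject.

    ``transforms[0]`` is the identity (the b=0 reference volume); subsequent
    entries map each diffusion-weighted volume back to the reference.
    """

    subject_id: str
    transforms: list[np.ndarray]
    striped: set[int] = field(default_factory=set)
    voxel_size: float = 2.0
    striping_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if len(self.transforms) < 2:
            raise ValueError("motion log needs at least 2 volumes")
        self.transforms = [np.asarray(t, dtype=float) for t in self.transforms]
        if not np.allclose(self.transforms[0], np.eye(4)):
            raise ValueError("transform 0 (b=0 reference) must be the identity")
        for i, t in enumerate(self.transforms):
            if t.shape != (4, 4) or abs(np.linalg.det(t[:3, :3])) < 1e-12:
                raise ValueError(f"transform {i} is not an invertible 4x4 affine")
        bad = [i for i in self.striped if not 0 < i < len(self.transforms)]
        if bad:
            raise ValueError(f"striped indices out of range: {bad}")

    @property
    def n_volumes(self) -> int:
        return len(self.transforms)


@dataclass
class GroupMotion:
    """Motion model for one group.

    ``jitter_mm`` sets the frame-to-frame translation scale (the expected
    per-volume displacement of the jitter component), ``drift_mm`` a slow
    linear drift away from the b=0 position, so absolute displacement
    exceeds relative displacement as in real drift-dominated head motion.
    A ``high_mover_frac`` fraction of subjects get ``high_mover_factor``
    times more motion and a higher striping rate, emulating the scans that
    quality control is meant to reject.
    """

    jitter_mm: float = 0.32
    drift_mm: float = 3.2
    rotation_rad: float = 0.002
    high_mover_frac: float = 0.10
    high_mover_factor: float = 3.0
    striping_rate: float = 0.3       # Poisson mean striped volumes, normal movers
    high_striping_rate: float = 5.0  # Poisson mean for high movers


def _default_motion() -> dict[str, GroupMotion]:
    # high-mover fractions chosen to emulate group-dependent scan failure
    # rates (patients move more than controls; PSP-RS worst affected)
    return {
        "Control": GroupMotion(high_mover_frac=0.10),
        "PD": GroupMotion(jitter_mm=0.34, drift_mm=3.5, high_mover_frac=0.09),
        "PSP-RS": GroupMotion(jitter_mm=0.36, drift_mm=3.4, high_mover_frac=0.37),
        "CBS": GroupMotion(jitter_mm=0.34, drift_mm=3.3, high_mover_frac=0.28),
    }


# demographic sampling ranges per group: (age mean, age sd, age lo, age hi,
# female fraction, updrs mean, updrs sd, mmse mean, mmse sd)
_DEMOGRAPHICS = {
    "Control": (67.3, 7.0, 51.0, 84.0, 0.45, None, None, 29.1, 1.0),
    "PD": (66.9, 7.5, 46.0, 76.0, 0.45, 20.5, 9.0, 29.1, 1.3),
    "PSP-RS": (71.9, 6.5, 51.0, 92.0, 0.45, 27.2, 14.0, 25.9, 3.3),
    "CBS": (66.9, 8.5, 39.0, 88.0, 0.48, 28.9, 16.0, 26.7, 3.8),
}


@dataclass
class EffectSpec:
    """Per-group, per-region effects plus noise and motion settings.

    ``gm_mult`` maps group -> {region label: multiplicative effect on GM
    volume (and on thickness in cortical regions)}. ``fa_shift`` and
    ``md_shift`` are additive effects on FA (dimensionless) and MD (mm^2/s)
    in white-matter regions. Regions not listed are unaffected.
    """

    gm_mult: dict[str, dict[int, float]] = field(default_factory=dict)
    fa_shift: dict[str, dict[int, float]] = field(default_factory=dict)
    md_shift: dict[str, dict[int, float]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "gm": 0.04, "ct": 0.12, "fa": 0.025, "md": 4e-5, "t1": 0.05})
    # baseline tissue values on the common grid
    base: dict[str, float] = field(default_factory=lambda: {
        "gm_in_gm": 0.70, "gm_in_wm": 0.15, "ct_cortical": 2.5,
        "fa_in_wm": 0.45, "fa_in_gm": 0.15, "md": 8.0e-4,
        "t1_gm": 1.0, "t1_wm": 1.4, "t1_bg": 0.1, "t1_base_fwhm_mm": 3.0})
    motion_smoothing_coupling: float = 1.5   # mm FWHM per mm mean abs displacement
    motion: dict[str, GroupMotion] = field(default_factory=_default_motion)
    n_dwi_volumes: int = 64                  # one b=0 plus 63 diffusion directions
    head_size_sd: float = 0.045

    def validate(self, atlas: LabelAtlas) -> None:
        """Reject effects that push FA outside [0, 1], MD <= 0 or GM <= 0."""
        known = set(int(v) for v in atlas.regions["label"])
        for group, table in self.gm_mult.items():
            for label, mult in table.items():
                if label not in known:
                    raise ValueError(f"gm_mult: unknown region {label} for {group}")
                if mult <= 0:
                    raise ValueError(
                        f"GM multiplier must be positive (group {group}, region {label})")
        for group, table in self.fa_shift.items():
            for label, shift in table.items():
                if label not in known:
                    raise ValueError(f"fa_shift: unknown region {label} for {group}")
                fa = self.base["fa_in_wm"] + shift
                if not 0.0 <= fa <= 1.0:
                    raise ValueError(
                        f"FA effect leaves [0,1] (group {group}, region {label}: {fa:.3f})")
        for group, table in self.md_shift.items():
            for label, shift in table.items():
                if label not in known:
                    raise ValueError(f"md_shift: unknown region {label} for {group}")
                if self.base["md"] + shift <= 0:
                    raise ValueError(
                        f"MD effect non-positive (group {group}, region {label})")


@dataclass
class Cohort:
    """Everything the generator emits for one synthetic study."""

    subjects: list[SubjectRecord]
    maps: dict[str, dict[str, ScalarVolume]]   # subject id -> modality -> volume
    motion_logs: dict[str, MotionLog]
    atlas: LabelAtlas

    def subject_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "id": s.id, "group": s.group, "age": s.age, "sex": s.sex,
            "updrs3": s.updrs3, "mmse": s.mmse, "tiv": s.tiv} for s in self.subjects])


def make_fixture_atlas(shape: tuple[int, int, int] = (32, 32, 24),
                       voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
                       n_gm: int = 63, n_wm: int = 100,
                       n_cortical: int = 48) -> LabelAtlas:
    """Blocky label atlas with ``n_gm`` grey- and ``n_wm`` white-matter regions.

    The grid is partitioned into a lattice of rectangular blocks; the first
    ``n_gm`` blocks become GM regions (the first ``n_cortical`` of them
    tagged cortical), the next ``n_wm`` become WM regions, and any leftover
    blocks stay background. Defaults mirror a 63-region GM / 100-region WM
    parcellation with 48 cortical regions.
    """
    if n_cortical > n_gm:
        raise ValueError("n_cortical cannot exceed n_gm")
    n_regions = n_gm + n_wm
    # pick a block lattice with at least n_regions blocks, roughly cubic blocks
    best = None
    for bx in range(1, shape[0] + 1):
        for by in range(1, shape[1] + 1):
            bz = math.ceil(n_regions / (bx * by))
            if bz > shape[2]:
                continue
            nblocks = bx * by * bz
            waste = nblocks - n_regions
            aspect = abs(shape[0] / bx - shape[1] / by) + abs(shape[1] / by - shape[2] / bz)
            key = (waste, aspect)
            if best is None or key < best[0]:
                best = (key, (bx, by, bz))
    if best is None:
        raise ValueError(f"grid {shape} too small for {n_regions} regions")
    bx, by, bz = best[1]
    xs = np.array_split(np.arange(shape[0]), bx)
    ys = np.array_split(np.arange(shape[1]), by)
    zs = np.array_split(np.arange(shape[2]), bz)
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    lbl = 0
    for xi in xs:
        for yi in ys:
            for zi in zs:
                lbl += 1
                if lbl > n_regions:
                    break
                labels[np.ix_(xi, yi, zi)] = lbl
                if lbl <= n_cortical:
                    rows.append((lbl, f"GM_cortical_{lbl:03d}", "GM"))
                elif lbl <= n_gm:
                    rows.append((lbl, f"GM_subcortical_{lbl:03d}", "GM"))
                else:
                    rows.append((lbl, f"WM_{lbl:03d}", "WM"))
    regions = pd.DataFrame(rows, columns=["label", "name", "tissue"])
    return LabelAtlas(labels, regions, voxel_size, name=f"fixture-{n_gm}gm-{n_wm}wm")


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def expected_mean_abs_displacement(displacement_scale: float) -> float:
    """Closed-form expected mean absolute displacement of ``synth_motion_log``.

    With zero drift and zero rotation the per-volume translation is isotropic
    Gaussian with per-axis sd ``scale / (2*sqrt(2/pi))``, whose norm has mean
    exactly ``scale``.
    """
    return float(displacement_scale)


def synth_motion_log(n_volumes: int, displacement_scale: float, n_striped: int,
                     seed: int, *, subject_id: str = "synthetic",
                     drift_mm: float = 0.0, rotation_scale: float = 0.0,
                     striping_amplitude: float = 0.0,
                     voxel_size: float = 2.0) -> MotionLog:
    """Simulate a DWI motion log.

    Each volume after the b=0 reference gets a translation composed of
    i.i.d. Gaussian jitter (per-axis sd set so the jitter norm has mean
    ``displacement_scale``) plus, optionally, a linear drift along a random
    direction reaching ``drift_mm`` at the last volume, and a small random
    rotation (per-axis angle sd ``rotation_scale`` rad). Exactly
    ``n_striped`` distinct non-reference volumes are flagged as striped.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    if displacement_scale < 0:
        raise ValueError("displacement_scale must be >= 0")
    if n_striped >= n_volumes:
        raise ValueError("n_striped must be smaller than n_volumes")
    rng = stream(seed, f"motion/{subject_id}")
    sigma = displacement_scale / _CHI3_MEAN
    u = rng.normal(size=3)
    norm = np.linalg.norm(u)
    u = u / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    transforms = [np.eye(4)]
    for i in range(1, n_volumes):
        t = rng.normal(scale=sigma, size=3) if sigma > 0 else np.zeros(3)
        t = t + u * drift_mm * (i / (n_volumes - 1))
        ang = rng.normal(scale=rotation_scale, size=3) if rotation_scale > 0 else np.zeros(3)
        aff = np.eye(4)
        aff[:3, :3] = _rotation_matrix(ang)
        aff[:3, 3] = t
        transforms.append(aff)
    striped = set()
    if n_striped > 0:
        striped = set(int(i) for i in rng.choice(
            np.arange(1, n_volumes), size=n_striped, replace=False))
    return MotionLog(subject_id, transforms, striped, voxel_size, striping_amplitude)


def default_effects(atlas: LabelAtlas, strength: float = 1.0) -> EffectSpec:
    """Moderate disease effects on the fixture atlas.

    Regional atrophy/diffusion patterns of the real disorders are not
    quantitatively known, so these are plausibility placeholders: each
    patient group loses GM volume in a distinct subset of GM regions and
    shows FA decrease / MD increase in a distinct subset of WM regions,
    scaled by ``strength`` (0 disables all effects).
    """
    gm = atlas.region_labels("GM")
    wm = atlas.region_labels("WM")
    third = max(1, len(gm) // 3)
    wthird = max(1, len(wm) // 3)
    spec = EffectSpec()
    assign = {"PD": 0, "PSP-RS": 1, "CBS": 2}
    for group, k in assign.items():
        g_regions = gm[k * third:(k + 1) * third]
        w_regions = wm[k * wthird:(k + 1) * wthird]
        mult = {"PD": 0.95, "PSP-RS": 0.85, "CBS": 0.90}[group]
        dfa = {"PD": -0.02, "PSP-RS": -0.05, "CBS": -0.035}[group]
        dmd = {"PD": 4e-5, "PSP-RS": 1.0e-4, "CBS": 7e-5}[group]
        spec.gm_mult[group] = {r: 1.0 + strength * (mult - 1.0) for r in g_regions}
        spec.fa_shift[group] = {r: strength * dfa for r in w_regions}
        spec.md_shift[group] = {r: strength * dmd for r in w_regions}
    return spec


def save_motion_log(log: MotionLog, path) -> None:
    """Write one affine per line as 16 whitespace-separated row-major entries."""
    with open(path, "w") as fh:
        for t in log.transforms:
            fh.write(" ".join(f"{v:.10g}" for v in np.asarray(t).ravel()) + "\n")


def load_motion_log(path, subject_id: str | None = None,
                    striped: Iterable[int] = (), voxel_size: float = 2.0) -> MotionLog:
    rows = []
    with open(path) as fh:
        for line in fh:
            vals = [float(v) for v in line.split()]
            if len(vals) != 16:
                raise ValueError(f"expected 16 affine entries per line, got {len(vals)}")
            rows.append(np.array(vals).reshape(4, 4))
    sid = subject_id if subject_id is not None else str(path)
    return MotionLog(sid, rows, set(int(i) for i in striped), voxel_size)


def _sample_subject(group: str, idx: int, rng: np.random.Generator) -> SubjectRecord:
    mu, sd, lo, hi, f_frac, u_mu, u_sd, m_mu, m_sd = _DEMOGRAPHICS[group]
    age = float(np.clip(rng.normal(mu, sd), lo, hi))
    sex = "F" if rng.random() < f_frac else "M"
    updrs = None
    if group != "Control":
        updrs = int(np.clip(round(rng.normal(u_mu, u_sd)), 0, 80))
    mmse = int(np.clip(round(rng.normal(m_mu, m_sd)), 0, 30))
    return SubjectRecord(id=f"{group}_{idx:03d}", group=group, age=age, sex=sex,
                         updrs3=updrs, mmse=mmse)


def generate_cohort(spec: EffectSpec, n_per_group: int, atlas: LabelAtlas,
                    seed: int) -> Cohort:
    """Generate a full synthetic cohort: subjects, aligned maps, motion logs.

    Per subject the generator draws demographics, a global head-size factor,
    a motion level (jitter + drift, with a group-dependent chance of being a
    high mover), builds GM/thickness/FA/MD maps as region-wise group effects
    on tissue baselines plus voxel noise, emits native-space GM/WM/CSF
    probability maps (for TIV estimation) and a T1-like image whose extra
    Gaussian smoothing is ``motion_smoothing_coupling`` x the subject's mean
    absolute displacement. Fully reproducible for a fixed (spec, seed).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if len(atlas.region_labels("GM")) < 2 or len(atlas.region_labels("WM")) < 2:
        raise ValueError("atlas must have at least 2 GM and 2 WM regions")
    spec.validate(atlas)

    labels = atlas.labels
    gm_regions = atlas.region_labels("GM")
    wm_regions = atlas.region_labels("WM")
    cortical = atlas.region_labels("GM", cortical_only=True)
    gm_mask = np.isin(labels, gm_regions)
    wm_mask = np.isin(labels, wm_regions)
    ct_mask = np.isin(labels, cortical)
    brain = labels > 0
    vox = atlas.voxel_size

    subjects: list[SubjectRecord] = []
    maps: dict[str, dict[str, ScalarVolume]] = {}
    logs: dict[str, MotionLog] = {}

    for group in GROUPS:
        gmot = spec.motion[group]
        for idx in range(n_per_group):
            rng = stream(seed, f"cohort/{group}/{idx}")
            subj = _sample_subject(group, idx, rng)
            sid = subj.id
            head = 1.0 + rng.normal(0.0, spec.head_size_sd)

            high = rng.random() < gmot.high_mover_frac
            factor = gmot.high_mover_factor if high else 1.0
            jitter = gmot.jitter_mm * factor * math.exp(rng.normal(0.0, 0.2))
            drift = gmot.drift_mm * (1.0 + 0.5 * (factor - 1.0)) * math.exp(rng.normal(0.0, 0.2))
            rate = gmot.high_striping_rate if high else gmot.striping_rate
            n_striped = min(int(rng.poisson(rate)), spec.n_dwi_volumes - 1)
            log = synth_motion_log(
                spec.n_dwi_volumes, jitter, n_striped,
                seed=int(rng.integers(2**31)), subject_id=sid, drift_mm=drift,
                rotation_scale=gmot.rotation_rad, striping_amplitude=2.0,
                voxel_size=vox[0])
            logs[sid] = log
            # mean abs displacement drives the T1 smoothing (motion proxy)
            disp = np.mean([np.linalg.norm(t[:3, 3]) for t in log.transforms[1:]])

            gm_map = np.where(gm_mask, spec.base["gm_in_gm"],
                              np.where(wm_mask, spec.base["gm_in_wm"], 0.0)) * head
            ct_map = np.where(ct_mask, spec.base["ct_cortical"], 0.0)
            fa_map = np.where(wm_mask, spec.base["fa_in_wm"],
                              np.where(gm_mask, spec.base["fa_in_gm"], 0.0))
            md_map = np.where(brain, spec.base["md"], 0.0)
            for label, mult in spec.gm_mult.get(group, {}).items():
                reg = labels == label
                gm_map[reg] *= mult
                ct_map[reg] *= mult
            for label, shift in spec.fa_shift.get(group, {}).items():
                fa_map[labels == label] += shift
            for label, shift in spec.md_shift.get(group, {}).items():
                md_map[labels == label] += shift

            gm_map = gm_map + rng.normal(0.0, spec.noise_sd["gm"], labels.shape)
            ct_map = ct_map + rng.normal(0.0, spec.noise_sd["ct"], labels.shape) * ct_mask
            fa_map = np.clip(fa_map + rng.normal(0.0, spec.noise_sd["fa"], labels.shape),
                             0.0, 1.0)
            md_map = np.maximum(md_map + rng.normal(0.0, spec.noise_sd["md"], labels.shape),
                                1e-6)

            t1 = np.where(gm_mask, spec.base["t1_gm"],
                          np.where(wm_mask, spec.base["t1_wm"], spec.base["t1_bg"]))
            t1 = t1 + rng.normal(0.0, spec.noise_sd["t1"], labels.shape)
            fwhm = spec.base["t1_base_fwhm_mm"] + spec.motion_smoothing_coupling * disp
            sigma_vox = [fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / v for v in vox]
            t1 = ndimage.gaussian_filter(t1, sigma=sigma_vox)

            f = float(np.clip(head, 0.7, 1.3))
            gm_p = np.where(brain, 0.42 * f, 0.0)
            wm_p = np.where(brain, 0.38 * f, 0.0)
            csf_p = np.where(brain, 0.18 * f, 0.0)

            subjects.append(subj)
            maps[sid] = {
                "gm": ScalarVolume(gm_map, vox, atlas.name),
                "ct": ScalarVolume(ct_map, vox, atlas.name),
                "fa": ScalarVolume(fa_map, vox, atlas.name),
                "md": ScalarVolume(md_map, vox, atlas.name),
                "t1": ScalarVolume(t1, vox, atlas.name),
                "gm_prob": ScalarVolume(gm_p, vox, "native"),
                "wm_prob": ScalarVolume(wm_p, vox, "native"),
                "csf_prob": ScalarVolume(csf_p, vox, "native"),
            }

    return Cohort(subjects, maps, logs, atlas)
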