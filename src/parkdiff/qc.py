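"""Motion quality control: smoothness, displacement, striping, exclusion rules.

Head motion corrupts structural and diffusion MRI, and patients with
movement disorders move more than controls, so motion-sensitive metrics must
be screened before any classification. Three proxies are computed per
subject:

* T1 image smoothness (FWHM in mm, from the variance of normalized spatial
  derivatives) — motion induces spatially correlated noise, so smoother
  images indicate more motion;
* absolute and relative head displacement from per-volume DWI registration
  transforms (mean displacement of points on a reference sphere);
* a striping score per volume (odd/even interleave slice-intensity
  alternation), with a per-subject affected-volume count.

Exclusion rules: cohort-level 2-sd outliers on smoothness or mean
displacement, any relative displacement above 3 mm, or more than five
striped volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import MotionLog
from .volumes import ScalarVolume

__all__ = ["SubjectQC", "QCReport", "estimate_smoothness_fwhm",
           "displacement_metrics", "striping_scores", "striping_affected",
           "apply_exclusion_rules", "qc_from_cohort"]

_LN2_4 = 4.0 * math.log(2.0)


@dataclass
class SubjectQC:
    """Per-subject motion metrics."""

    subject_id: str
    t1_fwhm: float                      # combined (geometric-mean) FWHM, mm
    t1_fwhm_axes: tuple[float, float, float] = (0.0, 0.0, 0.0)
    abs_disp: list[float] = field(default_factory=list)
    rel_disp: list[float] = field(default_factory=list)
    n_striped_volumes: int = 0
    group: str | None = None

    @property
    def mean_abs_disp(self) -> float:
        return float(np.mean(self.abs_disp)) if self.abs_disp else 0.0

    @property
    def mean_rel_disp(self) -> float:
        return float(np.mean(self.rel_disp)) if self.rel_disp else 0.0

    @property
    def max_rel_disp(self) -> float:
        return float(np.max(self.rel_disp)) if self.rel_disp else 0.0


@dataclass
class QCReport:
    """Exclusion decisions plus the cohort statistics the rules used."""

    subjects: list[SubjectQC]
    excluded: dict[str, list[str]]      # subject id -> triggered rule names
    retained: list[str]
    cohort_stats: dict[str, dict[str, float]]   # metric -> {mean, sd}

    def as_frame(self):
        import pandas as pd
        rows = []
        for s in self.subjects:
            rows.append({
                "id": s.subject_id, "group": s.group, "t1_fwhm": s.t1_fwhm,
                "mean_abs_disp": s.mean_abs_disp, "mean_rel_disp": s.mean_rel_disp,
                "max_rel_disp": s.max_rel_disp,
                "n_striped_volumes": s.n_striped_volumes,
                "rules": ";".join(self.excluded.get(s.subject_id, [])),
                "retained": s.subject_id in self.retained})
        return pd.DataFrame(rows)


def estimate_smoothness_fwhm(volume: ScalarVolume,
                             mask: ScalarVolume | np.ndarray) -> tuple[tuple[float, float, float], float]:
    """Estimate per-axis and combined image smoothness (FWHM, mm).

    The masked intensities are standardized to zero mean / unit variance;
    the per-axis FWHM is ``voxel_size_a * sqrt(4 ln 2 / Var(forward
    difference along axis a))`` (derivative variance of the normalized
    field), and the combined estimate is the geometric mean of the three
    axes. Monotone decreasing in derivative variance, invariant to affine
    intensity rescaling.
    """
    m = mask.values if isinstance(mask, ScalarVolume) else np.asarray(mask)
    m = m > 0
    if m.sum() < 100:
        raise ValueError("mask must contain at least 100 voxels")
    vals = volume.values
    inside = vals[m]
    sd = inside.std()
    if sd == 0:
        raise ValueError("degenerate volume: zero intensity variance in mask")
    z = (vals - inside.mean()) / sd
    fwhm = []
    for axis in range(3):
        d = np.diff(z, axis=axis)
        # forward differences where both endpoints are inside the mask
        pair = np.logical_and(np.take(m, range(m.shape[axis] - 1), axis=axis),
                              np.take(m, range(1, m.shape[axis]), axis=axis))
        dv = d[pair]
        var = dv.var()
        if var <= 0:
            raise ValueError("degenerate volume: zero derivative variance")
        fwhm.append(volume.voxel_size[axis] * math.sqrt(_LN2_4 / var))
    combined = float(np.exp(np.mean(np.log(fwhm))))
    return (fwhm[0], fwhm[1], fwhm[2]), combined


def _sphere_points(radius: float, n: int = 256) -> np.ndarray:
    """Deterministic Fibonacci lattice on a sphere of given radius."""
    if radius == 0:
        return np.zeros((1, 3))
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + math.sqrt(5)) * i
    pts = np.stack([np.sin(phi) * np.cos(theta),
                    np.sin(phi) * np.sin(theta),
                    np.cos(phi)], axis=1)
    return radius * pts


def displacement_metrics(log: MotionLog, reference_radius: float = 80.0
                         ) -> tuple[list[float], list[float], dict[str, float]]:
    """Absolute and relative per-volume displacements (mm).

    Displacement of volume i relative to a reference transform is the mean,
    over points on a sphere of ``reference_radius``, of the distance the
    point moves between the two transforms. Absolute uses the b=0 transform
    (index 0) as reference; relative uses the predecessor volume. For a pure
    translation t the metric equals ``||t||`` for any radius.
    """
    n = log.n_volumes
    for i, t in enumerate(log.transforms):
        if abs(np.linalg.det(np.asarray(t)[:3, :3])) < 1e-12:
            raise ValueError(f"singular transform at volume {i}")
    pts = _sphere_points(reference_radius)
    pts_h = np.hstack([pts, np.ones((len(pts), 1))])

    def disp(ti: np.ndarray, tref: np.ndarray) -> float:
        diff = (pts_h @ (ti - tref).T)[:, :3]
        return float(np.mean(np.linalg.norm(diff, axis=1)))

    abs_disp = [disp(log.transforms[i], log.transforms[0]) for i in range(1, n)]
    rel_disp = [disp(log.transforms[i], log.transforms[i - 1]) for i in range(1, n)]
    summaries = {
        "mean_abs_disp": float(np.mean(abs_disp)),
        "mean_rel_disp": float(np.mean(rel_disp)),
        "max_rel_disp": float(np.max(rel_disp)),
    }
    return abs_disp, rel_disp, summaries


def striping_scores(series: list[ScalarVolume] | list[np.ndarray],
                    interleave_axis: int = 2) -> np.ndarray:
    """Per-volume striping score: odd/even slice-mean separation in sd units.

    score = |mean(odd-slice means) - mean(even-slice means)| / pooled
    within-parity sd of the slice means. Constant volumes score 0.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 volumes")
    scores = []
    for vol in series:
        arr = vol.values if isinstance(vol, ScalarVolume) else np.asarray(vol)
        nsl = arr.shape[interleave_axis]
        if nsl < 4:
            raise ValueError("need at least 4 slices along the interleave axis")
        axes = tuple(a for a in range(arr.ndim) if a != interleave_axis)
        slice_means = arr.mean(axis=axes)
        odd, even = slice_means[1::2], slice_means[0::2]
        pooled = math.sqrt(((len(odd) - 1) * odd.var(ddof=1)
                            + (len(even) - 1) * even.var(ddof=1))
                           / (len(odd) + len(even) - 2))
        if pooled == 0:
            scores.append(0.0)
        else:
            scores.append(abs(odd.mean() - even.mean()) / pooled)
    return np.asarray(scores)


def striping_affected(scores: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Boolean mask of volumes whose score exceeds median + k * MAD."""
    scores = np.asarray(scores, dtype=float)
    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    return scores > med + k * mad


# rule names are stable identifiers used in reports
RULE_SMOOTHNESS = "t1_fwhm>mean+2sd"
RULE_DISPLACEMENT = "mean_disp>mean+2sd"
RULE_MAX_REL = "max_rel_disp>3mm"
RULE_STRIPING = "striped_volumes>5"


def apply_exclusion_rules(qcs: list[SubjectQC], *, groupwise: bool = False,
                          max_rel_mm: float = 3.0,
                          max_striped: int = 5, n_sd: float = 2.0) -> QCReport:
    """Apply the four exclusion rules and report every triggered rule.

    R1: T1 smoothness above cohort mean + 2 sd. R2: mean absolute or mean
    relative displacement above cohort mean + 2 sd. R3: any
    volume-to-volume displacement strictly above 3 mm. R4: strictly more
    than five striped volumes. Cohort means/sds use the sample (n-1) sd and
    are computed over all input subjects before any exclusion; with
    ``groupwise`` the outlier screens run within each group.
    """
    if not qcs:
        raise ValueError("no subjects supplied")
    if len(qcs) < 3:
        raise ValueError("need at least 3 subjects for outlier screening")

    metrics = {
        "t1_fwhm": np.array([q.t1_fwhm for q in qcs], dtype=float),
        "mean_abs_disp": np.array([q.mean_abs_disp for q in qcs], dtype=float),
        "mean_rel_disp": np.array([q.mean_rel_disp for q in qcs], dtype=float),
    }
    groups = np.array([q.group if q.group is not None else "all" for q in qcs])

    def thresholds(values: np.ndarray) -> np.ndarray:
        out = np.empty_like(values)
        if groupwise:
            for g in np.unique(groups):
                sel = groups == g
                out[sel] = values[sel].mean() + n_sd * values[sel].std(ddof=1)
        else:
            out[:] = values.mean() + n_sd * values.std(ddof=1)
        return out

    stats = {name: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
             for name, v in metrics.items()}
    thr = {name: thresholds(v) for name, v in metrics.items()}

    excluded: dict[str, list[str]] = {}
    for i, q in enumerate(qcs):
        rules = []
        if q.t1_fwhm > thr["t1_fwhm"][i]:
            rules.append(RULE_SMOOTHNESS)
        if (q.mean_abs_disp > thr["mean_abs_disp"][i]
                or q.mean_rel_disp > thr["mean_rel_disp"][i]):
            rules.append(RULE_DISPLACEMENT)
        if q.max_rel_disp > max_rel_mm:
            rules.append(RULE_MAX_REL)
        if q.n_striped_volumes > max_striped:
            rules.append(RULE_STRIPING)
        if rules:
            excluded[q.subject_id] = rules
    retained = [q.subject_id for q in qcs if q.subject_id not in excluded]
    return QCReport(qcs, excluded, retained, stats)


def qc_from_cohort(cohort, reference_radius: float = 80.0) -> list[SubjectQC]:
    """Compute SubjectQC for every subject of a synthetic cohort."""
    mask = cohort.atlas.labels > 0
    out = []
    for subj in cohort.subjects:
        sid = subj.id
        axes, combined = estimate_smoothness_fwhm(cohort.maps[sid]["t1"], mask)
        log = cohort.motion_logs[sid]
        a, r, _ = displacement_metrics(log, reference_radius)
        out.append(SubjectQC(subject_id=sid, t1_fwhm=combined, t1_fwhm_axes=axes,
                             abs_disp=a, rel_disp=r,
                             n_striped_volumes=len(log.striped), group=subj.group))
    return out
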