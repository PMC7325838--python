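"""Matched-group selection, assumption-driven group tests, and TIV.

Group comparisons (age, UPDRS-III, MMSE, TIV, motion metrics) are routed
through a decision tree: residual normality is assessed by skewness and
excess kurtosis (both must lie in (-2, 2)) plus a Shapiro-Wilk test; with
normal residuals the variance-homogeneity ratio (largest to smallest group
residual variance, cutoff 3) decides between one-way ANOVA and Welch's
ANOVA; non-normal residuals go to Kruskal-Wallis with pairwise Mann-Whitney
post hocs when the omnibus test is significant. Sex uses a chi-squared test.

Matched equal-sized groups are selected by a seeded greedy search that
repeatedly drops the subject whose removal most improves the worst
covariate-balance p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._streams import stream
from .volumes import ScalarVolume

__all__ = ["TestDecision", "MatchReport", "choose_group_test",
           "select_matched_groups", "estimate_tiv", "fill_tiv"]

ALPHA = 0.05


@dataclass
class TestDecision:
    """Which omnibus test was used, why, and what it found."""

    route: str                      # ANOVA | Welch | Kruskal-Wallis | chi-squared
    p: float
    statistic: float
    rationale: dict[str, float] = field(default_factory=dict)
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def choose_group_test(values: dict[str, "np.ndarray | list[float]"] | np.ndarray,
                      alpha: float = ALPHA) -> TestDecision:
    """Route a group comparison through the assumption-checking tree.

    ``values`` is either a mapping group -> numeric observations, or a 2 x G
    contingency table of category counts (categorical data, chi-squared).
    """
    if isinstance(values, (np.ndarray, pd.DataFrame)) and np.asarray(values).ndim == 2:
        table = np.asarray(values, dtype=float)
        chi2, p, dof, _ = stats.chi2_contingency(table)
        return TestDecision("chi-squared", float(p), float(chi2),
                            rationale={"dof": float(dof)})

    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 observations")

    residuals = np.concatenate([v - v.mean() for v in groups.values()])
    skew = float(stats.skew(residuals, bias=False))
    kurt = float(stats.kurtosis(residuals, fisher=True, bias=False))
    sw_stat, sw_p = stats.shapiro(residuals)
    variances = {g: float(v.var(ddof=1)) for g, v in groups.items()}
    vmin = min(variances.values())
    ratio = max(variances.values()) / vmin if vmin > 0 else np.inf
    rationale = {"skewness": skew, "kurtosis": kurt, "shapiro_p": float(sw_p),
                 "variance_ratio": float(ratio)}

    normal = (-2.0 < skew < 2.0) and (-2.0 < kurt < 2.0) and sw_p > 0.05
    if not normal:
        stat, p = stats.kruskal(*groups.values())
        dec = TestDecision("Kruskal-Wallis", float(p), float(stat), rationale)
        if p < alpha:
            for g1, g2 in combinations(sorted(groups), 2):
                _, mw_p = stats.mannwhitneyu(groups[g1], groups[g2],
                                             alternative="two-sided")
                dec.posthoc[(g1, g2)] = float(mw_p)
        return dec
    if ratio <= 3.0:
        stat, p = stats.f_oneway(*groups.values())
        if not np.isfinite(p):  # identical group means -> F rounds below 0
            stat, p = max(float(stat), 0.0), 1.0
        return TestDecision("ANOVA", float(p), float(stat), rationale)
    # Welch's ANOVA for heteroscedastic but normal residuals
    import pingouin as pg
    long = pd.DataFrame({
        "value": np.concatenate(list(groups.values())),
        "group": np.concatenate([[g] * len(v) for g, v in groups.items()])})
    res = pg.welch_anova(data=long, dv="value", between="group")
    return TestDecision("Welch", float(res["p_unc"].iloc[0]),
                        float(res["F"].iloc[0]), rationale)


@dataclass
class MatchReport:
    """Outcome of matched-group selection."""

    selected: dict[str, list[str]]          # group -> subject ids
    tests: dict[str, TestDecision]          # covariate -> final test
    passed: dict[str, bool]                 # covariate -> p > alpha
    alpha: float
    seed: int

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())


def _covariate_test(frame: pd.DataFrame, covariate: str, alpha: float) -> TestDecision:
    if covariate == "sex":
        table = pd.crosstab(frame["sex"], frame["group"])
        return choose_group_test(table.to_numpy(), alpha)
    sub = frame[["group", covariate]].dropna()
    per_group = {g: v[covariate].to_numpy(dtype=float)
                 for g, v in sub.groupby("group") if len(v) >= 3}
    return choose_group_test(per_group, alpha)


def select_matched_groups(subjects: pd.DataFrame, n_per_group: int,
                          covariates: list[str], alpha: float = ALPHA,
                          seed: int = 0, max_iter: int = 10_000) -> MatchReport:
    """Greedy seeded selection of equal-sized groups balanced on covariates.

    Starting from all retained subjects, the currently largest oversized
    group repeatedly loses the subject whose removal most increases the
    minimum covariate-balance p-value (seeded tie-breaking), until every
    group has ``n_per_group`` subjects. Covariates absent for a group (e.g.
    UPDRS-III for controls) are tested across the groups that have them. If
    a covariate ends with p <= alpha the report is returned with that
    covariate marked as failed rather than raising.
    """
    frame = subjects.copy()
    if "id" not in frame or "group" not in frame:
        raise ValueError("subject table needs 'id' and 'group' columns")
    sizes = frame.groupby("group").size()
    too_small = sizes[sizes < n_per_group]
    if len(too_small):
        raise ValueError(f"groups smaller than n_per_group={n_per_group}: "
                         f"{dict(too_small)}")
    rng = stream(seed, "match")

    def min_p(fr: pd.DataFrame) -> float:
        return min(_covariate_test(fr, c, alpha).p for c in covariates)

    it = 0
    while True:
        sizes = frame.groupby("group").size()
        oversized = sizes[sizes > n_per_group]
        if oversized.empty:
            break
        it += 1
        if it > max_iter:
            raise RuntimeError("matching did not converge within max_iter")
        biggest = oversized.max()
        candidates_groups = sorted(oversized[oversized == biggest].index)
        g = candidates_groups[int(rng.integers(len(candidates_groups)))] \
            if len(candidates_groups) > 1 else candidates_groups[0]
        ids = frame.loc[frame["group"] == g, "id"].tolist()
        scores = []
        for sid in ids:
            trial = frame[frame["id"] != sid]
            scores.append(min_p(trial))
        scores = np.asarray(scores)
        best = np.flatnonzero(scores == scores.max())
        drop_idx = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
        frame = frame[frame["id"] != ids[drop_idx]]

    tests = {c: _covariate_test(frame, c, alpha) for c in covariates}
    passed = {c: t.p > alpha for c, t in tests.items()}
    selected = {g: sorted(v["id"]) for g, v in frame.groupby("group")}
    return MatchReport(selected, tests, passed, alpha, seed)


def estimate_tiv(gm: ScalarVolume, wm: ScalarVolume, csf: ScalarVolume) -> float:
    """Total intracranial volume: sum of the three tissue probability maps
    times the voxel volume (mm^3)."""
    if not (gm.same_grid(wm) and gm.same_grid(csf)):
        raise ValueError("tissue probability maps must share grid and voxel size")
    for name, vol in (("gm", gm), ("wm", wm), ("csf", csf)):
        if vol.values.min() < 0 or vol.values.max() > 1:
            raise ValueError(f"{name} map has values outside [0, 1]")
    total = gm.values.sum() + wm.values.sum() + csf.values.sum()
    return float(total * gm.voxel_volume)


def fill_tiv(cohort) -> None:
    """Fill ``SubjectRecord.tiv`` from each subject's tissue probability maps."""
    for subj in cohort.subjects:
        m = cohort.maps[subj.id]
        subj.tiv = estimate_tiv(m["gm_prob"], m["wm_prob"], m["csf_prob"])
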