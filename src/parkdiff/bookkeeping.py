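"""Cohort accounting: exclusion rates and cross-validation/validation splits.

These helpers make the study bookkeeping explicit and auditable: how many
subjects each quality-control step removed (as percentages of recruitment),
what remains per group, and how a fixed-size cross-validation selection
partitions the retained sample into training and independent-validation
cohorts.
"""

from __future__ import annotations

import numpy as np

__all__ = ["exclusion_rates", "retained_counts", "validation_cohort_sizes",
           "mean_accuracy_drop"]

CONTROL = "Control"


def retained_counts(recruited: dict[str, int], excluded: dict[str, int]) -> dict[str, int]:
    """Per-group post-QC sample sizes."""
    bad = {g: e for g, e in excluded.items() if e > recruited.get(g, 0)}
    if bad:
        raise ValueError(f"excluded more than recruited: {bad}")
    return {g: recruited[g] - excluded.get(g, 0) for g in recruited}


def exclusion_rates(recruited: dict[str, int], excluded: dict[str, int]) -> dict[str, float]:
    """Exclusion percentages per group plus pooled patient and control rates.

    Returns a mapping with one entry per group (percent of that group's
    recruitment excluded) plus ``patients`` (all non-control groups pooled)
    and ``controls``.
    """
    retained_counts(recruited, excluded)  # validates
    rates = {g: 100.0 * excluded.get(g, 0) / recruited[g] for g in recruited}
    pat_rec = sum(n for g, n in recruited.items() if g != CONTROL)
    pat_exc = sum(n for g, n in excluded.items() if g != CONTROL)
    rates["patients"] = 100.0 * pat_exc / pat_rec if pat_rec else 0.0
    if CONTROL in recruited:
        rates["controls"] = 100.0 * excluded.get(CONTROL, 0) / recruited[CONTROL]
    return rates


def validation_cohort_sizes(post_qc: dict[str, int], n_cv_per_group: int) -> dict[str, int]:
    """Independent-validation group sizes after removing the CV selection.

    Each group contributes ``post_qc[group] - n_cv_per_group`` subjects; the
    pooled size is returned under ``total``.
    """
    short = {g: n for g, n in post_qc.items() if n < n_cv_per_group}
    if short:
        raise ValueError(f"groups smaller than the CV selection: {short}")
    sizes = {g: n - n_cv_per_group for g, n in post_qc.items()}
    sizes["total"] = sum(n - n_cv_per_group for n in post_qc.values())
    return sizes


def mean_accuracy_drop(cv_accuracies, validation_accuracies) -> float:
    """Mean cross-validation-minus-validation accuracy difference (points)."""
    cv = np.asarray(cv_accuracies, dtype=float)
    val = np.asarray(validation_accuracies, dtype=float)
    if cv.shape != val.shape or cv.size == 0:
        raise ValueError("accuracy lists must be non-empty and equal length")
    return float(np.mean(cv - val))
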