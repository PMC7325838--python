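# parkdiff

MRI-based pairwise classification of parkinsonian syndromes — healthy
controls, idiopathic Parkinson's disease (PD), progressive supranuclear
palsy Richardson's syndrome (PSP-RS) and corticobasal syndrome (CBS) — as a
tested, reusable Python pipeline.

Differential diagnosis of these disorders from structural (T1-weighted) and
diffusion MRI is complicated by three confounds that routinely inflate
reported accuracies: unequal or poorly matched groups, feature selection
that touches the test data, and head motion that differs systematically
between patients and controls. This package implements the full
motion-aware design:

1. **Motion quality control** — per-subject T1 smoothness (FWHM from the
   variance of normalized spatial derivatives), absolute/relative head
   displacement from per-volume DWI registration transforms, and an
   interleave striping score; exclusion of 2-sd outliers, any displacement
   > 3 mm, or > 5 striped volumes.
2. **Matched-group design** — greedy seeded selection of equal-sized groups
   balanced on age, sex, motion and UPDRS-III, with every covariate test
   routed through an assumption-checking tree (ANOVA / Welch's ANOVA /
   Kruskal-Wallis with Mann-Whitney post hocs / chi-squared).
3. **Feature extraction** — atlas-ROI means or masked-voxel PCA (at most
   N − 1 components) from GM volume, cortical thickness, FA and MD maps,
   with leakage-safe z-scoring.
4. **Classification** — features ranked by the Fisher Discriminant Ratio

       FDR = (μ₁ − μ₂)² / (σ₁² + σ₂²)

   and added one at a time to a linear soft-margin SVM (C = 1), giving
   accuracy as a function of the number of features. Evaluation by
   leave-two-out paired cross-validation (one held-out subject per class
   per fold, ranking re-fit per fold) and by frozen-ranking independent
   validation, plus localization of SVM weights back to atlas regions.

Because the original patient MRI cannot be shared, a **synthetic cohort
generator** stands in for the data: four groups with realistic demographics,
region-wise atrophy and FA/MD effects, motion logs whose magnitude couples
into T1 smoothness, and optional striping — so every stage is testable
against known ground truth.

## Worked example

```python
from parkdiff import (CVConfig, default_effects, generate_cohort,
                      leave_two_out_cv, make_fixture_atlas,
                      roi_feature_matrix, summarize_curve)
import pandas as pd

atlas = make_fixture_atlas((24, 24, 16), n_gm=8, n_wm=8, n_cortical=6)
cohort = generate_cohort(default_effects(atlas), n_per_group=8, atlas=atlas, seed=2)
ids = [s.id for s in cohort.subjects if s.group in ("Control", "PSP-RS")]
labels = pd.Series({s.id: s.group for s in cohort.subjects if s.id in ids})
features = roi_feature_matrix({i: cohort.maps[i]["gm"] for i in ids},
                              atlas, "GMvol", "GM")
curve = leave_two_out_cv(features, labels, CVConfig(folds="exhaustive"))
print(summarize_curve(curve, modality="gm", method="roi"))
```

which prints (64 folds, Control vs PSP-RS, accuracy over k = 1..8 features):

```
CurveSummary(label='Control vs PSP-RS', mean=100.0, max=100.0, iqr=0.0,
             modality='gm', method='roi', validation='cv',
             quartile_convention='linear-interpolation')
```

The default generator injects a 15% GM volume loss in the PSP-RS-affected
regions, which is an easily separable effect at this noise level — hence a
flat 100% curve. With `default_effects(atlas, strength=0.0)` the same run
returns chance-level accuracy (~50%). The `examples/` directory has one
short script per capability (simulation, QC, matching, classification,
validation + weight localization, full pipeline); the `parkdiff` CLI runs
the same stages from a YAML config:

```bash
parkdiff all --config cohort.yaml --seed 5
```

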