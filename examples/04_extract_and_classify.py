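"""ROI feature extraction and leave-two-out cross-validated classification.

Extracts mean grey-matter volume per atlas region, then classifies
Control vs PSP-RS with an incremental linear SVM over FDR-ranked features,
holding out one subject from each group per fold.
"""

import numpy as np
import pandas as pd

from parkdiff import (CVConfig, default_effects, generate_cohort,
                      leave_two_out_cv, make_fixture_atlas,
                      roi_feature_matrix, summarize_curve)

atlas = make_fixture_atlas((24, 24, 16), n_gm=8, n_wm=8, n_cortical=6)
cohort = generate_cohort(default_effects(atlas), n_per_group=8, atlas=atlas,
                         seed=2)

ids = [s.id for s in cohort.subjects if s.group in ("Control", "PSP-RS")]
labels = pd.Series({s.id: s.group for s in cohort.subjects if s.id in ids})
gm_maps = {sid: cohort.maps[sid]["gm"] for sid in ids}
features = roi_feature_matrix(gm_maps, atlas, "GMvol", "GM")
print(f"feature matrix: {features.data.shape[0]} subjects x "
      f"{features.data.shape[1]} ROI features")

curve = leave_two_out_cv(features, labels,
                         CVConfig(method="roi", mode="safe", folds="exhaustive"))
print(f"\n{curve.label}: {curve.n_folds} folds, positive class "
      f"{curve.positive_class}")
print(curve.as_frame().round(3).to_string(index=False))
s = summarize_curve(curve, modality="gm", method="roi")
print(f"\nmean {s.mean:.1f}%  max {s.max:.1f}%  IQR {s.iqr:.1f}%  "
      "(accuracy over the number of included features)")
# Accuracy rises as informative regions enter the model and plateaus once
# the injected PSP-RS atrophy pattern is covered.
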