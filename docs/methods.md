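# Methods

## Scope and model

`parkdiff` implements pairwise classification of four groups (Control, PD,
PSP-RS, CBS) from spatially aligned scalar MRI maps. The statistical core
is deliberately simple and transparent: per-feature Fisher Discriminant
Ratio (FDR) ranking,

    FDR = (μ₁ − μ₂)² / (σ₁² + σ₂²),

with sample (n−1) variances, followed by a linear soft-margin SVM trained
on the top-k features for every k. The quantity of interest is the whole
accuracy-vs-k curve, summarized as mean, maximum and inter-quartile range
(type-7 linear-interpolation quartiles, recorded in each summary) rather
than a single tuned operating point — serial hypothesis tests across k
would be non-independent, since the first k features are nested in the
first k+1.

Two evaluation schemes are provided:

* **Leave-two-out paired CV.** Each fold holds out one subject from each of
  the two classes; folds enumerate all N_A × N_B cross-class pairs (or a
  seeded subsample). Accuracy is the mean over folds of the held-out pair's
  correct fraction (0, ½ or 1); sensitivity/specificity accumulate per
  class, with the clinically later group of the pair (the patient, or the
  rarer disorder) as the positive class.
* **Independent validation.** Ranking, normalization and the PCA basis are
  frozen on the full training cohort and applied to unseen subjects.
  Validation groups may be unequal, so balanced accuracy is reported
  alongside the raw fraction.

### Leakage modes

`mode="safe"` fits z-scoring (and the PCA basis, for voxel features) on the
2N−2 training subjects of every fold; `mode="paper"` fits them once on all
subjects jointly. FDR ranking is re-fit per fold in both modes. Because the
selection step (ranking) is fold-local either way, the joint-preprocessing
leak is small: per-feature z-scoring is an affine map applied identically
to train and test (the SVM solution is nearly invariant to it), and a
global PCA rotation adds little class-specific information on null data.
The package therefore treats the paper-mode/safe-mode gap as a measured
quantity: the leakage test asserts, over paired null cohorts with common
random numbers, that paper mode is not *less* optimistic than safe mode up
to two Monte-Carlo standard errors of the paired difference, rather than
assuming a large positive gap.

Safe-mode leave-pair-out CV is exactly unbiased on null data (the held-out
pair is independent of everything the model saw), but fold outcomes within
a cohort are strongly correlated — each subject is re-tested in many
pairings — so per-cohort mean accuracy has a standard deviation of roughly
14 percentage points for 19 + 19 subjects. Calibration checks consequently
average over tens of replicate cohorts; simulation sizes in the tests were
chosen to keep the Monte-Carlo error of such grand means near 1.5 points.

## Quality control

Three motion proxies are computed per subject:

* **T1 smoothness.** Masked intensities are standardized; per-axis FWHM is
  `voxel × sqrt(4·ln2 / Var(forward difference))` and the combined value is
  the geometric mean of the axes. This is computed on the standardized
  T1-like volume within a brain mask (tissue segmentation is out of scope),
  so the absolute scale differs from segmentation-based estimators; only
  the ordering across subjects matters for outlier screening. The estimator
  is exact for Gaussian autocorrelation in the wide-kernel limit and
  recovers an applied 6 mm kernel within 15% on 2 mm grids.
* **Displacement.** For each DWI volume, the mean distance moved by 256
  Fibonacci-lattice points on an 80 mm sphere (a standard framewise-
  displacement convention; configurable radius) between the volume's affine
  and the reference — volume 0 for absolute, the predecessor for relative
  displacement. Exact (`‖t‖`) for pure translations at any radius, and
  invariant to a common rigid re-expression of all transforms.
* **Striping.** Per volume, |mean(odd-slice means) − mean(even-slice
  means)| divided by the pooled *within-parity* slice-mean sd; a volume is
  affected when its score exceeds the cohort median + 5·MAD. This is a
  documented approximation of interleave-artefact detectors. Note that a
  median+5·MAD cut on any continuous null score sits near its ~99th
  percentile, so a ~1–3% per-volume false-flag rate is expected; the
  subject-level exclusion rule (more than five affected volumes) absorbs
  it, and the null tests assert exactly that.

Exclusion rules (cohort statistics computed before any exclusion, sample
sd): smoothness above mean + 2 sd; mean absolute or mean relative
displacement above mean + 2 sd; any relative displacement strictly above
3 mm; strictly more than five striped volumes. The 2-sd screens default to
the whole cohort (a `groupwise` flag switches to per-group screening), and
every excluded subject cites all rules it triggered.

## Group tests and matching

Numeric covariates are routed by recorded assumption checks: residuals
(value − group mean) must have adjusted Fisher–Pearson skewness and excess
kurtosis in (−2, 2) *and* pooled Shapiro–Wilk p > 0.05 to count as normal;
normal residuals go to one-way ANOVA when the max/min group-variance ratio
is ≤ 3 and to Welch's ANOVA otherwise; non-normal residuals go to
Kruskal–Wallis, with pairwise Mann–Whitney post hocs when the omnibus test
is significant at α = 0.05. Categorical covariates (sex) use chi-squared.
The route is a pure function of the rationale stored in every report.

Matched selection uses a greedy seeded search: starting from all retained
subjects, the largest oversized group repeatedly loses the subject whose
removal most increases the minimum covariate-balance p-value (ties broken
by a seeded draw) until all groups reach the target size. This is a design
choice — simple, reproducible and auditable — not an optimal-matching
algorithm; a failed final balance (p ≤ α) is reported, not raised.
Covariates missing for a group (UPDRS-III for controls) are tested across
the groups that have them. TIV is the sum of the GM, WM and CSF probability
maps times the voxel volume.

## Feature extraction

ROI features are arithmetic means of the map within each atlas region,
ordered by ascending label id (63 GM regions, 48 cortical regions for
thickness, 100 WM regions each for FA and MD with the default fixture
atlas). Masks threshold the cross-subject mean GM map strictly above 0.1,
or the FA template at ≥ 0.2 (the half-open/closed conventions follow the
two use cases deliberately). PCA is computed by thin SVD of the centered
training matrix (efficient when voxels ≫ subjects); components with
numerically zero variance are dropped, so at most N − 1 survive, and
held-out subjects are projected with the training mean and directions only.
Voxel traversal is fixed C-order for reproducibility. Z-scoring uses the
training columns' mean and sample sd; zero-variance columns are dropped
from all matrices and logged.

## Synthetic cohort generator

The generator emulates the study conditions, not brain geometry. On a
small common grid (blocky fixture atlas, default 32×32×24 at 2 mm,
63 GM / 100 WM regions of which 48 cortical) it draws, per subject:

* demographics from group-typical ranges (ages centred at 67–72 years,
  UPDRS-III ≈ 20–29 for patients, MMSE lower in PSP-RS/CBS), matching the
  reported cohort's distributions;
* a head-size factor (sd 4.5%) scaling GM volume and the tissue
  probability maps (hence TIV);
* region-wise group effects: multiplicative on GM volume and thickness,
  additive on FA (kept in [0, 1]) and MD (kept positive), then iid voxel
  noise (GM sd 0.04 on a 0.70 baseline, FA sd 0.025 on 0.45, MD sd 4e-5 on
  8e-4 mm²/s). The real disorders' spatial patterns are not quantitatively
  known, so the default effect sizes (GM ×0.85–0.95, FA −0.02 to −0.05,
  MD +4e-5 to +1e-4 in group-specific region subsets) are plausibility
  placeholders chosen to be recoverable but not trivial;
* a motion log of 64 volumes (one b=0 plus 63 directions): per-volume
  translations combine frame-to-frame jitter (per-axis sd chosen so the
  jitter norm has a closed-form mean equal to the displacement scale) with
  a slow random-direction drift, reproducing the drift-dominated pattern of
  real head motion (absolute ≈ 1.6 mm ≫ relative ≈ 0.45 mm), plus small
  rotations. A group-dependent fraction of subjects (10% controls, 9% PD,
  37% PSP-RS, 28% CBS — the study's observed exclusion rates) are "high
  movers" with ~3× motion and a high striping rate, so the QC stage has
  realistic work to do;
* T1-like images smoothed by a base 3 mm FWHM plus 1.5 mm per mm of mean
  absolute displacement — the linear motion–smoothness coupling that makes
  smoothness a motion proxy. Only the monotone association matters for QC.

All randomness flows from one master seed through named SeedSequence
streams, so any module can be re-run independently and cohorts are
byte-identical under a fixed (spec, seed). What the generator does *not*
emulate: anatomy, registration error, k-space artefact physics, diffusion
tensor fitting (FA/MD are emitted directly), and correlated voxel noise.
Passing tests therefore demonstrate the correctness and calibration of the
*pipeline*, not expected accuracy on real patients.

## Numerical choices and degenerate inputs

* FDR with zero pooled variance: +inf when means differ (logged), 0 when
  they coincide; ranking ties broken lexicographically by feature name.
* SVM: linear kernel, C = 1 (a linear decision function is required for
  per-feature weight maps); both exposed in `SVMConfig`.
* Weight localization uses |w|, rescaled to a maximum of 1 per modality —
  or jointly over FA and MD, so a single top diffusion feature carries
  weight 1; PCA weights are back-projected through the basis and averaged
  per region. The reported k defaults to the accuracy-maximizing k
  (smallest on ties), recorded with the outputs.
* ANOVA on groups with numerically identical means can round the F
  statistic below zero; the router clamps this to F = 0, p = 1.
* Pipeline runs at demonstration scale by default (8–10 subjects/group,
  8 + 8 regions, subsampled folds), chosen so a full grid cell runs in
  seconds; all sizes are config fields.

## Known limitations

Volumetric stand-in for surface-based thickness; no multiclass
classification, probability calibration or hyperparameter search; no
eddy-current/susceptibility correction (transform logs are consumed, not
produced); matching is greedy, not optimal; the striping detector is an
approximation scoring slice-mean parity only.
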