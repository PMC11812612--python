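# Methods

This note documents the models and procedures implemented in `octshap`,
the choices made where the design was genuinely open, and the known
limitations of both.

## Grid and zone conventions

All grids are 8×8 thickness matrices in micrometres, row 1 superior.
Right-eye (OD) grids have column 1 temporal; left-eye (OS) grids are
stored in their own device view, which is the mirror image, so the zone
map is mirrored column-wise before being applied to an OS grid. Some
orientation convention has to be frozen for mirroring to be well defined;
this one is asserted throughout the I/O layer.

The default cell-to-zone assignment is a documented convention, not a
vendor map: zone 1 (central papillomacular bundle) is the 2×4 block
spanning the two foveal rows immediately temporal of centre; zone 2
(peripheral papillomacular bundle) is the surrounding ring of
temporal-central cells; the remaining cells split into the four quadrants
defined by the horizontal and vertical grid midlines (3 supero-nasal,
4 infero-nasal, 5 infero-temporal, 6 supero-temporal). Every cell is
assigned. Any alternative 8×8 integer map can be supplied instead
(`ZoneMap`, `read_zone_map`); all zones must be non-empty.

Zone aggregation uses the **arithmetic mean** of member cells rather than
the sum: zone sizes differ (8–16 cells under the default map), and the
mean keeps all zone values in comparable µm units.

## Features

Per structure (mRNFL, mGCL, mIPL, mIRL) and zone:

* `AVG_{layer}_{zone}` = (OD zone mean + OS zone mean) / 2,
* `DIFF_{layer}_{zone}` = OD zone mean − OS zone mean.

mIRL is always derived as the exact cellwise sum mRNFL + mGCL + mIPL and
never measured or simulated independently; because the zone mean is
linear in the grid, every mIRL feature equals the sum of the
corresponding base-layer features (a tested invariant).

DIFF is **signed** by default. Inter-eye asymmetry literature sometimes
uses the absolute difference; both are supported
(`build_features(..., signed_diff=False)`), the signed form is the
default because "difference between the right eye and the left eye" is a
signed quantity, and a linear classifier can learn a sign itself but
cannot recover it once folded away.

Canonical feature order is AVG before DIFF, layers mRNFL, mGCL, mIPL,
mIRL, zones 1–6: 48 features.

## Synthetic cohort generator

The generator works at the thickness-grid level (no B-scans, speckle or
segmentation artefacts) and draws, per subject and layer:

    cell(eye, r, c) = baseline(layer)
                    + subject offset            ~ N(0, subject_sd²)   shared by both eyes
                    + zone offset(zone(r, c))   ~ N(0, local_sd²)     shared by both eyes
                    − effect(layer, zone)                             patients only
                    ± asym/2,  asym             ~ N(0, asym_sd(group)²)  (+OD, −OS)
                    + noise(eye, r, c)          ~ N(0, noise_sd²)     i.i.d. per cell

All distributions are Gaussian — the simplest model carrying the assumed
structure. Zone membership for the left eye uses the mirrored map, so
with zero asymmetry and zero noise the OS grid is exactly the mirrored OD
grid (tested invariant), and with all SDs at zero patients differ from
controls by exactly the configured effect, zone-localized (tested
invariant).

Defaults (all µm):

| parameter | default | rationale |
|---|---|---|
| cohort size | 79 patients / 69 controls | scale of early-RRMS OCT case-control studies |
| baselines mRNFL / mGCL / mIPL | 30 / 42 / 36 | plausible macular layer thicknesses |
| effects | mGCL z2: 4, mGCL z6: 3, mRNFL z2: 3, mRNFL z6: 2, mIPL z2: 1.5 | thinning concentrated in GCL/RNFL, papillomacular bundle and supero-temporal quadrant, matching where early-RRMS damage localizes; gives feature-recovery tests a known ground truth |
| subject_sd | 6 | between-subject SD of macular layer thickness |
| local_sd | 3 | per-zone topographic variability (see below) |
| asym_sd patient / control | 2 / 1 | inter-eye difference carries some signal in patients, less than AVG |
| noise_sd | 1.5 | cell-level measurement noise |

`local_sd_um` exists because a purely global subject offset makes the
difference of two zone means within a layer cancel subject variability
exactly, leaving the planted effect against ~0.3 µm of averaged
measurement noise — every cohort becomes perfectly separable and the
selection problem trivial. Real retinal topography varies between
subjects locally as well as globally; per-zone bilateral offsets are the
coarsest model of that. With the defaults, LOO accuracy on the full
feature set is ~0.72–0.82 and peaks higher at reduced subsets, the regime
the elimination loop is designed for.

These defaults are conventions chosen for plausibility, not estimates of
any clinical population; no published per-cell thickness distributions
exist for the cohorts this emulates. What passing tests show is that the
*pipeline* recovers planted structure under realistic noise; they say
nothing about the effect sizes of real disease.

`planted_feature_table` bypasses the grid model entirely and generates
i.i.d. standard-normal features with a configurable mean shift on a named
subset — used to study selection behaviour with an exactly known
informative set and unit effect sizes.

## Classifier and evaluation

Linear SVM, L2 penalty, squared-hinge loss, C = 1.0. The objective is
the liblinear convention ½(‖w‖² + b²) + C·Σ max(0, 1 − yᵢf(xᵢ))²
(intercept regularized, solver tolerance 1e-6, primal Newton method —
deterministic); the test suite checks the reached objective value against
an independent generic minimizer.

Features are z-scored before fitting. Raw µm features mix scales
(mIRL zone means are ~3× mRNFL ones; DIFF features are an order of
magnitude smaller than AVG), and C = 1.0 is only meaningful on a
normalized scale. Standardization is part of the model and is refit
inside every LOO fold; it can be disabled (`standardize=False`).

Positive class = patient; a decision value of exactly 0 predicts patient
(an explicit, testable rule). Metrics follow the standard definitions
with patient as positive; a ratio with zero denominator is reported as
undefined (`None`), never silently 0. Comparisons against
published-precision values round half-up to 4 decimal places.

`solve_confusion` inverts printed metrics back to integer confusion
counts by exhaustive enumeration of (TP, TN) and demands uniqueness —
a verification utility for published tables.

## Shapley attributions

The model is linear and the background is treated interventionally
(features independent), so Shapley values have the closed form
φ<sub>ij</sub> = w<sub>j</sub>(z<sub>ij</sub> − mean(background)<sub>j</sub>)
with base value = mean decision function over the background. No
sampling approximation is used anywhere: exactness is free for linear
models and makes tests sharp. A brute-force oracle
(`brute_force_shapley`, ≤ 12 features, 2^M coalitions, interventional
expectation over background rows) verifies the closed form to 1e-10 in
the suite, along with the efficiency, symmetry and dummy axioms.

Choices the attribution depends on:

* **Background** = the training samples of the model being explained —
  always available in-pipeline and the standard interventional choice.
* **Scale**: attributions are computed on the standardized scale where
  the model lives and are *not* rescaled back to µm. |φ| rankings are
  only meaningful on one consistent scale; reports translate feature
  names, not values.
* **Explained set** = all samples.

## RFE–SHAP loop

From N = 48 down to 1: LOO evaluation on the active features; fit on all
samples; rank active features by mean |SHAP|; drop the lowest-ranked
feature. Exactly one feature is eliminated per step. Ties in the ranking
break to the feature later in canonical order (reproducibility requires a
stated rule; with continuous features ties essentially never occur).
`select_optimal` returns the smallest N among the argmax of LOO accuracy.

The per-step ranking is computed from a single full-data fit by default.
`rank_per_fold=True` instead averages mean-|SHAP| over the LOO fold
models (n + 0 extra fits instead of 1, since the fold models are already
fitted). Both orderings are deterministic; the default is cheaper and is
the primary supported reading of the procedure.

## Selection bias — the important caveat

The elimination ranking is computed from models fitted on **all**
samples, while accuracy is estimated by LOO *inside* the same loop. The
surviving features at step N were therefore chosen with knowledge of
every held-out label, and the trace accuracies are optimistically biased
— the well-known selection-bias effect of performing feature selection
outside the cross-validation loop (Ambroise & McLachlan, PNAS 2002).

Measured on pure-noise cohorts with permuted labels, the maximum LOO
accuracy along the trace typically reaches 0.65–0.85 at n = 80 and
0.58–0.70 at n = 150–200 — far outside binomial noise around chance —
and the `rank_per_fold` variant is equally affected (the elimination
decision still pools information across folds). Consequently:

* the *selected subset's* LOO accuracy should be read as an upper bound,
  not an unbiased generalization estimate;
* on null data the trace does **not** stay at chance level, and no
  implementation of this protocol can make it do so;
* unbiased performance estimation would require an outer validation
  layer (nested CV or a held-out set), which is outside this package's
  scope.

The ranking itself is more robust than the accuracy: on synthetic tables
with 6 features shifted by 1 SD among 42 noise features (n = 150), at
least 5 of the 6 planted features survive to the last 10 in 19 of 20
seeded runs. The *size* of the selected subset is noisy, however: the
argmax over 48 correlated LOO accuracies (quantized at 1/n) frequently
lands on upward blips at larger N, so N_RELEVANT scatters widely
(observed 7–31, median ≈ 21, under those conditions).

## Numerical and degenerate-input choices

* Solver: liblinear primal Newton, tol 1e-6, max_iter 100000; no
  randomness anywhere in the pipeline except the seeded generators, so
  identical config + seed reproduce byte-identical CSV/JSON outputs
  (tested).
* Constant features get unit scale during standardization (no division
  by zero); they receive weight ≈ 0 and SHAP exactly proportional to
  their deviation — i.e. 0.
* A LOO fold whose training labels collapse to one class is an error
  naming the fold, not a silent skip.
* Empty zones, missing grids/cells, duplicate cells, single-class
  training data, unparseable feature names: all hard errors naming the
  offending subject/eye/layer/cell or field.

## Limitations

* The zone map is a stated convention; analyses of real Spectralis
  exports should supply the instrument's actual assignment if available.
* The generator's Gaussian, zone-piecewise-constant model omits smooth
  spatial correlation, floor effects, age trends and scan-quality
  artefacts; passing recovery tests demonstrates pipeline correctness,
  not clinical effect sizes.
* Only a linear kernel is supported, by design: the exact SHAP closed
  form and the weight-based interpretability both depend on it.
* No class weighting despite mild cohort imbalance; sensitivity and
  specificity are reported separately so the imbalance is visible.
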