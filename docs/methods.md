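# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `ldctbio`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Imaging operators

**Hounsfield convention.** All grids are float64 HU indexed
(slice, row, col); in-plane spacing is (row, col) in mm.  The nominal HU
range is [−1024, 3071]; validation accepts a guard band down to −1100 HU so
that uncalibrated scans whose air level has drifted low (the very input
background normalization exists to fix) remain representable.

**Background normalization.** Screening scans from heterogeneous scanners
can carry a uniform intensity offset.  The offset is estimated as
`median(pixels < −800 HU) − (−1000)` and subtracted everywhere.  The
median over sub-−800 pixels is used rather than a fixed air ROI because it
is parameter-free and robust whenever exterior air dominates lung tissue
in that tail (true for chest fields of view).  If fewer than 1% of pixels
are below −800 HU the operator refuses to guess and raises.

**CAC.** Pixels strictly above 130 HU (the conventional calcium
threshold on non-contrast CT) are counted inside a user-supplied circular
heart ROI; membership is by pixel center and the ROI must lie fully inside
the grid.  Counts map to the 4-grade scale through three cutpoints
c1 < c2 < c3; a count equal to a cutpoint takes the higher grade (frozen
tie rule).  Cutpoints are calibrated against reference reader grades by
quantile matching: for boundary k, with m = #{reference grades < k}, the
cutpoint is the midpoint of the m-th and (m+1)-th order statistics of the
counts.  This reproduces the readers' grade marginal on the calibration
set exactly when counts are distinct, and requires all four grades to be
present.  Severity is coded 0–3 internally (none/minimal/moderate/severe
labels for I/O).  Counting is per slice; volumetric slab counting is a
possible extension, not implemented.  Program-vs-reader agreement is
summarized as the squared Pearson correlation of the two grade vectors.

**Emphysema.** Lung segmentation is threshold-based: voxels < −400 HU,
face-connected components (4-connectivity in-plane), components touching
the in-plane border discarded (exterior air), two largest kept.  The LAA
fraction counts voxels strictly below −950 HU ("less than", frozen as a
strict inequality) over the mask; it is a pure histogram statistic,
invariant to voxel permutation within the mask and monotone nonincreasing
in the threshold.  "Proportion of total lung volume" is interpreted as a
voxel-count proportion of whatever grid is supplied (single slice or
volume).

**Body composition.** The pectoralis is segmented on a user-designated
T3-level slice (no automated vertebral-level detection): threshold in the
skeletal-muscle window, default [−29, +150] HU inclusive; remove the
4-connected component containing the user's mediastinum click; keep the
remaining components whose centroids lie at or anterior to the seed row.
The muscle window is configurable because published threshold methods do
not agree on exact bounds; [−29, 150] is the field's convention for
unenhanced CT.  (Observed muscle attenuations near 57 HU are high for
unenhanced CT; since the window behind such values is not standardized, it
stays a parameter rather than a hard-coded constant.)  Muscle area is
`pixels × row_spacing × col_spacing / 100` cm² — exactly quadratic in
spacing.  Subcutaneous fat is the fat-window ([−120, −60] HU, inclusive)
portion of the body mask (largest border-free component of pixels
≥ −500 HU); "subcutaneous" is geometric in the phantom (the painted ring)
and approximated on real anatomy by the window-plus-body-component rule —
a documented limitation, since internal fat in the same window inside the
body component would be included on real images.  All connected-component
operations use 4-connectivity (frozen).

## Synthetic phantoms

The phantom emulates a single axial chest slice at the pectoralis level:
exterior air (−1000 HU), a body oval (−45 HU filler chosen outside both
the muscle and fat windows so threshold oracles are exact), a
subcutaneous fat ring (Gaussian −92.5 ± 4 HU, clipped to the fat window),
two rectangular pectoralis compartments (Gaussian 57 ± 4 HU clipped to
the muscle window; rectangles rather than ellipses so configured pixel
counts are exact — the default 2 × 50 × 50 px at 0.8 mm gives 32.0 cm²,
the survivors' scale), two elliptical lungs (−850 HU) with randomly
scattered single-pixel low-attenuation holes (−1000 HU) hitting the
configured LAA fraction to within one pixel, a heart disk (30 HU) with
disk-shaped plaques at 300–800 HU placed fully inside it, and a
mediastinal soft-tissue bridge (45 HU) that is in the muscle window,
4-adjacent to the heart, but separated from both muscle rectangles by at
least one body column — so seeded exclusion removes bridge + heart and
leaves exactly the painted muscle.

Every truth field is enumerated from the final painted label map (and the
calibrated image), never copied from configuration intent; the label map
travels with the truth object so tests can use painted masks as oracles.
An optional uniform background offset is applied *after* truth
enumeration to exercise normalization, and an optional Gaussian blur
(default off) breaks pixel-count exactness deliberately when enabled.
The phantom is not an anatomically realistic CT simulation: no scanner
noise, no partial-volume effects by default, no bone, and tissue classes
are separated by construction.  Exact-oracle tests on it therefore
demonstrate the operators' correctness on their contracts, not their
accuracy on real anatomy.

## Synthetic roster

The roster reconstructs the published cohort flow: 623 screen-detected
cancers = 373 survivors (stage I/II/III strata 296/40/22, 4 stage IV, 11
with missing stage) + 216 nonsurvivors (182 lung-cancer-related deaths:
strata 49/19/65 plus 49 stage IV; 34 unrelated deaths) + 34
indeterminate-status subjects, plus 30 non-screen-detected extras to
exercise that filter.  The published flow numbers are not mutually
consistent (373 + 216 ≠ 623; the printed nonsurvivor stage counts sum to
203, not 182); this reconstruction keeps the eligible-nonsurvivor count
(182), the stage I–III strata entering matching (49/19/65 vs 296/40/22)
and the group totals, at the cost of the stage-IV nonsurvivor count
(49 here).  The indeterminate block is a labeled reconstruction, not a
claim about the real data.

Marginals follow the published group descriptives: age N(64, 5²) /
N(64, 6²) (survivors / nonsurvivors), height N(1.70, 0.10²) m, weight
N(80, 16²) / N(81, 18²) kg, follow-up N(1660, 488²) clipped to
[405, 2744] days vs time-to-death N(894, 542²) clipped to [14, 2399]
days.  Pack-years are N(56, 24²) clipped to [30, 150] (the trial's
eligibility floor; the publication prints no pack-year summary) and COPD
rates 0.25 / 0.35 (plausible screening-population values; also not
printed).  Gender is allocated per (group, stage) stratum by rounding the
54:36 male fraction and shuffling, rather than independent Bernoulli
draws: the per-stratum sex ratio is then the same for every seed, which
is what makes the matched-cohort sizes (min over (stage, gender) cells)
deterministic and equal to the per-stage minima.  Histology is sampled
from the printed group-specific tables.

Effect-planted generators (`make_survival_data`, `make_logistic_data`)
draw covariates from declared normal/Bernoulli specs, event times from an
exponential hazard `h0·exp(xβ)` (h0 = 10⁻³/day) with independent
exponential censoring calibrated to the requested censored fraction, and
outcomes from the planted log-odds with an intercept centering the
marginal rate near ½.

## Cohort construction and matching

BMI = weight/height² and survival time = fup − candx days are derived per
record; missing inputs propagate as missing with a flag, and exclusion
decisions are centralized in `apply_exclusions` (screen-detected filter →
outcome classification → stage IV / missing-stage removal), which logs a
count for every rule.

NSM matching treats stage and gender as exact strata (the "six criteria"
= four continuous distance terms + two exact strata; stage-exact matching
is the only reading consistent with per-stage matched counts, and
near-identical published sex ratios support exact gender).  Distances are
variance-normalized Euclidean over age, BMI, pack-years and survival
time, with variances pooled over all eligible subjects before matching
(frozen; recomputed from data so matching is invariant to affine
rescaling of any criterion).  Pairing is a global minimum-total-distance
1:1 assignment per stratum (Hungarian algorithm via
`scipy.optimize.linear_sum_assignment`), chosen over greedy
nearest-neighbour as the reading of "all possible matches" that avoids
order-dependent selection bias; greedy remains available
(`MatchConfig(method="greedy")`) for sensitivity analysis.  Subjects are
sorted by pid for deterministic tie-breaking.  Balance is reported as
standardized mean differences before/after matching, using the pooled-SD
denominator √((s₁² + s₂²)/2).

## Statistical models

The default design has 10 covariate terms: muscle area, fat attenuation,
emphysema fraction, three CAC indicators (minimal/moderate/severe vs
none), ordinal stage (I=1..III=3), age, male indicator, height.  Stage
enters as a single ordinal term because the published model χ² carries
10 degrees of freedom, which is only consistent with one stage term
alongside the three CAC indicators; indicator coding (II, III vs I) is
available via `AnalysisSpec(stage_as_indicators=True)`.  Emphysema enters
as a fraction in [0, 1], so its coefficient is per unit of fraction —
this is why its OR/HR is numerically huge relative to per-HU or per-cm²
terms.

Logistic fits use maximum likelihood (statsmodels `Logit`) with Wald 95%
CIs on exponentiated coefficients and a likelihood-ratio model χ² against
the intercept-only model; rank-deficient designs and separation raise
errors naming the offending terms.  Cox fits use lifelines' `CoxPHFitter`
(Efron tie handling, its default — the tie rule is otherwise
unspecified), Wald CIs, and a likelihood-ratio test against the null
partial likelihood.  `exp(coefficient) = ratio` holds exactly by
construction and is asserted in tests for every term.

Group comparisons use Welch's unequal-variance t-test (the publication
does not name its test; Welch is the safe default under unequal group
variances).  Stratified analyses dichotomize pack-years at 50 with the
boundary value assigned to the low stratum (">50" is strictly greater);
strata with a missing group are flagged, never silently dropped.  No
multiple-testing correction is applied (α = 0.05 per test), mirroring the
source analysis.

## Pipeline and problem sizes

One global seed fans out to per-stage child seeds via SHA-256 of
"seed:stage" (stable across processes, < 2³¹), so stages are individually
reproducible and reruns are bit-for-bit identical.  The demo pipeline
quantifies 30 phantoms and models the 180-subject matched cohort with
group-conditional biomarkers drawn at the published survivor/nonsurvivor
means; model-recovery tests use n = 5000 single-covariate simulations and
200 replicates of n = 400 for null CI coverage — sizes at which
3-standard-error recovery bands and ±4-point coverage bands are
comfortably informative while the whole suite runs in well under a
minute of CPU for the statistical parts.

## Known limitations

- Threshold segmentations are validated exactly on phantoms only; on real
  CT they are approximations (no partial-volume handling, no bone
  exclusion in the muscle window, geometric "subcutaneous" rule).
- Single-slice muscle/fat measurements inherit the slice-selection
  sensitivity of the original protocol; no volumetric extension.
- The roster generator reproduces marginal distributions and stratum
  counts, not the joint covariate structure of real screening subjects;
  matched-cohort balance results on it demonstrate the machinery, not
  epidemiological effect sizes.
- No automated heart ROI or vertebral-level detection: both are user
  inputs by design.
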