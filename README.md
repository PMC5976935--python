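# ldctbio

Opportunistic imaging biomarkers from low-dose chest CT (LDCT) for
lung-cancer screening cohorts, with matched-cohort construction and
mortality modelling.

Screening LDCT examinations contain prognostic information beyond the lung
nodule itself: coronary artery calcification (CAC), emphysema, skeletal
muscle mass and subcutaneous fat quality are all visible on the same scan.
`ldctbio` implements a complete, testable pipeline that

1. **quantifies four biomarkers** from Hounsfield-unit (HU) images —
   CAC as the count of pixels > 130 HU inside a circular heart ROI (after
   anchoring exterior air at −1000 HU), mapped to a 4-grade severity scale
   (0 none / 1 minimal / 2 moderate / 3 severe) via cutpoints calibrated
   against reader grades; emphysema as the low-attenuation-area fraction
   LAA% = #{lung voxels < −950 HU} / #{lung voxels}; pectoralis muscle
   area (cm²) and attenuation at a user-chosen T3-level slice via
   muscle-window thresholding ([−29, 150] HU) with one-click mediastinum
   exclusion; and subcutaneous fat attenuation as the mean HU of
   fat-window ([−120, −60] HU) body pixels;
2. **builds a matched case–control cohort** from a trial-style roster:
   screen-detected cancers only, survivors vs lung-cancer-related deaths,
   stage IV and unrelated deaths excluded, then nonstandard matching
   (NSM) — optimal 1:1 assignment inside exact (stage, gender) strata with
   distances d(i,j) = √(Σ_c (x_ic − x_jc)²/σ̂²_c) over age, BMI,
   pack-years and survival time (variances pooled over all eligible
   subjects);
3. **fits mortality models** on the matched cohort: multivariate binary
   logistic regression (ORs) and Cox proportional hazards (HRs, Efron
   ties), each with 10 covariate terms (muscle area, fat attenuation,
   emphysema fraction, 3 CAC indicators, ordinal stage, age, gender,
   height), plus Welch group comparisons stratified by stage, pack-years
   (≤50 / >50) and COPD.

Because real trial data are access-restricted, the package ships a
first-class synthetic-data module: thorax phantoms whose ground truth
(calcified pixel count, LAA fraction, muscle area, fat/muscle means) is
enumerated from the painted label map — making every imaging operator
testable *exactly* — and rosters reproducing the published stratum counts,
plus effect-planted survival/logistic datasets for model-recovery tests.

## Worked example

```python
from ldctbio import *
from ldctbio.cohort_builder import derive_all

# exact imaging oracle on one phantom
vol, truth = make_phantom(PhantomConfig(seed=3))
n = count_calcified_pixels(vol, truth.heart_center, truth.heart_radius)
print(n == truth.calcified_pixel_count)        # True (47 == 47)

# cohort flow on the default synthetic roster
roster = make_roster(RosterConfig(seed=42))
survivors, nonsurvivors, log = apply_exclusions(derive_all(roster))
print(log.nonsurvivors_lc)                     # 182 eligible nonsurvivors
cohort = nsm_match(survivors, nonsurvivors)
print(2 * cohort.n_pairs)                      # 180 matched subjects (90 + 90)
print(cohort.pairs.groupby("stage").size().to_dict())
# {'I': 49, 'II': 19, 'III': 22}
```

The end-to-end pipeline (synthesize → quantify → match → model → report)
runs from one command:

```bash
ldctbio run-all --out-dir demo --seed 7
```

which writes `roster.csv`, `phantom_quantification.csv` (30 phantoms; all
30 CAC counts, LAA fractions and muscle areas equal painted truth
exactly), `exclusion_log.csv`, `matched_cohort.csv`, `balance_table.csv`,
model tables and a manifest. With seed 7 the logistic model on the matched
cohort gives χ²(10) = 69.07 and, per term (OR, p): muscle area 0.90
(p < 0.001), fat attenuation 1.16 (p = 0.001), severe CAC 12.7
(p < 0.001) — lower muscle mass, denser subcutaneous fat and heavy
coronary calcium all predict nonsurvival in the synthetic cohort, while
age and gender (matched away) do not.  The Cox model gives χ²(10) = 48.58
with the same qualitative pattern (e.g. severe CAC HR 2.94, p = 0.005).
`balance_table.csv` shows the matching shrinking the survival-time
standardized mean difference from 1.38 to 0.49 and BMI from 0.12 to 0.04.

Individual stages are exposed as subcommands (`synth`, `cac`,
`emphysema`, `bodycomp`, `match`, `model`); see `ldctbio --help`.

## Layout

| module | role |
| --- | --- |
| `io_formats` | DICOM / NIfTI volumes in HU; roster CSV with master-sheet column names; tabular writers |
| `synthetic_data` | phantoms with enumerated truth; rosters; effect-planted datasets |
| `cac_scoring` | background normalization, 130-HU pixel counting, cutpoint calibration, grading, reader agreement (r²) |
| `emphysema_quant` | lung segmentation, LAA fraction |
| `body_composition` | seeded pectoralis segmentation, muscle area/attenuation, subcutaneous fat attenuation |
| `cohort_builder` | derived fields, exclusion flow, NSM matching, balance diagnostics |
| `stat_models` | logistic / Cox fits, Welch comparisons, stratified tables |
| `pipeline`, `cli` | one-config orchestration and the `ldctbio` command |
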