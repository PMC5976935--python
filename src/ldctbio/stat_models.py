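"""Mortality models on the matched cohort: logistic regression, Cox
proportional hazards, and stratified group comparisons.

The default covariate set is the study's: pectoralis muscle area (cm^2),
subcutaneous fat attenuation (HU), emphysema as an LAA fraction in [0, 1]
(so its coefficient is per unit of fraction, hence large ratios), CAC
severity as three indicators (minimal/moderate/severe against the "none"
reference), tumor stage as a single ordinal term (I=1..III=3), age, gender
(male indicator) and height — ten covariate terms in total, matching the
model chi-square degrees of freedom reported for this design.

Group comparisons use Welch's unequal-variance t-test.  No
multiple-comparison correction is applied (alpha = 0.05 per test).  Cox
ties are handled with the Efron approximation (lifelines' default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_STAGE_ORD = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class AnalysisSpec:
    """Which columns enter a model, and how categorical terms expand.

    ``covariates`` may name plain numeric columns or the special names
    ``"cac"`` (expands to three severity indicators vs none),
    ``"stage"`` (ordinal by default, two indicators vs stage I when
    ``stage_as_indicators``), and ``"gender"`` (male indicator).
    """

    outcome: str = "nonsurvivor"
    time_col: str = "survival_time"
    event_col: str = "nonsurvivor"
    covariates: tuple[str, ...] = (
        "muscle_area", "fat_attenuation", "emphysema", "cac", "stage",
        "age", "gender", "height")
    cac_col: str = "cac_grade"
    stage_col: str = "stage"
    gender_col: str = "gender"
    stage_as_indicators: bool = False


@dataclass
class ModelResult:
    """Per-term effect estimates plus the overall model test."""

    kind: str                      # "logistic" or "cox"
    terms: pd.DataFrame            # term, coefficient, ratio, ci_low, ci_high, p_value
    chi2: float                    # likelihood-ratio statistic vs null model
    df: int
    p_value: float
    nobs: int

    def to_frame(self) -> pd.DataFrame:
        return self.terms

    def term(self, name: str) -> pd.Series:
        row = self.terms.loc[self.terms["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def build_design(data: pd.DataFrame, spec: AnalysisSpec) -> pd.DataFrame:
    """Expand an analysis spec into a numeric design matrix (no intercept)."""
    cols: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        if cov == "cac":
            g = data[spec.cac_col].astype(int)
            for code, label in ((1, "cac_minimal"), (2, "cac_moderate"), (3, "cac_severe")):
                cols[label] = (g == code).astype(float).to_numpy()
        elif cov == "stage":
            s = data[spec.stage_col]
            ordv = s.map(_STAGE_ORD) if s.dtype == object else s
            if spec.stage_as_indicators:
                for code, label in ((2, "stage_II"), (3, "stage_III")):
                    cols[label] = (ordv == code).astype(float).to_numpy()
            else:
                cols["stage"] = ordv.astype(float).to_numpy()
        elif cov == "gender":
            g = data[spec.gender_col]
            cols["gender_male"] = ((g == "male") | (g == 1)).astype(float).to_numpy()
        else:
            cols[cov] = data[cov].astype(float).to_numpy()
    X = pd.DataFrame(cols, index=data.index)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"design matrix contains missing values in terms: {bad}")
    return X


def _check_full_rank(X: pd.DataFrame, with_const: bool = True) -> None:
    M = np.column_stack([np.ones(len(X)), X.to_numpy()]) if with_const else X.to_numpy()
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        degenerate = [c for c in X.columns if X[c].nunique() <= 1]
        raise ValueError(
            "design matrix is rank deficient; check collinear or constant "
            f"terms (constant: {degenerate or 'none identified'})")


def fit_logistic(data: pd.DataFrame, spec: AnalysisSpec | None = None) -> ModelResult:
    """Multivariate binary logistic regression with Wald 95% CIs on ORs.

    The model chi-square is the likelihood-ratio statistic against the
    intercept-only model with df equal to the number of covariate terms.
    """
    import statsmodels.api as sm

    spec = spec or AnalysisSpec()
    y = data[spec.outcome].astype(int)
    if set(y.unique()) != {0, 1}:
        raise ValueError("outcome must be binary with both classes present")
    X = build_design(data, spec)
    _check_full_rank(X)
    try:
        res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0)
    except Exception as exc:  # perfect separation, non-convergence
        raise ValueError(
            f"logistic fit failed (possible separation) for terms "
            f"{list(X.columns)}: {exc}") from exc
    ci = res.conf_int()
    terms = pd.DataFrame({
        "term": X.columns,
        "coefficient": res.params[X.columns].to_numpy(),
        "ratio": np.exp(res.params[X.columns].to_numpy()),
        "ci_low": np.exp(ci.loc[X.columns, 0].to_numpy()),
        "ci_high": np.exp(ci.loc[X.columns, 1].to_numpy()),
        "p_value": res.pvalues[X.columns].to_numpy(),
    })
    return ModelResult(kind="logistic", terms=terms, chi2=float(res.llr),
                       df=int(res.df_model), p_value=float(res.llr_pvalue),
                       nobs=int(res.nobs))


def fit_cox(data: pd.DataFrame, spec: AnalysisSpec | None = None) -> ModelResult:
    """Cox proportional-hazards fit (Efron ties) with Wald 95% CIs on HRs."""
    from lifelines import CoxPHFitter

    spec = spec or AnalysisSpec()
    time = data[spec.time_col].astype(float)
    event = data[spec.event_col].astype(int)
    if (time < 0).any():
        raise ValueError("survival times must be nonnegative")
    if event.sum() == 0:
        raise ValueError("no events present; Cox model undefined on all-censored data")
    X = build_design(data, spec)
    _check_full_rank(X, with_const=False)
    df = X.copy()
    df["_time"] = time.to_numpy()
    df["_event"] = event.to_numpy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    summ = cph.summary
    terms = pd.DataFrame({
        "term": summ.index,
        "coefficient": summ["coef"].to_numpy(),
        "ratio": np.exp(summ["coef"].to_numpy()),
        "ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
        "ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
        "p_value": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    lr = cph.log_likelihood_ratio_test()
    return ModelResult(kind="cox", terms=terms, chi2=float(lr.test_statistic),
                       df=int(X.shape[1]), p_value=float(lr.p_value),
                       nobs=int(len(df)))


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def group_compare(values_a, values_b) -> GroupComparison:
    """Welch two-sample comparison with group descriptives."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    t = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        p_value=float(t.pvalue))


def stratified_analysis(data: pd.DataFrame, stratifier: str,
                        value_col: str = "muscle_area",
                        group_col: str = "nonsurvivor",
                        pkyr_cutoff: float = 50.0) -> pd.DataFrame:
    """Within-stratum group comparisons of one measured variable.

    ``stratifier`` is ``"stage"``, ``"pkyr"`` (dichotomized at the cutoff;
    a subject exactly at the cutoff goes to the low stratum — the high
    stratum is strictly greater) or ``"copd"``.  Strata where one group is
    absent are flagged, not dropped.
    """
    if stratifier == "pkyr":
        labels = np.where(data["pkyr"].astype(float) > pkyr_cutoff,
                          f">{pkyr_cutoff:g}", f"<={pkyr_cutoff:g}")
    elif stratifier in ("stage", "copd"):
        labels = data[stratifier].astype(str).to_numpy()
    else:
        raise ValueError("stratifier must be one of 'stage', 'pkyr', 'copd'")
    if pd.isna(labels).any():
        raise ValueError(f"stratifier {stratifier!r} undefined for some subjects")

    rows = []
    flag_group = data[group_col].astype(int)
    for stratum in sorted(pd.unique(labels)):
        sel = labels == stratum
        a = data.loc[sel & (flag_group == 0), value_col]
        b = data.loc[sel & (flag_group == 1), value_col]
        row = {"stratum": stratum, "n_survivors": int(len(a)),
               "n_nonsurvivors": int(len(b))}
        if len(a) < 2 or len(b) < 2:
            row |= {"mean_survivors": float(a.mean()) if len(a) else np.nan,
                    "sd_survivors": np.nan,
                    "mean_nonsurvivors": float(b.mean()) if len(b) else np.nan,
                    "sd_nonsurvivors": np.nan,
                    "p_value": np.nan, "flag": "one_group_absent_or_too_small"}
        else:
            cmp = group_compare(a, b)
            row |= {"mean_survivors": cmp.mean_a, "sd_survivors": cmp.sd_a,
                    "mean_nonsurvivors": cmp.mean_b, "sd_nonsurvivors": cmp.sd_b,
                    "p_value": cmp.p_value, "flag": ""}
        rows.append(row)
    return pd.DataFrame(rows)
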