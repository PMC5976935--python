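"""Cohort flow and variance-normalized survivor/nonsurvivor matching.

Reproduces the screening study's cohort construction: keep screen-detected
cancers, classify outcomes (survivors alive at trial end; nonsurvivors are
lung-cancer-related deaths only — unrelated deaths are excluded), drop
stage IV and missing-stage subjects, derive BMI and survival time, then
pair survivors to nonsurvivors by nonstandard matching (NSM): within each
exact (stage, gender) stratum, pairwise Euclidean distances over the
continuous criteria (age, BMI, pack-years, survival time), each normalized
by its variance pooled over all eligible subjects, solved as a global
minimum-total-distance 1:1 assignment.  Six criteria in all: four
continuous distance terms plus two exact strata.

Matching is invariant to input row order (subjects are sorted by pid) and
to affine rescaling of any continuous criterion (variances are recomputed
from the data).  Per-stratum pair count equals the smaller stratum side.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io_formats import SubjectRecord, records_to_frame

logger = logging.getLogger(__name__)

CONTINUOUS_CRITERIA = ("age", "bmi", "pkyr", "survival_time")
EXACT_CRITERIA = ("stage", "gender")


@dataclass
class MatchConfig:
    """Configuration of the six-criterion NSM matching.

    ``variances`` override the pooled per-criterion variances used for
    normalization; by default they are recomputed from all eligible
    subjects.  ``method`` selects optimal (global minimum-cost) or greedy
    assignment; optimal is the default.
    """

    continuous: tuple[str, ...] = CONTINUOUS_CRITERIA
    exact: tuple[str, ...] = EXACT_CRITERIA
    variances: dict[str, float] | None = None
    method: str = "optimal"

    def validate(self) -> None:
        if self.method not in ("optimal", "greedy"):
            raise ValueError("method must be 'optimal' or 'greedy'")
        if self.variances is not None:
            for k, v in self.variances.items():
                if v <= 0:
                    raise ValueError(f"variance for {k!r} must be > 0")


@dataclass
class ExclusionLog:
    """Per-rule removal counts of the cohort flow, in application order."""

    total: int = 0
    not_screen_detected: int = 0
    indeterminate_outcome: int = 0
    survivors_initial: int = 0
    nonsurvivors_initial: int = 0
    unrelated_death: int = 0
    nonsurvivors_lc: int = 0       # eligible nonsurvivors before stage filtering
    stage_iv_survivors: int = 0
    stage_iv_nonsurvivors: int = 0
    missing_stage_survivors: int = 0
    missing_stage_nonsurvivors: int = 0
    survivors_eligible: int = 0
    nonsurvivors_eligible: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v) for k, v in dataclasses.asdict(self).items()],
            columns=["step", "count"])


@dataclass
class MatchedCohort:
    """1:1 matched pairs with per-pair normalized distances."""

    pairs: pd.DataFrame                  # survivor_pid, nonsurvivor_pid, distance, stage, gender
    stratum_log: pd.DataFrame            # stage, gender, n_survivors, n_nonsurvivors, n_pairs
    balance: pd.DataFrame | None = None  # criterion, smd_before, smd_after

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def survivor_pids(self) -> list[str]:
        return self.pairs["survivor_pid"].tolist()

    @property
    def nonsurvivor_pids(self) -> list[str]:
        return self.pairs["nonsurvivor_pid"].tolist()

    def to_frame(self) -> pd.DataFrame:
        return self.pairs


def derive_fields(record: SubjectRecord) -> SubjectRecord:
    """Return a copy with BMI (kg/m^2) and survival time (days) derived.

    ``bmi = weight / height**2``; ``survival_time = fup_days - candx_days``.
    Missing inputs leave the derived field missing and set a flag.
    """
    rec = dataclasses.replace(record)
    flags = list(rec.flags)
    if rec.weight is not None and rec.height is not None:
        rec.bmi = rec.weight / rec.height ** 2
    else:
        rec.bmi = None
        flags.append("bmi_underivable")
    if rec.fup_days is not None and rec.candx_days is not None:
        rec.survival_time = rec.fup_days - rec.candx_days
    else:
        rec.survival_time = None
        flags.append("survival_time_underivable")
    rec.flags = tuple(flags)
    return rec


def derive_all(records: Sequence[SubjectRecord]) -> list[SubjectRecord]:
    return [derive_fields(r) for r in records]


def apply_exclusions(roster: Sequence[SubjectRecord]
                     ) -> tuple[list[SubjectRecord], list[SubjectRecord], ExclusionLog]:
    """Apply the cohort flow's exclusion rules.

    Order: keep screen-detected; split by outcome (indeterminate outcomes
    excluded; unrelated deaths excluded from the nonsurvivor side); drop
    stage IV and missing-stage subjects from both groups.  Returns eligible
    survivors, eligible nonsurvivors, and the per-rule log.
    """
    log = ExclusionLog(total=len(roster))
    screen = [r for r in roster if r.screen_detected]
    log.not_screen_detected = len(roster) - len(screen)

    survivors = [r for r in screen if r.death_lc == "alive"]
    lc_deaths = [r for r in screen if r.death_lc == "lung_cancer_death"]
    unrelated = [r for r in screen if r.death_lc == "unrelated_death"]
    log.indeterminate_outcome = len(screen) - len(survivors) - len(lc_deaths) - len(unrelated)
    log.survivors_initial = len(survivors)
    log.nonsurvivors_initial = len(lc_deaths) + len(unrelated)
    log.unrelated_death = len(unrelated)
    log.nonsurvivors_lc = len(lc_deaths)

    def stage_filter(group: list[SubjectRecord]) -> tuple[list[SubjectRecord], int, int]:
        kept = [r for r in group if r.stage in ("I", "II", "III")]
        n_iv = sum(1 for r in group if r.stage == "IV")
        n_missing = len(group) - len(kept) - n_iv
        return kept, n_iv, n_missing

    survivors, log.stage_iv_survivors, log.missing_stage_survivors = stage_filter(survivors)
    nonsurvivors, log.stage_iv_nonsurvivors, log.missing_stage_nonsurvivors = \
        stage_filter(lc_deaths)
    log.survivors_eligible = len(survivors)
    log.nonsurvivors_eligible = len(nonsurvivors)
    logger.info("cohort flow: %s", dataclasses.asdict(log))
    return survivors, nonsurvivors, log


def _criteria_frame(records: Sequence[SubjectRecord], config: MatchConfig) -> pd.DataFrame:
    df = records_to_frame(records)
    needed = list(config.continuous) + list(config.exact)
    complete = df[needed].notna().all(axis=1)
    if (~complete).any():
        logger.warning("dropping %d subject(s) with missing matching criteria",
                       int((~complete).sum()))
    return df.loc[complete].sort_values("pid", kind="stable").reset_index(drop=True)


def _pooled_variances(df_all: pd.DataFrame, config: MatchConfig) -> dict[str, float]:
    if config.variances is not None:
        return dict(config.variances)
    out = {}
    for c in config.continuous:
        v = float(df_all[c].astype(float).var(ddof=1))
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"pooled variance of criterion {c!r} is not positive")
        out[c] = v
    return out


def _distance_matrix(a: pd.DataFrame, b: pd.DataFrame, variances: dict[str, float],
                     criteria: tuple[str, ...]) -> np.ndarray:
    d2 = np.zeros((len(a), len(b)))
    for c in criteria:
        xa = a[c].to_numpy(dtype=float)[:, None]
        xb = b[c].to_numpy(dtype=float)[None, :]
        d2 += (xa - xb) ** 2 / variances[c]
    return np.sqrt(d2)


def _greedy_assignment(cost: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, m = cost.shape
    order = np.dstack(np.unravel_index(np.argsort(cost, axis=None, kind="stable"),
                                       cost.shape))[0]
    used_r = np.zeros(n, bool)
    used_c = np.zeros(m, bool)
    rows, cols = [], []
    for r, c in order:
        if not used_r[r] and not used_c[c]:
            used_r[r] = used_c[c] = True
            rows.append(r)
            cols.append(c)
            if len(rows) == min(n, m):
                break
    return np.array(rows, dtype=int), np.array(cols, dtype=int)


def nsm_match(survivors: Sequence[SubjectRecord], nonsurvivors: Sequence[SubjectRecord],
              config: MatchConfig | None = None) -> MatchedCohort:
    """Variance-normalized 1:1 matching within exact (stage, gender) strata.

    Distances are ``sqrt(sum_c (x_ic - x_jc)**2 / var_c)`` over the
    continuous criteria with variances pooled over all eligible subjects;
    pairing is a global minimum-total-distance assignment per stratum, so
    every stratum yields ``min(stratum sizes)`` pairs.  Subjects are sorted
    by pid for deterministic tie-breaking.
    """
    cfg = config or MatchConfig()
    cfg.validate()
    if not survivors or not nonsurvivors:
        raise ValueError("both groups must be nonempty after exclusions")
    df_s = _criteria_frame(survivors, cfg)
    df_n = _criteria_frame(nonsurvivors, cfg)
    variances = _pooled_variances(pd.concat([df_s, df_n], ignore_index=True), cfg)

    cells = sorted(set(map(tuple, df_s[list(cfg.exact)].itertuples(index=False)))
                   | set(map(tuple, df_n[list(cfg.exact)].itertuples(index=False))))
    pair_rows = []
    stratum_rows = []
    for cell in cells:
        sel_s = np.ones(len(df_s), bool)
        sel_n = np.ones(len(df_n), bool)
        for key, val in zip(cfg.exact, cell):
            sel_s &= (df_s[key] == val).to_numpy()
            sel_n &= (df_n[key] == val).to_numpy()
        sub_s = df_s.loc[sel_s].reset_index(drop=True)
        sub_n = df_n.loc[sel_n].reset_index(drop=True)
        n_pairs = min(len(sub_s), len(sub_n))
        stratum_rows.append(dict(zip(cfg.exact, cell))
                            | {"n_survivors": len(sub_s), "n_nonsurvivors": len(sub_n),
                               "n_pairs": n_pairs})
        if n_pairs == 0:
            logger.info("stratum %s: empty on one side, zero pairs", cell)
            continue
        cost = _distance_matrix(sub_s, sub_n, variances, cfg.continuous)
        if cfg.method == "optimal":
            ri, ci = linear_sum_assignment(cost)
        else:
            ri, ci = _greedy_assignment(cost)
        for r, c in zip(ri, ci):
            pair_rows.append(dict(zip(cfg.exact, cell))
                             | {"survivor_pid": sub_s.at[r, "pid"],
                                "nonsurvivor_pid": sub_n.at[c, "pid"],
                                "distance": float(cost[r, c])})
    pairs = pd.DataFrame(pair_rows, columns=["survivor_pid", "nonsurvivor_pid",
                                             "distance", *cfg.exact])
    if len(pairs):
        pairs = pairs.sort_values(["survivor_pid"], kind="stable").reset_index(drop=True)
    cohort = MatchedCohort(pairs=pairs, stratum_log=pd.DataFrame(stratum_rows))
    cohort.balance = balance_check(cohort, survivors, nonsurvivors, cfg)
    return cohort


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 1 or b.size < 1:
        return float("nan")
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    denom = np.sqrt((va + vb) / 2.0)
    diff = a.mean() - b.mean()
    if denom == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(abs(diff) / denom)


def balance_check(cohort: MatchedCohort, survivors: Sequence[SubjectRecord],
                  nonsurvivors: Sequence[SubjectRecord],
                  config: MatchConfig | None = None) -> pd.DataFrame:
    """Standardized mean differences per criterion, before and after matching."""
    cfg = config or MatchConfig()
    if cohort.n_pairs == 0:
        raise ValueError("cannot compute balance for an empty cohort")
    df_s = records_to_frame(survivors).set_index("pid")
    df_n = records_to_frame(nonsurvivors).set_index("pid")
    rows = []
    for c in cfg.continuous:
        before = _smd(df_s[c].to_numpy(dtype=float), df_n[c].to_numpy(dtype=float))
        after = _smd(df_s.loc[cohort.survivor_pids, c].to_numpy(dtype=float),
                     df_n.loc[cohort.nonsurvivor_pids, c].to_numpy(dtype=float))
        rows.append({"criterion": c, "smd_before": before, "smd_after": after})
    return pd.DataFrame(rows)
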