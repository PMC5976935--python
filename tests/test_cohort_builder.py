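import dataclasses

import numpy as np
import pytest

from ldctbio.cohort_builder import (MatchConfig, apply_exclusions, balance_check,
                                    derive_all, derive_fields, nsm_match)
from ldctbio.io_formats import SubjectRecord
from ldctbio.synthetic_data import RosterConfig, make_roster


def _subject(pid, stage="I", gender="male", age=64.0, bmi_hw=(80.0, 1.7),
             pkyr=50.0, st=1000.0, death="alive"):
    w, h = bmi_hw
    return derive_fields(SubjectRecord(
        pid=pid, age=age, gender=gender, height=h, weight=w, pkyr=pkyr,
        stage=stage, screen_detected=True, death_lc=death,
        candx_days=100.0, fup_days=100.0 + st))


class TestDeriveFields:
    def test_bmi_closed_form(self):
        rec = derive_fields(SubjectRecord(pid="1", weight=80.0, height=1.7,
                                          candx_days=0.0, fup_days=10.0))
        assert rec.bmi == pytest.approx(27.68, abs=0.005)

    def test_zero_survival_time(self):
        rec = derive_fields(SubjectRecord(pid="1", weight=80.0, height=1.7,
                                          candx_days=500.0, fup_days=500.0))
        assert rec.survival_time == 0.0

    def test_missing_height_flags_record(self):
        rec = derive_fields(SubjectRecord(pid="1", weight=80.0,
                                          candx_days=0.0, fup_days=10.0))
        assert rec.bmi is None
        assert "bmi_underivable" in rec.flags


class TestApplyExclusions:
    def test_default_roster_flow_counts(self, default_roster):
        survivors, nonsurvivors, log = apply_exclusions(derive_all(default_roster))
        assert log.nonsurvivors_lc == 182       # eligible before stage filtering
        assert log.unrelated_death == 34
        assert log.survivors_initial == 373
        assert log.nonsurvivors_initial == 216
        assert log.survivors_eligible == 358 == len(survivors)
        assert log.nonsurvivors_eligible == 133 == len(nonsurvivors)
        assert log.missing_stage_survivors == 11

    def test_stage_iv_only_roster_empties_both_groups(self):
        roster = [_subject("1", stage="IV"), _subject("2", stage="IV",
                                                      death="lung_cancer_death")]
        s, n, log = apply_exclusions(roster)
        assert s == [] and n == []
        assert log.stage_iv_survivors == 1 and log.stage_iv_nonsurvivors == 1

    def test_missing_stage_excluded_with_own_reason(self):
        roster = [_subject("1", stage=None), _subject("2")]
        s, _, log = apply_exclusions(roster)
        assert len(s) == 1
        assert log.missing_stage_survivors == 1


class TestNSMMatch:
    def test_identical_subjects_distance_zero(self):
        s = [_subject("s1"), _subject("s2", age=70.0, bmi_hw=(90.0, 1.8), pkyr=80.0, st=2000.0)]
        n = [_subject("n1", death="lung_cancer_death")]
        cohort = nsm_match(s, n)
        pair = cohort.pairs.iloc[0]
        assert pair["survivor_pid"] == "s1" and pair["distance"] == 0.0

    def test_pair_count_is_min_of_stratum_sizes(self, default_roster):
        s, n, _ = apply_exclusions(derive_all(default_roster))
        cohort = nsm_match(s, n)
        for _, row in cohort.stratum_log.iterrows():
            assert row["n_pairs"] == min(row["n_survivors"], row["n_nonsurvivors"])
        per_stage = cohort.pairs.groupby("stage").size()
        assert per_stage["I"] == 49 and per_stage["II"] == 19 and per_stage["III"] == 22

    def test_invariant_to_affine_rescaling_of_a_criterion(self):
        rng = np.random.default_rng(0)
        s = [_subject(f"s{i}", age=float(rng.normal(64, 5)), pkyr=float(rng.uniform(30, 90)),
                      st=float(rng.uniform(500, 2500)),
                      bmi_hw=(float(rng.normal(80, 10)), 1.7)) for i in range(12)]
        n = [_subject(f"n{i}", age=float(rng.normal(64, 5)), pkyr=float(rng.uniform(30, 90)),
                      st=float(rng.uniform(200, 1500)),
                      bmi_hw=(float(rng.normal(80, 10)), 1.7), death="lung_cancer_death")
             for i in range(8)]
        base = nsm_match(s, n)
        scaled = [dataclasses.replace(r, pkyr=10.0 * r.pkyr + 3.0) for r in s]
        scaled_n = [dataclasses.replace(r, pkyr=10.0 * r.pkyr + 3.0) for r in n]
        rescaled = nsm_match(scaled, scaled_n)
        assert base.pairs[["survivor_pid", "nonsurvivor_pid"]].equals(
            rescaled.pairs[["survivor_pid", "nonsurvivor_pid"]])
        np.testing.assert_allclose(base.pairs["distance"], rescaled.pairs["distance"])

    def test_invariant_to_input_row_order(self):
        rng = np.random.default_rng(1)
        s = [self._varied(f"s{i}", rng) for i in range(10)]
        n = [self._varied(f"n{i}", rng, death="lung_cancer_death") for i in range(6)]
        a = nsm_match(s, n)
        b = nsm_match(list(reversed(s)), list(reversed(n)))
        assert a.pairs.equals(b.pairs)

    @staticmethod
    def _varied(pid, rng, death="alive"):
        return _subject(pid, age=float(rng.normal(64, 6)),
                        pkyr=float(rng.uniform(30, 90)),
                        st=float(rng.uniform(200, 2500)),
                        bmi_hw=(float(rng.normal(80, 10)), 1.7), death=death)

    def test_paired_subjects_share_stage_and_gender_and_pids_unique(self, default_roster):
        s, n, _ = apply_exclusions(derive_all(default_roster))
        cohort = nsm_match(s, n)
        assert cohort.pairs["survivor_pid"].is_unique
        assert cohort.pairs["nonsurvivor_pid"].is_unique
        lookup = {r.pid: r for r in s + n}
        for _, row in cohort.pairs.iterrows():
            a, b = lookup[row["survivor_pid"]], lookup[row["nonsurvivor_pid"]]
            assert a.stage == b.stage and a.gender == b.gender

    def test_optimal_total_distance_not_worse_than_greedy(self):
        rng = np.random.default_rng(2)
        s = [self._varied(f"s{i}", rng) for i in range(15)]
        n = [self._varied(f"n{i}", rng, death="lung_cancer_death") for i in range(15)]
        opt = nsm_match(s, n, MatchConfig(method="optimal"))
        greedy = nsm_match(s, n, MatchConfig(method="greedy"))
        assert opt.pairs["distance"].sum() <= greedy.pairs["distance"].sum() + 1e-12

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            nsm_match([], [_subject("n1", death="lung_cancer_death")])


class TestBalance:
    def test_perfect_pairs_have_zero_smd(self):
        s = [_subject(f"s{i}", age=60.0 + i, pkyr=40.0 + 5 * i, st=900.0 + 100 * i,
                      bmi_hw=(70.0 + 3 * i, 1.7)) for i in range(4)]
        n = [_subject(f"n{i}", age=60.0 + i, pkyr=40.0 + 5 * i, st=900.0 + 100 * i,
                      bmi_hw=(70.0 + 3 * i, 1.7), death="lung_cancer_death")
             for i in range(4)]
        cohort = nsm_match(s, n)
        assert (cohort.balance["smd_after"] == 0.0).all()

    def test_planted_age_shift_reduced_by_matching(self):
        improvements = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s = [_subject(f"s{i}", age=float(rng.normal(66, 5)),
                          pkyr=float(rng.uniform(30, 90)), st=float(rng.uniform(400, 2400)),
                          bmi_hw=(float(rng.normal(80, 10)), 1.7)) for i in range(40)]
            n = [_subject(f"n{i}", age=float(rng.normal(62, 5)),
                          pkyr=float(rng.uniform(30, 90)), st=float(rng.uniform(400, 2400)),
                          bmi_hw=(float(rng.normal(80, 10)), 1.7),
                          death="lung_cancer_death") for i in range(12)]
            cohort = nsm_match(s, n)
            row = cohort.balance.set_index("criterion").loc["age"]
            if row["smd_after"] < row["smd_before"]:
                improvements += 1
        assert improvements >= 18

    def test_single_pair_cohort_computes_without_error(self):
        s = [_subject("s1")]
        n = [_subject("n1", age=66.0, pkyr=60.0, st=1400.0, bmi_hw=(90.0, 1.7),
                      death="lung_cancer_death")]
        cohort = nsm_match(s, n)
        bal = balance_check(cohort, s, n)
        assert len(bal) == 4
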