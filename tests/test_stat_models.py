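import math

import numpy as np
import pandas as pd
import pytest

from ldctbio.stat_models import (AnalysisSpec, build_design, fit_cox, fit_logistic,
                                 group_compare, stratified_analysis)
from ldctbio.synthetic_data import make_logistic_data, make_survival_data


def _se_from_ci(row):
    return (math.log(row["ci_high"]) - math.log(row["ci_low"])) / (2 * 1.959964)


class TestLogistic:
    def test_null_simulation_recovers_zero(self):
        d = make_logistic_data(2000, {"x1": 0.0, "x2": 0.0}, seed=0)
        res = fit_logistic(d, AnalysisSpec(outcome="y", covariates=("x1", "x2")))
        for _, row in res.terms.iterrows():
            assert abs(row["coefficient"]) < 3 * _se_from_ci(row)

    def test_planted_fat_attenuation_effect_recovered(self):
        # 0.23 log-odds per HU on a fat-attenuation-like covariate
        d = make_logistic_data(5000, {"fat": 0.23}, seed=0,
                               covariates={"fat": ("normal", -91.0, 4.5)})
        res = fit_logistic(d, AnalysisSpec(outcome="y", covariates=("fat",)))
        row = res.term("fat")
        assert abs(row["coefficient"] - 0.23) < 3 * _se_from_ci(row)

    def test_two_by_two_odds_ratio_equals_cross_product(self):
        # x=0: 40/60 events, x=1: 70/30 events -> OR = (70*60)/(30*40) = 3.5
        x = np.repeat([0, 1], 100)
        y = np.concatenate([np.repeat([1, 0], [40, 60]), np.repeat([1, 0], [70, 30])])
        res = fit_logistic(pd.DataFrame({"x": x, "y": y}),
                           AnalysisSpec(outcome="y", covariates=("x",)))
        assert res.term("x")["ratio"] == pytest.approx(3.5, rel=1e-5)

    def test_constant_term_raises_named_error(self):
        d = make_logistic_data(200, {"x": 0.5}, seed=1)
        d["const_col"] = 1.0
        with pytest.raises(ValueError, match="const_col"):
            fit_logistic(d, AnalysisSpec(outcome="y", covariates=("x", "const_col")))

    def test_nonbinary_outcome_raises(self):
        d = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [0, 0, 0]})
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(d, AnalysisSpec(outcome="y", covariates=("x",)))


class TestCox:
    def test_planted_hazard_ratio_two_recovered(self):
        d = make_survival_data(5000, {"group": math.log(2.0)}, 0.0, seed=0,
                               covariates={"group": ("binary", 0.5)})
        res = fit_cox(d, AnalysisSpec(time_col="time", event_col="event",
                                      covariates=("group",)))
        row = res.term("group")
        assert abs(row["coefficient"] - math.log(2.0)) < 3 * _se_from_ci(row)

    def test_all_censored_raises(self):
        d = make_survival_data(100, {"x": 0.5}, 0.0, seed=2)
        d["event"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_cox(d, AnalysisSpec(time_col="time", event_col="event",
                                    covariates=("x",)))

    def test_model_chi_square_df_is_ten_for_default_spec(self):
        # full design: muscle + fat + emphysema + 3 CAC + stage + age + gender
        # + height = 10 covariate terms
        rng = np.random.default_rng(3)
        n = 400
        d = pd.DataFrame({
            "muscle_area": rng.normal(31, 7, n),
            "fat_attenuation": rng.normal(-91, 4.5, n),
            "emphysema": rng.uniform(0, 0.5, n),
            "cac_grade": rng.integers(0, 4, n),
            "stage": rng.choice(["I", "II", "III"], n),
            "age": rng.normal(64, 5, n),
            "gender": rng.choice(["male", "female"], n),
            "height": rng.normal(1.7, 0.1, n),
            "nonsurvivor": rng.integers(0, 2, n),
            "survival_time": rng.uniform(100, 2500, n),
        })
        logit = fit_logistic(d)
        cox = fit_cox(d)
        assert logit.df == 10 and cox.df == 10
        assert len(logit.terms) == 10 and len(cox.terms) == 10


class TestSelfConsistency:
    def test_exp_coefficient_equals_ratio_for_every_term(self):
        d = make_logistic_data(500, {"x1": 0.4, "x2": -0.2}, seed=4)
        res = fit_logistic(d, AnalysisSpec(outcome="y", covariates=("x1", "x2")))
        np.testing.assert_array_equal(res.terms["ratio"].to_numpy(),
                                      np.exp(res.terms["coefficient"].to_numpy()))
        ds = make_survival_data(500, {"x1": 0.4, "x2": -0.2}, 0.2, seed=4)
        rc = fit_cox(ds, AnalysisSpec(time_col="time", event_col="event",
                                      covariates=("x1", "x2")))
        np.testing.assert_array_equal(rc.terms["ratio"].to_numpy(),
                                      np.exp(rc.terms["coefficient"].to_numpy()))
        for res_ in (res, rc):
            assert (res_.terms["ci_low"] <= res_.terms["ratio"]).all()
            assert (res_.terms["ratio"] <= res_.terms["ci_high"]).all()


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = group_compare(a, a)
        assert res.p_value == pytest.approx(1.0)
        assert res.mean_a == res.mean_b

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        res = group_compare(rng.normal(0, 1, 200), rng.normal(1, 1, 200))
        assert res.p_value < 0.001

    def test_hand_computed_welch_three_vs_three(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 9.0])
        # Welch by hand
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
        from scipy.stats import t as tdist
        p = 2 * tdist.sf(abs(t), df)
        res = group_compare(a, b)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [1.0, 2.0])


class TestStratifiedAnalysis:
    def _cohort(self, seed=6, deficit_stage="I"):
        rng = np.random.default_rng(seed)
        rows = []
        for stage, n_per in (("I", 80), ("II", 60)):
            for grp in (0, 1):
                mu = 32.0
                if grp == 1 and stage == deficit_stage:
                    mu = 27.0
                for _ in range(n_per):
                    rows.append({"stage": stage, "nonsurvivor": grp,
                                 "muscle_area": rng.normal(mu, 5.0),
                                 "pkyr": float(rng.uniform(30, 90)),
                                 "copd": bool(rng.uniform() < 0.3)})
        return pd.DataFrame(rows)

    def test_planted_stage_specific_deficit_detected(self):
        df = self._cohort()
        table = stratified_analysis(df, "stage").set_index("stratum")
        assert table.loc["I", "p_value"] < 0.01
        assert table.loc["II", "p_value"] > 0.05

    def test_constant_stratifier_equals_unstratified(self):
        df = self._cohort()
        df["stage"] = "I"
        table = stratified_analysis(df, "stage")
        assert len(table) == 1
        overall = group_compare(df.loc[df["nonsurvivor"] == 0, "muscle_area"],
                                df.loc[df["nonsurvivor"] == 1, "muscle_area"])
        assert table.iloc[0]["p_value"] == pytest.approx(overall.p_value)

    def test_pack_year_boundary_goes_to_low_stratum(self):
        df = self._cohort()
        df.loc[0, "pkyr"] = 50.0
        table = stratified_analysis(df, "pkyr")
        assert set(table["stratum"]) == {"<=50", ">50"}
        low = df["pkyr"] <= 50.0
        assert table.set_index("stratum").loc["<=50", "n_survivors"] + \
            table.set_index("stratum").loc["<=50", "n_nonsurvivors"] == int(low.sum())

    def test_one_sided_stratum_flagged_not_dropped(self):
        df = self._cohort().head(50).copy()
        df["stage"] = "I"
        df.loc[df.index[:2], "stage"] = "III"
        df.loc[df.index[:2], "nonsurvivor"] = 0
        table = stratified_analysis(df, "stage").set_index("stratum")
        assert "III" in table.index
        assert table.loc["III", "flag"] != ""
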