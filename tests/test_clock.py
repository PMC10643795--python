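"""QC, split, fit, normalization, scoring, sweeps, serialization."""

import numpy as np
import pandas as pd
import pytest

from physiage import (
    CohortSimParams,
    NormalizationTable,
    PUBLISHED_MODEL,
    PhysiAgeModel,
    build_normalization,
    fit_model,
    load_model,
    physiage_score,
    qc_filter,
    raw_predict,
    remove_step_outliers,
    save_model,
    score_table,
    simulate_nhanes_cohort,
    split_train_test,
    whatif_sweep,
)
from physiage.clock import SingularModelError
from physiage.pipeline import attach_phenoage


class TestRawPredict:
    def test_printed_equation_evaluation(self):
        # -18.5 + 3.348*6.0 - 0.0004715*5000 + 0.3988*130, by hand: 51.0745
        assert raw_predict(PUBLISHED_MODEL, 0, 6.0, 5000, 130) == pytest.approx(
            51.0745, abs=1e-10
        )

    def test_sex_coefficient_is_exact_difference(self):
        male = raw_predict(PUBLISHED_MODEL, 1, 6.0, 5000, 130)
        female = raw_predict(PUBLISHED_MODEL, 0, 6.0, 5000, 130)
        assert male - female == pytest.approx(1.972, abs=1e-12)

    def test_zero_model_zero_output(self):
        zero = PhysiAgeModel(0.0, {"sex": 0, "glucose": 0, "avg_daily_steps": 0,
                                   "systolic_bp": 0})
        assert raw_predict(zero, 0, 1.0, 0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "kwargs", [dict(sex=2), dict(glucose=0.0), dict(steps=-1.0)]
    )
    def test_invalid_inputs_rejected(self, kwargs):
        base = dict(sex=0, glucose=5.0, steps=1000.0, systolic_bp=120.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            raw_predict(PUBLISHED_MODEL, **base)


class TestQCFilter:
    @pytest.fixture()
    def toy_table(self):
        rows = []
        for i in range(10):
            rows.append(
                dict(id=i, age=40 + i, is_85plus=False, sex=i % 2,
                     glucose=5.0, systolic_bp=120.0, avg_daily_steps=8000.0)
            )
        # plant three violations: zero glucose, missing steps, age 85
        rows[2]["glucose"] = 0.0
        rows[5]["avg_daily_steps"] = np.nan
        rows[8]["age"] = 85
        rows[8]["is_85plus"] = True
        return pd.DataFrame(rows)

    def test_planted_violations_counted(self, toy_table):
        filtered, held, report = qc_filter(toy_table)
        assert len(filtered) == 7
        assert report.n_excluded == 3
        assert report.n_zero_or_missing == 2
        assert report.n_85plus == 1

    def test_85plus_held_not_dropped(self, toy_table):
        _, held, _ = qc_filter(toy_table)
        assert len(held) == 1 and held.iloc[0]["age"] == 85

    def test_female_sex_code_not_a_zero_entry(self, toy_table):
        filtered, _, _ = qc_filter(toy_table)
        assert (filtered["sex"] == 0).any()

    def test_missing_column_is_schema_error(self):
        with pytest.raises(KeyError, match="avg_daily_steps"):
            qc_filter(pd.DataFrame({"age": [30], "sex": [1], "glucose": [5.0],
                                    "systolic_bp": [120.0]}))


class TestStepOutliers:
    def test_tukey_fence_by_hand(self):
        # steps {5000,6000,7000,8000,3e6}: Q1=6000, Q3=8000 (linear quartiles),
        # upper fence 8000+1.5*2000=11000, so only the 3e6 row is removed
        table = pd.DataFrame({"avg_daily_steps": [5000, 6000, 7000, 8000, 3e6]})
        out = remove_step_outliers(table)
        assert len(out) == 4 and out["avg_daily_steps"].max() == 8000

    def test_identical_steps_kept(self):
        table = pd.DataFrame({"avg_daily_steps": [7000.0] * 6})
        assert len(remove_step_outliers(table)) == 6

    def test_huge_fence_removes_nothing(self):
        table = pd.DataFrame({"avg_daily_steps": [5000, 6000, 7000, 8000, 3e6]})
        assert len(remove_step_outliers(table, k=1e9)) == 5

    def test_small_table_noop(self):
        table = pd.DataFrame({"avg_daily_steps": [1.0, 2.0, 3e6]})
        assert len(remove_step_outliers(table)) == 3


class TestSplit:
    def test_sizes_and_stratification(self, default_cohort):
        train, test = split_train_test(default_cohort, 0.8, seed=1)
        assert len(train) + len(test) == len(default_cohort)
        for sex in (0, 1):
            n_sex = (default_cohort["sex"] == sex).sum()
            n_train = (train["sex"] == sex).sum()
            assert n_train == int(np.floor(0.8 * n_sex + 0.5))

    def test_deterministic_and_disjoint(self, default_cohort):
        a_train, a_test = split_train_test(default_cohort, 0.8, seed=3)
        b_train, b_test = split_train_test(default_cohort, 0.8, seed=3)
        pd.testing.assert_frame_equal(a_train, b_train)
        assert set(a_train["id"]).isdisjoint(a_test["id"])

    def test_complementary_fractions_swap_sizes(self, default_cohort):
        a_train, _ = split_train_test(default_cohort, 0.8, seed=3)
        _, b_test = split_train_test(default_cohort, 0.2, seed=3)
        assert len(a_train) == len(b_test)


class TestFit:
    def test_exact_interpolation_of_published_coefficients(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "sex": [0, 1, 0, 1, 0, 1],
                "glucose": rng.uniform(4, 8, 6),
                "avg_daily_steps": rng.uniform(2000, 15000, 6),
                "systolic_bp": rng.uniform(100, 160, 6),
            }
        )
        table["phenoage"] = (
            -18.5 + 1.972 * table["sex"] + 3.348 * table["glucose"]
            - 0.0004715 * table["avg_daily_steps"] + 0.3988 * table["systolic_bp"]
        )
        fit = fit_model(table)
        assert fit.model.intercept == pytest.approx(-18.5, abs=1e-8)
        assert fit.model.coef_sex == pytest.approx(1.972, abs=1e-8)
        assert fit.model.coef_glucose == pytest.approx(3.348, abs=1e-8)
        assert fit.model.coef_steps == pytest.approx(-0.0004715, abs=1e-8)
        assert fit.model.coef_sysbp == pytest.approx(0.3988, abs=1e-8)

    def test_all_female_sex_inestimable(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "sex": [0] * 20,
                "glucose": rng.uniform(4, 8, 20),
                "avg_daily_steps": rng.uniform(2000, 15000, 20),
                "systolic_bp": rng.uniform(100, 160, 20),
            }
        )
        table["phenoage"] = rng.uniform(20, 80, 20)
        with pytest.raises(SingularModelError, match="sex"):
            fit_model(table)

    def test_planted_coefficients_inside_ci(self):
        cohort = simulate_nhanes_cohort(
            CohortSimParams(n_participants=2673, seed=17, mode="planted_linear")
        )
        cohort = attach_phenoage(cohort)
        fit = fit_model(cohort)
        planted = {"intercept": -18.5, "sex": 1.972, "glucose": 3.348,
                   "avg_daily_steps": -0.0004715, "systolic_bp": 0.3988}
        for name, truth in planted.items():
            lo, hi = fit.conf_int[name]
            assert lo <= truth <= hi, f"{name}: {truth} outside [{lo}, {hi}]"


class TestNormalization:
    def test_median_is_nf(self):
        train = pd.DataFrame(
            {
                "age": [50, 50, 50],
                "sex": [0, 0, 0],
                "glucose": [5, 5, 5],
                "avg_daily_steps": [8000, 8000, 8000],
                "systolic_bp": [100, 125, 150],
            }
        )
        model = PhysiAgeModel(0.0, {"systolic_bp": 1.0})
        nf = build_normalization(train, model)
        assert nf.nf(50) == 125.0

    def test_gap_filled_by_interpolation_and_flagged(self):
        train = pd.DataFrame(
            {
                "age": [40, 42],
                "systolic_bp": [100.0, 120.0],
            }
        )
        model = PhysiAgeModel(0.0, {"systolic_bp": 1.0})
        nf = build_normalization(train, model)
        assert nf.nf(41) == pytest.approx((nf.nf(40) + nf.nf(42)) / 2)
        assert 41 in nf.interpolated

    def test_median_physiage_equals_age_on_training_data(self, default_cohort):
        cohort = attach_phenoage(default_cohort)
        fit = fit_model(cohort)
        nf = build_normalization(cohort, fit.model)
        scored = score_table(fit.model, nf, cohort)
        for age, group in scored.groupby("age"):
            assert np.median(group["physiage"]) == pytest.approx(age, abs=1e-9)
            assert np.median(group["delta_age"]) == pytest.approx(0.0, abs=1e-9)

    def test_nf_clamped_above_table_maximum(self):
        nf = NormalizationTable({60: 50.0, 61: 51.0})
        assert nf.nf(85) == 51.0
        with pytest.raises(KeyError):
            nf.nf(59)

    def test_nf_csv_round_trip(self, tmp_path):
        nf = NormalizationTable({60: 50.0, 61: 51.0, 62: 52.5},
                                interpolated=frozenset({61}))
        path = tmp_path / "nf.csv"
        nf.to_csv(path)
        again = NormalizationTable.from_csv(path)
        assert again.values == nf.values
        assert again.interpolated == nf.interpolated


class TestScoring:
    def test_fixed_point_of_normalization(self):
        nf = NormalizationTable({60: 51.0745})
        scored = physiage_score(PUBLISHED_MODEL, nf, age=60, sex=0, glucose=6.0,
                                steps=5000, systolic_bp=130)
        assert scored["physiage"] == pytest.approx(60.0, abs=1e-9)
        assert scored["delta_age"] == pytest.approx(0.0, abs=1e-9)

    def test_worked_example_steps_change(self):
        # NF(60) calibrated so the 5,000-step profile scores 61.34
        raw5k = raw_predict(PUBLISHED_MODEL, 0, 6.0, 5000, 130)
        nf = NormalizationTable({60: raw5k * 60 / 61.34})
        assert nf.nf(60) == pytest.approx(49.96, abs=0.01)
        scored = physiage_score(PUBLISHED_MODEL, nf, age=60, sex=0, glucose=6.0,
                                steps=12000, systolic_bp=130)
        assert scored["physiage"] == pytest.approx(57.38, abs=0.01)

    def test_85plus_scored_at_default_age(self, reference_nf):
        scored = physiage_score(PUBLISHED_MODEL, reference_nf, age=91, sex=1,
                                glucose=6.5, steps=3000, systolic_bp=140,
                                is_85plus=True)
        raw = raw_predict(PUBLISHED_MODEL, 1, 6.5, 3000, 140)
        expected = raw / reference_nf.nf(85) * 85
        assert scored["physiage"] == pytest.approx(expected)

    def test_serialization_round_trip_reproduces_scores(self, tmp_path, reference_nf):
        path = tmp_path / "model.yaml"
        save_model(PUBLISHED_MODEL, path)
        again = load_model(path)
        a = physiage_score(PUBLISHED_MODEL, reference_nf, age=50, sex=1,
                           glucose=5.5, steps=9000, systolic_bp=125)
        b = physiage_score(again, reference_nf, age=50, sex=1,
                           glucose=5.5, steps=9000, systolic_bp=125)
        assert a == b


class TestSweeps:
    PROFILE = dict(age=60, sex=0, glucose=6.0, avg_daily_steps=5000,
                   systolic_bp=130)

    def test_steps_sweep_shape_and_monotonicity(self, reference_nf):
        sweep = whatif_sweep(self.PROFILE, "avg_daily_steps", PUBLISHED_MODEL,
                             reference_nf)
        assert len(sweep) == 16
        assert (np.diff(sweep["physiage"]) < 0).all()

    def test_glucose_sweep_shape_and_monotonicity(self, reference_nf):
        sweep = whatif_sweep(self.PROFILE, "glucose", PUBLISHED_MODEL, reference_nf)
        assert len(sweep) == 7
        assert (np.diff(sweep["physiage"]) > 0).all()

    def test_sweep_rows_equal_pointwise_calls(self, reference_nf):
        sweep = whatif_sweep(self.PROFILE, "glucose", PUBLISHED_MODEL, reference_nf)
        for _, row in sweep.iterrows():
            direct = physiage_score(
                PUBLISHED_MODEL, reference_nf, age=60, sex=0,
                glucose=row["glucose"], steps=5000, systolic_bp=130,
            )
            assert row["physiage"] == direct["physiage"]
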