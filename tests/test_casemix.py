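import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from hospprofile.casemix import (
    AGE_EDGES,
    BandEdges,
    EmptyCohortError,
    ExclusionRules,
    RiskModel,
    apply_exclusions,
    band_index,
    c_statistic,
    derive_bands,
    design_matrix,
    expected_deaths,
    fit_risk_model,
    predict_probabilities,
)
from hospprofile.cohort import CohortConfig, generate_cohort


def _patients(rows):
    return pd.DataFrame(
        rows,
        columns=["hospital_id", "age", "sbp", "heart_rate", "diagnosis", "died_30d"],
    ).assign(died_30d=lambda d: pd.array(d["died_30d"], dtype="Int64"))


def _base_rows(n, hospital_id=1, died=0):
    return [[hospital_id, 60, 130, 80, "chest_pain", died] for _ in range(n)]


class TestApplyExclusions:
    def test_age_101_removed(self):
        rows = _base_rows(10, died=1) + [[1, 101, 130, 80, "chest_pain", 1]]
        out, report = apply_exclusions(_patients(rows), ExclusionRules())
        assert len(out) == 10
        assert report.removed_age == 1

    def test_range_endpoints_inclusive(self):
        rows = [
            [1, 18, 49, 20, "chest_pain", 1],
            [1, 100, 250, 200, "chest_pain", 1],
        ] + _base_rows(10, died=1)
        out, _ = apply_exclusions(_patients(rows), ExclusionRules())
        assert len(out) == 12

    def test_single_admission_hospital_removed(self):
        rows = _base_rows(20, hospital_id=1, died=1) + [[2, 60, 130, 80, "chest_pain", 1]]
        out, report = apply_exclusions(_patients(rows), ExclusionRules())
        assert set(out["hospital_id"]) == {1}
        assert report.hospitals_removed_few_admissions == 1

    def test_few_deaths_hospital_removed(self):
        rows = _base_rows(20, hospital_id=1, died=1) + _base_rows(30, hospital_id=2, died=0)
        out, report = apply_exclusions(_patients(rows), ExclusionRules(min_deaths=5))
        assert set(out["hospital_id"]) == {1}
        assert report.hospitals_removed_few_deaths == 1

    def test_excess_missingness_hospital_removed(self):
        missing = [[2, 60, 130, 80, "chest_pain", None] for _ in range(15)]
        rows = _base_rows(20, hospital_id=1, died=1) + _base_rows(6, 2, died=1) + missing
        out, report = apply_exclusions(_patients(rows), ExclusionRules(max_missing=0.5))
        assert set(out["hospital_id"]) == {1}
        assert report.hospitals_removed_missingness == 1

    def test_identity_when_rules_span_all_data(self):
        frame, _ = generate_cohort(CohortConfig(n_hospitals=5, size_median=100, seed=3))
        rules = ExclusionRules(min_admissions=1, min_deaths=0, max_missing=1.0)
        out, report = apply_exclusions(frame, rules)
        pd.testing.assert_frame_equal(out, frame)
        assert report.patients_in == report.patients_out

    def test_empty_survivors_signalled(self):
        rows = [[1, 101, 130, 80, "chest_pain", 1]] * 5
        with pytest.raises(EmptyCohortError):
            apply_exclusions(_patients(rows), ExclusionRules())

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            ExclusionRules(age_range=(100, 18))


class TestDeriveBands:
    def test_uniform_grid_gives_equal_fifths(self):
        values = np.tile(np.arange(100, 200), 5)  # 100 distinct, each x5
        rows = [[1, 60, v, 40 + (i % 9) * 10, "chest_pain", 0] for i, v in enumerate(values)]
        edges = derive_bands(_patients(rows))
        bands = band_index(values.astype(float), edges.sbp)
        counts = np.bincount(bands, minlength=5)
        assert counts.max() - counts.min() <= 5  # one grid value per edge

    def test_age_band_assignment(self):
        assert band_index(np.array([64.0]), AGE_EDGES)[0] == 1  # 55-64
        assert band_index(np.array([65.0]), AGE_EDGES)[0] == 2  # 65-74
        assert band_index(np.array([54.0]), AGE_EDGES)[0] == 0
        assert band_index(np.array([85.0]), AGE_EDGES)[0] == 4  # >= 85

    def test_published_quintile_edges_recovered(self):
        # piecewise-uniform SBP whose fifths sit at 117/133/147/165
        rng = np.random.default_rng(0)
        blocks = [(80, 117), (117, 133), (133, 147), (147, 165), (165, 250)]
        values = np.concatenate([rng.uniform(lo, hi, 4000) for lo, hi in blocks])
        rows = [[1, 60, v, 40 + (i % 9) * 10, "chest_pain", 0] for i, v in enumerate(values)]
        edges = derive_bands(_patients(rows))
        np.testing.assert_allclose(edges.sbp, (117, 133, 147, 165), atol=1.0)

    def test_too_few_distinct_values(self):
        rows = [[1, 60, 130, 80, "chest_pain", 0]] * 20
        with pytest.raises(ValueError, match="distinct"):
            derive_bands(_patients(rows))

    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            BandEdges(sbp=(117, 117, 147, 165))


def _null_cohort(n, seed=0):
    rng = np.random.default_rng(seed)
    return _patients(
        [
            [
                1 + i % 10,
                int(rng.integers(20, 100)),
                int(rng.integers(60, 240)),
                int(rng.integers(30, 190)),
                rng.choice(["chest_pain", "st_elevation", "other"]),
                int(rng.random() < 0.1),
            ]
            for i in range(n)
        ]
    )


class TestFitRiskModel:
    def test_null_model_effects_near_zero(self):
        patients = _null_cohort(20_000)
        edges = derive_bands(patients)
        model = fit_risk_model(patients, edges)
        for name, eff in model.category_effects.items():
            se = model.standard_errors[name]
            assert abs(eff) < 4 * se, f"{name}: {eff} vs se {se}"

    def test_parameter_recovery(self):
        # cohort generated from known coefficients with no hospital
        # variation: every coefficient recovered within 3 SEs
        config = CohortConfig(sigma0_true=0.0, seed=21)
        frame, truth = generate_cohort(config)
        filtered, _ = apply_exclusions(frame, ExclusionRules())
        edges = derive_bands(filtered)
        model = fit_risk_model(filtered, edges)
        coef = config.risk_coefficients
        true_by_term = {}
        from hospprofile.cohort import AGE_BAND_LABELS, DIAGNOSES

        for k in range(1, 5):
            true_by_term[f"age:{AGE_BAND_LABELS[k]}"] = coef.age[k]
            true_by_term[f"sbp:q{k + 1}"] = coef.sbp[k]
            true_by_term[f"hr:q{k + 1}"] = coef.heart_rate[k]
        for d in DIAGNOSES:
            if d != "chest_pain":
                true_by_term[f"diagnosis:{d}"] = coef.diagnosis[d]
        assert len(frame) >= 50_000
        for name, true in true_by_term.items():
            est = model.category_effects[name]
            se = model.standard_errors[name]
            assert abs(est - true) < 3 * se, f"{name}: {est} vs {true} (se {se})"
        assert abs(model.intercept - truth.intercept) < 3 * model.standard_errors["intercept"]

    def test_single_level_factor_rejected(self):
        rows = _base_rows(50, died=1) + _base_rows(50, died=0)
        patients = _patients(rows)
        patients["sbp"] = np.tile(np.arange(100, 150), 2)
        patients["heart_rate"] = np.tile(np.arange(60, 110), 2)
        patients["age"] = np.tile(np.arange(30, 80), 2)
        with pytest.raises(ValueError, match="diagnosis"):
            fit_risk_model(patients, derive_bands(patients))

    def test_missing_outcomes_dropped(self):
        patients = _null_cohort(5000)
        with_missing = patients.copy()
        extra = patients.head(500).copy()
        extra["died_30d"] = pd.array([None] * 500, dtype="Int64")
        with_missing = pd.concat([with_missing, extra], ignore_index=True)
        edges = derive_bands(patients)
        m1 = fit_risk_model(patients, edges)
        m2 = fit_risk_model(with_missing, edges)
        # the NA rows cannot enter the likelihood: fits are identical
        assert m2.log_likelihood == pytest.approx(m1.log_likelihood)
        for name, eff in m1.category_effects.items():
            assert m2.category_effects[name] == pytest.approx(eff)


class TestCStatistic:
    def test_all_ties_is_half(self):
        auc, _ = c_statistic(np.full(100, 0.3), np.r_[np.ones(30), np.zeros(70)])
        assert auc == pytest.approx(0.5)

    def test_perfect_separation_is_one(self):
        auc, _ = c_statistic(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert auc == pytest.approx(1.0)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(4)
        pred = rng.random(60)
        pred[rng.random(60) < 0.3] = 0.5  # force ties
        y = (rng.random(60) < 0.4).astype(int)
        auc, _ = c_statistic(pred, y)
        # brute force over all (death, survivor) pairs
        deaths, survivors = pred[y == 1], pred[y == 0]
        wins = half = 0
        for d in deaths:
            for s in survivors:
                if d > s:
                    wins += 1
                elif d == s:
                    half += 1
        oracle = (wins + 0.5 * half) / (len(deaths) * len(survivors))
        assert auc == pytest.approx(oracle)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_interval_contains_point(self):
        rng = np.random.default_rng(1)
        pred = rng.random(500)
        y = (rng.random(500) < pred).astype(int)
        auc, (lo, hi) = c_statistic(pred, y)
        assert lo < auc < hi


def _toy_model(edges, age_effects):
    effects = {f"age:{lab}": age_effects.get(lab, 0.0) for lab in ("55-64", "65-74", "75-84", ">=85")}
    effects.update({f"sbp:q{k}": 0.0 for k in range(2, 6)})
    effects.update({f"hr:q{k}": 0.0 for k in range(2, 6)})
    for d in ("st_elevation", "non_st_elevation", "troponin_positive", "troponin_negative", "other"):
        effects[f"diagnosis:{d}"] = 0.0
    return RiskModel(
        intercept=float(logit(0.1)),
        category_effects=effects,
        standard_errors={},
        band_edges=edges,
        c_statistic=float("nan"),
        c_statistic_ci=(float("nan"), float("nan")),
    )


class TestExpectedDeaths:
    EDGES = BandEdges(sbp=(110, 120, 130, 140), hr=(60, 70, 80, 90))

    def test_two_patient_hand_sum(self):
        # p = 0.1 at reference; second patient's band effect lifts it to 0.2
        model = _toy_model(self.EDGES, {"55-64": float(logit(0.2) - logit(0.1))})
        rows = [[1, 40, 100, 50, "chest_pain", 0], [1, 60, 100, 50, "chest_pain", 1]]
        out = expected_deaths(_patients(rows), model)
        assert out.loc[0, "expected_deaths"] == pytest.approx(0.3)
        assert out.loc[0, "observed_deaths"] == 1

    def test_six_patient_hand_summed_oracle(self):
        shift = float(logit(0.25) - logit(0.1))
        model = _toy_model(self.EDGES, {">=85": shift})
        rows = [
            [1, 40, 100, 50, "chest_pain", 0],
            [1, 90, 100, 50, "chest_pain", 1],
            [1, 90, 100, 50, "chest_pain", 0],
            [2, 40, 100, 50, "chest_pain", 0],
            [2, 40, 100, 50, "chest_pain", 0],
            [2, 90, 100, 50, "chest_pain", 1],
        ]
        out = expected_deaths(_patients(rows), model).set_index("hospital_id")
        assert out.loc[1, "expected_deaths"] == pytest.approx(0.1 + 0.25 + 0.25)
        assert out.loc[2, "expected_deaths"] == pytest.approx(0.1 + 0.1 + 0.25)
        assert out.loc[1, "observed_deaths"] == 1
        assert out.loc[2, "observed_deaths"] == 1

    def test_refit_balances_totals(self, small_summaries):
        # logistic ML score equation: sum(E) == sum(O) on training data
        assert small_summaries["expected_deaths"].sum() == pytest.approx(
            small_summaries["observed_deaths"].sum()
        )

    def test_hospital_with_no_valid_patients_rejected(self):
        model = _toy_model(self.EDGES, {})
        rows = [[1, 40, 100, 50, "chest_pain", 0], [2, 40, 100, 50, "chest_pain", None]]
        with pytest.raises(ValueError, match="zero valid"):
            expected_deaths(_patients(rows), model)

    def test_permutation_invariance(self):
        model = _toy_model(self.EDGES, {"65-74": 0.5})
        rng = np.random.default_rng(2)
        rows = [
            [int(rng.integers(1, 4)), int(rng.integers(20, 100)), 100, 50, "chest_pain", int(rng.random() < 0.2)]
            for _ in range(60)
        ]
        patients = _patients(rows)
        shuffled = patients.sample(frac=1, random_state=1).reset_index(drop=True)
        a = expected_deaths(patients, model)
        b = expected_deaths(shuffled, model)
        pd.testing.assert_frame_equal(a, b)


def test_banding_conserves_patients(small_cohort):
    _, frame, _ = small_cohort
    edges = derive_bands(frame)
    X, names = design_matrix(frame, edges)
    assert X.shape == (len(frame), 1 + 4 + 4 + 4 + 5)
    # each factor's indicator columns plus implicit reference cover everyone
    age_cols = X[:, 1:5]
    assert np.all(age_cols.sum(axis=1) <= 1)


def test_predict_probabilities_in_unit_interval(small_cohort):
    _, frame, _ = small_cohort
    edges = derive_bands(frame)
    model = fit_risk_model(frame, edges)
    p = predict_probabilities(frame, model)
    assert np.all((p > 0) & (p < 1))
    assert 0.7 < model.c_statistic < 0.9
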