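"""Age regression: splits, transforms, screening, stepwise, evaluation."""
import itertools

import numpy as np
import pandas as pd
import pytest

from epiage import (
    AgeRegression,
    AgeRegressionResults,
    StepwiseConfig,
    TransformSpec,
    evaluate_predictions,
    fit_model,
    fit_power_transform,
    split_train_test,
    stepwise_select,
    test_assay_equivalence as assay_equivalence,
    univariate_screen,
)
from epiage.agemodel import DEFAULT_CATEGORY_BOUNDS


def _synthetic_training(rng, n=200, n_cpgs=10, informative=(0, 1), noise=1.0,
                        coefs=(0.5, -0.3), intercept=10.0):
    """Age driven by a known CpG subset; remaining CpGs are pure noise."""
    meth = pd.DataFrame(
        rng.uniform(5, 95, size=(n, n_cpgs)),
        columns=[f"M{i}_C1" for i in range(n_cpgs)],
    )
    age = intercept + sum(
        c * meth.iloc[:, i] for c, i in zip(coefs, informative)
    ) + rng.normal(0, noise, n)
    return age.to_numpy(), meth


class TestSplit:
    def _cohort(self, n=160, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "age": rng.uniform(1, 75, n),
            "sex": rng.permutation(["M"] * (n // 2) + ["F"] * (n - n // 2)),
        })

    def test_112_48_split(self):
        df = split_train_test(self._cohort(), train_n=112, seed=1)
        assert (df["split"] == "train").sum() == 112
        assert (df["split"] == "test").sum() == 48

    def test_stratification_preserves_quartile_fractions(self):
        df = split_train_test(self._cohort(), train_n=112, seed=2)
        q = pd.qcut(df["age"], 4, labels=False)
        for quartile in range(4):
            sub = df[q == quartile]
            frac = (sub["split"] == "train").mean()
            assert abs(frac - 0.7) < 0.06  # within +/-1 sample per stratum

    def test_deterministic(self):
        a = split_train_test(self._cohort(), train_n=112, seed=3)
        b = split_train_test(self._cohort(), train_n=112, seed=3)
        assert (a["split"] == b["split"]).all()

    def test_train_n_too_large(self):
        with pytest.raises(ValueError):
            split_train_test(self._cohort(n=50), train_n=50)


class TestPowerTransform:
    def test_linear_data_chooses_identity(self, rng):
        meth = rng.uniform(10, 90, 200)
        age = 2.0 * meth + rng.normal(0, 0.5, 200)
        spec = fit_power_transform(meth, age)
        assert spec.form == "identity"

    def test_power_data_matches_grid_oracle(self, rng):
        meth = rng.uniform(5, 60, 300)
        age = 0.05 * meth**1.8 + rng.normal(0, 0.3, 300)
        grid = np.round(np.arange(0.5, 3.01, 0.1), 10)
        spec = fit_power_transform(meth, age, grid)
        # independent exhaustive search over the same grid
        r2 = [np.corrcoef(meth**k, age)[0, 1] ** 2 for k in grid]
        oracle = grid[int(np.argmax(r2))]
        assert spec.form == "power"
        assert abs(spec.exponent - oracle) <= 0.1 + 1e-9

    def test_rank_order_preserved(self, rng):
        meth = rng.uniform(1, 99, 50)
        spec = TransformSpec(cpg="X", form="power", exponent=1.7)
        assert (np.argsort(spec.apply(meth)) == np.argsort(meth)).all()

    def test_nonpositive_methylation_rejected(self, rng):
        meth = np.concatenate([[0.0], rng.uniform(1, 99, 20)])
        age = np.arange(21, dtype=float)
        with pytest.raises(ValueError, match="onpositive"):
            fit_power_transform(meth, age)


class TestUnivariateScreen:
    def test_perfect_positive_and_negative(self):
        meth = pd.DataFrame({"A_C1": np.arange(1.0, 21.0), "B_C1": np.arange(1.0, 21.0)})
        age_pos = 2.0 * meth["A_C1"].to_numpy()
        res = univariate_screen(age_pos, meth)
        assert res.loc["A_C1", "std_beta"] == pytest.approx(1.0)
        assert res.loc["A_C1", "r_squared"] == pytest.approx(1.0)
        res_neg = univariate_screen(-2.0 * meth["A_C1"].to_numpy(), meth)
        assert res_neg.loc["A_C1", "std_beta"] == pytest.approx(-1.0)

    def test_std_beta_equals_pearson_r(self, rng):
        meth = pd.DataFrame(rng.uniform(0, 100, size=(80, 5)),
                            columns=[f"M{i}_C1" for i in range(5)])
        age = rng.uniform(1, 90, 80)
        res = univariate_screen(age, meth)
        for cpg in meth.columns:
            r = np.corrcoef(meth[cpg], age)[0, 1]
            assert res.loc[cpg, "std_beta"] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_flagged(self):
        meth = pd.DataFrame({"A_C1": np.full(20, 50.0), "B_C1": np.arange(20.0)})
        res = univariate_screen(np.arange(20.0), meth)
        assert bool(res.loc["A_C1", "excluded"])
        assert not bool(res.loc["B_C1", "excluded"])


def _best_subset_adj_r2(age, meth, max_size=None):
    """Exhaustive best-subset oracle on adjusted R^2 (numpy lstsq)."""
    cols = list(meth.columns)
    n = len(age)
    best = 0.0  # empty model
    y = np.asarray(age, float)
    for k in range(1, (max_size or len(cols)) + 1):
        for subset in itertools.combinations(cols, k):
            x = np.column_stack([np.ones(n)] + [meth[c].to_numpy() for c in subset])
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
            adj = 1 - (1 - r2) * (n - 1) / (n - k - 1)
            best = max(best, adj)
    return best


class TestStepwise:
    def test_recovers_informative_subset(self, rng):
        age, meth = _synthetic_training(rng, n=200, noise=1.0)
        res = stepwise_select(age, meth)
        assert {"M0_C1", "M1_C1"} <= set(res.predictors)

    def test_adjusted_r2_bounded_by_best_subset(self, rng):
        for _ in range(3):
            age, meth = _synthetic_training(rng, n=60, n_cpgs=6, noise=8.0)
            res = stepwise_select(age, meth)
            oracle = _best_subset_adj_r2(age, meth)
            assert res.adjusted_r2 <= oracle + 1e-9

    def test_type_one_error_rate_tracks_p_enter(self):
        # a single null candidate should enter at about the p_enter rate
        hits = 0
        n_trials = 400
        for s in range(n_trials):
            rng = np.random.default_rng(1000 + s)
            meth = pd.DataFrame({"X_C1": rng.uniform(0, 100, 100)})
            age = rng.uniform(1, 90, 100)
            res = stepwise_select(age, meth, config=StepwiseConfig(p_enter=0.05, p_remove=0.10))
            hits += not res.is_empty
        rate = hits / n_trials
        # binomial 99% CI around 0.05 with 400 trials
        assert 0.022 <= rate <= 0.081

    def test_empty_model_signal(self):
        rng = np.random.default_rng(42)
        meth = pd.DataFrame({"X_C1": rng.uniform(0, 100, 100)})
        age = rng.uniform(1, 90, 100)
        res = stepwise_select(age, meth, config=StepwiseConfig(p_enter=1e-12, p_remove=1e-12))
        assert res.is_empty
        assert res.intercept == pytest.approx(np.mean(age))

    def test_deterministic(self, rng):
        age, meth = _synthetic_training(rng, n=150)
        a = stepwise_select(age, meth)
        b = stepwise_select(age, meth)
        assert a.predictors == b.predictors
        assert a.coefficients == b.coefficients

    def test_p_enter_must_not_exceed_p_remove(self):
        with pytest.raises(ValueError):
            StepwiseConfig(p_enter=0.2, p_remove=0.1)


class TestFitModel:
    def test_noiseless_single_predictor_exact(self):
        meth = pd.DataFrame({"A_C1": np.linspace(5, 95, 30)})
        age = 4.0 + 0.7 * meth["A_C1"].to_numpy()
        res = fit_model(age, meth, ["A_C1"])
        assert res.intercept == pytest.approx(4.0)
        assert res.coefficients["A_C1"] == pytest.approx(0.7)
        assert res.adjusted_r2 == pytest.approx(1.0)

    def test_adjusted_r2_formula(self, rng):
        age, meth = _synthetic_training(rng, n=50, n_cpgs=3, noise=20.0)
        res = fit_model(age, meth, list(meth.columns))
        n, p = 50, 3
        assert res.adjusted_r2 == pytest.approx(1 - (1 - res.r2) * (n - 1) / (n - p - 1))

    def test_two_predictor_recovery_within_ci(self):
        rng = np.random.default_rng(7)
        age, meth = _synthetic_training(rng, n=500, n_cpgs=2, noise=1.0)
        res = fit_model(age, meth, ["M0_C1", "M1_C1"])
        for cpg, truth in zip(["M0_C1", "M1_C1"], [0.5, -0.3]):
            lo = res.coefficients[cpg] - 1.96 * res.std_errors[cpg]
            hi = res.coefficients[cpg] + 1.96 * res.std_errors[cpg]
            assert lo <= truth <= hi

    def test_collinear_predictors_named(self, rng):
        a = rng.uniform(0, 100, 50)
        meth = pd.DataFrame({"A_C1": a, "B_C1": 2 * a + 1})
        with pytest.raises(ValueError, match="A_C1 and B_C1"):
            fit_model(np.arange(50.0), meth, ["A_C1", "B_C1"])

    def test_standardized_beta_matches_direct_formula(self, rng):
        age, meth = _synthetic_training(rng, n=120, n_cpgs=3, noise=5.0)
        res = fit_model(age, meth, list(meth.columns))
        sy = np.std(age, ddof=1)
        for cpg in meth.columns:
            expected = res.coefficients[cpg] * np.std(meth[cpg], ddof=1) / sy
            assert res.std_beta[cpg] == pytest.approx(expected)

    def test_prediction_invariant_to_predictor_rescaling(self, rng):
        age, meth = _synthetic_training(rng, n=100, n_cpgs=2, noise=2.0)
        res1 = fit_model(age, meth, list(meth.columns))
        scaled = meth.copy()
        scaled["M0_C1"] = scaled["M0_C1"] * 10 + 5
        res2 = fit_model(age, scaled, list(meth.columns))
        p1 = res1.predict(meth)["predicted_age"]
        p2 = res2.predict(scaled)["predicted_age"]
        assert np.allclose(p1, p2)


class TestPredict:
    def _model(self):
        return AgeRegressionResults(
            tissue="blood", predictors=["A_C1"],
            transforms={"A_C1": TransformSpec(cpg="A_C1")},
            intercept=0.0, coefficients={"A_C1": 2.0}, std_errors={"A_C1": 0.0},
            t_values={"A_C1": 0.0}, p_values={"A_C1": 0.0}, std_beta={"A_C1": 1.0},
            adjusted_r2=1.0, r2=1.0, training_n=10,
        )

    def test_affine_prediction(self):
        pred = self._model().predict(pd.DataFrame({"A_C1": [20.0]}, index=["S1"]))
        assert pred.loc["S1", "predicted_age"] == pytest.approx(40.0)

    def test_training_data_mae_zero_noiseless(self):
        meth = pd.DataFrame({"A_C1": np.linspace(10, 40, 20)})
        age = 2.0 * meth["A_C1"].to_numpy()
        res = fit_model(age, meth, ["A_C1"])
        pred = res.predict(meth)["predicted_age"].to_numpy()
        assert np.abs(pred - age).max() < 1e-8

    def test_depth_failure_gives_no_prediction(self):
        meth = pd.DataFrame({"A_C1": [20.0, 30.0]}, index=["S1", "S2"])
        passing = pd.DataFrame({"A_C1": [True, False]}, index=["S1", "S2"])
        pred = self._model().predict(meth, passing)
        assert pred.loc["S1", "predicted_age"] == pytest.approx(40.0)
        assert np.isnan(pred.loc["S2", "predicted_age"])
        assert "depth" in pred.loc["S2", "note"]

    def test_missing_predictor_raises(self):
        with pytest.raises(ValueError, match="A_C1"):
            self._model().predict(pd.DataFrame({"B_C1": [1.0]}))

    def test_json_roundtrip(self, tmp_path, rng):
        age, meth = _synthetic_training(rng, n=100, n_cpgs=3)
        res = fit_model(age, meth, list(meth.columns),
                        transforms={"M0_C1": TransformSpec(cpg="M0_C1", form="power", exponent=1.5)})
        path = tmp_path / "model.json"
        res.to_json(path)
        back = AgeRegressionResults.from_json(path)
        assert back.predictors == res.predictors
        assert back.coefficients == pytest.approx(res.coefficients)
        assert back.transforms["M0_C1"].exponent == 1.5
        pred_a = res.predict(meth)["predicted_age"]
        pred_b = back.predict(meth)["predicted_age"]
        assert np.allclose(pred_a, pred_b)


class TestEvaluate:
    def test_simple_mae(self):
        rep = evaluate_predictions(np.array([11.0, 33.0]), np.array([10.0, 30.0]))
        assert rep.mae_overall == pytest.approx(2.0)

    def test_age_45_in_category_3(self):
        truth = np.array([45.0, 45.0])
        rep = evaluate_predictions(truth + 1, truth)
        assert rep.n_by_category[3] == 2
        assert rep.mae_by_category[3] == pytest.approx(1.0)

    def test_empty_category_reported_none(self):
        truth = np.array([45.0, 50.0])
        rep = evaluate_predictions(truth + 1, truth)
        assert rep.mae_by_category[1] is None and rep.n_by_category[1] == 0

    def test_weighted_category_maes_average_to_overall(self, rng):
        truth = rng.uniform(1, 90, 200)
        pred = truth + rng.normal(0, 5, 200)
        rep = evaluate_predictions(pred, truth)
        total = sum(rep.mae_by_category[k] * rep.n_by_category[k]
                    for k in rep.mae_by_category if rep.mae_by_category[k] is not None)
        assert total / rep.n == pytest.approx(rep.mae_overall)

    def test_error_proportional_to_age_gives_r_one(self):
        truth = np.linspace(10, 80, 30)
        pred = truth + 0.1 * truth
        rep = evaluate_predictions(pred, truth)
        assert rep.pearson_r_abs_error_vs_age == pytest.approx(1.0)
        assert rep.pearson_p < 1e-20

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_predictions(np.array([1.0]), np.array([1.0, 2.0]))


class TestAssayEquivalence:
    def test_identity_not_rejected(self, rng):
        a = rng.uniform(0, 100, 20)
        out = assay_equivalence({"M": a}, {"M": a.copy()})
        assert out.loc["M", "slope"] == pytest.approx(1.0)
        assert out.loc["M", "intercept"] == pytest.approx(0.0, abs=1e-8)
        assert out.loc["M", "p_value"] == pytest.approx(1.0)

    def test_constant_shift_rejected(self):
        a = np.array([0.0, 5, 10, 25, 50, 75, 100])
        out = assay_equivalence({"M": a}, {"M": a + 2.4})
        assert out.loc["M", "slope"] == pytest.approx(1.0)
        assert out.loc["M", "intercept"] == pytest.approx(2.4)
        assert out.loc["M", "p_bonferroni"] < 0.05

    def test_bonferroni_capped_at_one(self, rng):
        a = rng.uniform(0, 100, 10)
        b = a + rng.normal(0, 5, 10)
        out = assay_equivalence({"M": a}, {"M": b}, n_tests=5)
        p = out.loc["M", "p_value"]
        assert out.loc["M", "p_bonferroni"] == pytest.approx(min(1.0, 5 * p))

    def test_noisy_but_equivalent_assays_not_rejected(self):
        rng = np.random.default_rng(5)
        a = np.tile([0.0, 5, 10, 25, 50, 75, 100], 3)
        b = a + rng.normal(0, 2, a.size)
        out = assay_equivalence({"M": a}, {"M": b})
        assert out.loc["M", "p_bonferroni"] > 0.05

    def test_degenerate_variance(self):
        with pytest.raises(ValueError, match="degenerate"):
            assay_equivalence({"M": np.full(5, 50.0)}, {"M": np.arange(5.0)})

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 paired"):
            assay_equivalence({"M": np.array([1.0, 2.0])}, {"M": np.array([1.0, 2.0])})


def test_summary_lists_predictors(rng):
    age, meth = _synthetic_training(rng, n=100, n_cpgs=3)
    res = fit_model(age, meth, list(meth.columns), tissue="blood")
    text = res.summary()
    assert "blood" in text
    for cpg in meth.columns:
        assert cpg in text
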