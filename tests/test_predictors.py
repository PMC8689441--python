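import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from taustage.predictors import (
    StepRecord,
    aic,
    backward_stepwise,
    encode_sex,
    fit_single_predictor,
    select_within_two,
    zscore_biomarkers,
)


class TestAic:
    def test_reference_points(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-10.0, 3) == aic(-10.0, 2) + 2.0

    def test_matches_hand_computed_gaussian_ols_aic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 1.0 + 0.5 * x + rng.normal(scale=0.7, size=30)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        n = len(y)
        sigma2 = np.sum(res.resid**2) / n  # MLE variance
        loglik = -n / 2 * (np.log(2 * np.pi * sigma2) + 1)
        # params: intercept, slope, residual variance
        assert aic(res.llf, 3) == pytest.approx(-2 * loglik + 6, rel=1e-10)


class TestZscore:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(1)
        n = 60
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["Ab- CU"] * 30 + ["Ab+ CU"] * 30,
            "plasma_ptau217": rng.normal(1.3, 0.5, n),
            "hippocampal_volume": rng.normal(3800, 400, n),
        })

    def test_reference_mean_maps_to_zero(self, cohort):
        # probe a non-reference subject so the reference moments stay fixed
        ref = cohort[cohort["group"] == "Ab- CU"]["plasma_ptau217"]
        probe = cohort.copy()
        probe.loc[30, "plasma_ptau217"] = ref.mean()
        z = zscore_biomarkers(probe, ["plasma_ptau217"])
        assert z.iloc[30, 0] == pytest.approx(0.0, abs=1e-12)

    def test_two_sd_above_reference_is_two(self, cohort):
        ref = cohort[cohort["group"] == "Ab- CU"]["plasma_ptau217"]
        probe = cohort.copy()
        probe.loc[30, "plasma_ptau217"] = ref.mean() + 2 * ref.std(ddof=1)
        z = zscore_biomarkers(probe, ["plasma_ptau217"])
        assert z.iloc[30, 0] == pytest.approx(2.0, rel=1e-9)

    def test_volume_sign_is_flipped(self, cohort):
        ref = cohort[cohort["group"] == "Ab- CU"]["hippocampal_volume"]
        probe = cohort.copy()
        probe.loc[30, "hippocampal_volume"] = ref.mean() - 2 * ref.std(ddof=1)
        z = zscore_biomarkers(probe, ["hippocampal_volume"])
        assert z.iloc[30, 0] == pytest.approx(2.0, rel=1e-9)

    def test_zero_reference_variance_named(self, cohort):
        bad = cohort.copy()
        bad.loc[bad["group"] == "Ab- CU", "plasma_ptau217"] = 1.0
        with pytest.raises(ValueError, match="plasma_ptau217"):
            zscore_biomarkers(bad, ["plasma_ptau217"])


def synthetic_regression_data(n=60, beta=0.5, n_null=6, seed=0):
    """One active z-scored predictor plus pure-noise companions."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = beta * x + np.sqrt(1 - beta**2) * rng.standard_normal(n)
    data = {"annual_change": y, "active": x}
    for j in range(n_null):
        data[f"noise{j}"] = rng.standard_normal(n)
    data["age"] = rng.normal(72, 7, n)
    data["sex_male"] = rng.integers(0, 2, n).astype(float)
    return pd.DataFrame(data)


class TestFitSinglePredictor:
    def test_generative_recovery(self):
        coefs, daics = [], []
        for seed in range(10):
            d = synthetic_regression_data(seed=seed)
            c = fit_single_predictor(d, "annual_change", "active", n_boot=100, seed=seed)
            coefs.append(c.coefficient)
            daics.append(c.delta_aic)
        assert np.mean(coefs) == pytest.approx(0.5, abs=0.1)
        assert np.mean(daics) < 0
        assert all(c < 0 for c in daics[:3]) or np.mean(daics) < -5

    def test_null_predictor_raises_aic(self):
        daics = []
        for seed in range(20):
            d = synthetic_regression_data(n=500, beta=0.0, seed=100 + seed)
            c = fit_single_predictor(d, "annual_change", "active", n_boot=50, seed=seed)
            daics.append(c.delta_aic)
        assert np.mean(daics) > 0  # +2 penalty minus chi2(1) noise

    def test_standardized_coefficient_affine_invariant(self):
        d = synthetic_regression_data(seed=3)
        c1 = fit_single_predictor(d, "annual_change", "active", n_boot=50, seed=0)
        d2 = d.copy()
        d2["active"] = 100.0 * d2["active"] + 55.0
        c2 = fit_single_predictor(d2, "annual_change", "active", n_boot=50, seed=0)
        assert c1.coefficient == pytest.approx(c2.coefficient, rel=1e-9)

    def test_constant_predictor_rejected(self):
        d = synthetic_regression_data(seed=4)
        d["active"] = 1.0
        with pytest.raises(ValueError):
            fit_single_predictor(d, "annual_change", "active", n_boot=10)

    def test_adj_r2_ci_brackets_estimate(self):
        d = synthetic_regression_data(n=200, seed=5)
        c = fit_single_predictor(d, "annual_change", "active", n_boot=500, seed=5)
        lo, hi = c.adj_r2_ci
        assert lo <= c.adjusted_r2 <= hi


TABLE3_PREDICTORS = (
    "plasma_ab42_40", "amyloid_pet", "plasma_ptau217", "tau_pet",
    "plasma_nfl", "hippocampal_volume", "ad_cortex",
)


def _published_path(removals, aics):
    """Rebuild a backward-elimination path from a removal order and its AICs."""
    current = list(TABLE3_PREDICTORS)
    steps = [StepRecord(tuple(current), np.nan, aics[0], None)]
    for removed, a in zip(removals, aics[1:]):
        current = [p for p in current if p != removed]
        steps.append(StepRecord(tuple(current), np.nan, a, removed))
    return steps


class TestSelectionRule:
    def test_published_mci_path(self):
        steps = _published_path(
            ["ad_cortex", "hippocampal_volume", "plasma_nfl", "amyloid_pet",
             "plasma_ab42_40", "tau_pet"],
            [120, 118, 116, 115, 113, 111, 114],
        )
        selected, sel_aic = select_within_two(steps)
        assert set(selected) == {"plasma_ptau217", "tau_pet"}
        assert sel_aic == 111

    def test_published_cu_path(self):
        steps = _published_path(
            ["plasma_nfl", "hippocampal_volume", "ad_cortex", "amyloid_pet",
             "plasma_ab42_40", "tau_pet"],
            [108, 106, 104, 102, 101, 100, 103],
        )
        selected, sel_aic = select_within_two(steps)
        assert set(selected) == {"plasma_ptau217", "tau_pet"}
        assert sel_aic == 100

    def test_within_two_is_inclusive(self):
        steps = [
            StepRecord(("a", "b"), np.nan, 100.0, None),
            StepRecord(("a",), np.nan, 102.0, "b"),
        ]
        selected, _ = select_within_two(steps)
        assert selected == ("a",)


class TestBackwardStepwise:
    def test_each_step_is_minimal_removal(self):
        d = synthetic_regression_data(seed=7)
        preds = ["active"] + [f"noise{j}" for j in range(6)]
        path = backward_stepwise(d, "annual_change", preds)
        dd = d[["annual_change", *preds, "age", "sex_male"]].dropna()
        y = dd["annual_change"].to_numpy()

        def ols_aic(cols):
            X = sm.add_constant(dd[list(cols) + ["age", "sex_male"]].to_numpy())
            res = sm.OLS(y, X).fit()
            return aic(res.llf, len(res.params) + 1)

        for prev, step in zip(path.steps, path.steps[1:]):
            candidates = [ols_aic([p for p in prev.predictors if p != c])
                          for c in prev.predictors]
            assert step.aic == pytest.approx(min(candidates), rel=1e-9)

    def test_path_minimum_not_below_exhaustive_best_subset(self):
        d = synthetic_regression_data(seed=8)
        preds = ["active"] + [f"noise{j}" for j in range(4)]
        path = backward_stepwise(d, "annual_change", preds)
        dd = d[["annual_change", *preds, "age", "sex_male"]].dropna()
        y = dd["annual_change"].to_numpy()
        best = np.inf
        for r in range(1, len(preds) + 1):
            for combo in itertools.combinations(preds, r):
                X = sm.add_constant(dd[list(combo) + ["age", "sex_male"]].to_numpy())
                res = sm.OLS(y, X).fit()
                best = min(best, aic(res.llf, len(res.params) + 1))
        assert min(s.aic for s in path.steps) >= best - 1e-9

    def test_empty_predictor_set_rejected(self):
        d = synthetic_regression_data(seed=9)
        with pytest.raises(ValueError):
            backward_stepwise(d, "annual_change", [])


def test_encode_sex_binary_indicator():
    df = pd.DataFrame({"sex": ["F", "M", "m", "female"]})
    out = encode_sex(df)
    assert list(out["sex_male"]) == [0.0, 1.0, 1.0, 0.0]
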