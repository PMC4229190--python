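"""Risk-model machinery: splits, logistic fits, AUC vs pair counting,
stepwise selection, dichotomization, score construction, calibration."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from artrisk.riskmodel import (
    DEFAULT_THRESHOLDS,
    RiskScoreSpec,
    SeparationError,
    apply_risk_score,
    assign_risk_groups,
    build_risk_score,
    compute_auc,
    dichotomize_by_decile_risk,
    fit_logistic,
    forward_stepwise_aic,
    hosmer_lemeshow,
    screen_measures,
    split_sample,
)

from _oracles import pair_count_auc

RNG = np.random.default_rng(20260925)


class TestSplitSample:
    def test_sizes_differ_by_at_most_one(self):
        df = pd.DataFrame({"x": range(923)})
        d, v = split_sample(df, seed=1)
        assert sorted([len(d), len(v)]) == [461, 462]

    def test_disjoint_exhaustive_and_seeded(self):
        df = pd.DataFrame({"x": range(101)})
        d1, v1 = split_sample(df, seed=7)
        d2, v2 = split_sample(df, seed=7)
        assert set(d1.index).isdisjoint(v1.index)
        assert set(d1.index) | set(v1.index) == set(df.index)
        assert list(d1.index) == list(d2.index)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_sample(pd.DataFrame({"x": [1]}), seed=0)


class TestFitLogistic:
    def test_intercept_only_recovers_prevalence(self):
        df = pd.DataFrame({"y": [0] * 70 + [1] * 30})
        m = fit_logistic(df, "y", [])
        assert m.fitted.mean() == pytest.approx(0.3, abs=1e-6)

    def test_null_covariate_coefficient_near_zero(self):
        n = 10000
        df = pd.DataFrame(
            {"x": RNG.normal(size=n), "y": RNG.random(n) < 0.3}
        )
        df["y"] = df["y"].astype(int)
        m = fit_logistic(df, "y", ["x"])
        assert abs(float(m.coefficients["x"])) < 0.1

    def test_categorical_gets_missing_category(self):
        n = 400
        df = pd.DataFrame(
            {
                "g": RNG.choice(["a", "b", None], n),
                "y": (RNG.random(n) < 0.4).astype(int),
            }
        )
        m = fit_logistic(df, "y", ["g"])
        assert any("missing" in c for c in m.design_columns)

    def test_perfect_separation_diagnosed(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(30), np.ones(30)],
                           "y": np.r_[np.zeros(30), np.ones(30)].astype(int)})
        with pytest.raises(SeparationError):
            fit_logistic(df, "y", ["x"])

    def test_planted_or_confidence_coverage(self):
        """Wald CIs on a correctly specified model cover the planted OR."""
        hits = 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            n = 3000
            x = rng.random(n) < 0.4
            p = special.expit(-1.5 + math.log(2.0) * x)
            y = (rng.random(n) < p).astype(int)
            df = pd.DataFrame({"x": x, "y": y})
            m = fit_logistic(df, "y", ["x"])
            import statsmodels.api as sm

            X = sm.add_constant(df[["x"]].astype(float))
            ci = sm.Logit(df["y"], X).fit(disp=0).conf_int().loc["x"]
            if ci[0] <= math.log(2.0) <= ci[1]:
                hits += 1
        assert hits / reps >= 0.85


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert compute_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_interleaved_hand_case(self):
        assert compute_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == 0.75

    def test_random_scores_near_half(self):
        n = 10000
        res = compute_auc(RNG.normal(size=n), RNG.random(n) < 0.3)
        assert res.auc == pytest.approx(0.5, abs=0.02)
        assert res.ci_lo <= res.auc <= res.ci_hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([1.0, 2.0], [1, 1])

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=9), min_size=2, max_size=50),
        st.data(),
    )
    def test_equals_exhaustive_pair_counting(self, scores, data):
        labels = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=1),
                min_size=len(scores),
                max_size=len(scores),
            )
        )
        if len(set(labels)) < 2:
            return
        assert compute_auc(scores, labels).auc == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12
        )


class TestStepwise:
    def _simulate(self, rng, n=4000, betas=None):
        betas = betas or {}
        df = pd.DataFrame(
            {
                "pdc": rng.random(n),
                "male": rng.random(n) < 0.4,
                "cd4": rng.random(n) < 0.3,
                "pre_art": rng.random(n) < 0.4,
                "noise": rng.random(n) < 0.5,
            }
        )
        lin = -1.6 + sum(
            b * df[k].astype(float) for k, b in betas.items()
        )
        df["y"] = (rng.random(n) < special.expit(lin)).astype(int)
        return df

    def test_no_improving_candidate_returns_forced_only(self):
        rng = np.random.default_rng(5)
        df = self._simulate(rng, n=2000, betas={})
        model, selected = forward_stepwise_aic(df, "y", ["pdc"], ["noise"])
        base = fit_logistic(df, "y", ["pdc"])
        assert model.aic <= base.aic
        if selected:  # a null candidate enters only by improving AIC
            assert model.aic < base.aic

    def test_planted_effects_selected(self):
        rng = np.random.default_rng(6)
        df = self._simulate(
            rng,
            betas={"male": math.log(2), "cd4": math.log(2.6), "pre_art": math.log(2.4)},
        )
        _, selected = forward_stepwise_aic(
            df, "y", ["pdc"], ["male", "cd4", "pre_art"]
        )
        assert set(selected) == {"male", "cd4", "pre_art"}

    def test_superset_with_noise_candidate(self):
        rng = np.random.default_rng(7)
        df = self._simulate(rng, betas={"male": math.log(2.2), "cd4": math.log(2.2)})
        _, selected = forward_stepwise_aic(
            df, "y", ["pdc"], ["male", "cd4", "noise"]
        )
        assert {"male", "cd4"} <= set(selected)


class TestDichotomize:
    def test_planted_step_recovered(self):
        rng = np.random.default_rng(8)
        n = 4000
        x = rng.random(n)
        p = np.where(x < 0.8, 0.32, 0.10)
        df = pd.DataFrame({"x": x, "y": (rng.random(n) < p).astype(int)})
        dt = dichotomize_by_decile_risk(df, "y", "x")
        assert dt.threshold == pytest.approx(0.8, abs=0.05)
        assert dt.jump < 0

    def test_flat_risk_still_returns_boundary(self):
        rng = np.random.default_rng(9)
        n = 3000
        df = pd.DataFrame(
            {"x": rng.random(n), "y": (rng.random(n) < 0.2).astype(int)}
        )
        dt = dichotomize_by_decile_risk(df, "y", "x")
        assert np.isfinite(dt.threshold)
        assert abs(dt.jump) < 0.08

    def test_few_distinct_values_fall_back(self):
        df = pd.DataFrame({"x": [0, 1, 2] * 50, "y": [0, 0, 1] * 50})
        dt = dichotomize_by_decile_risk(df, "y", "x")
        assert dt.fallback_distinct


class TestRiskScore:
    def test_weights_from_printed_simple_model_ors(self):
        coefs = pd.Series(
            {
                "low_pdc": math.log(2.16),
                "high_cd4": math.log(2.60),
                "short_pre_art": math.log(2.43),
                "male": math.log(1.87),
            }
        )
        model = _binary_model(coefs)
        spec = build_risk_score(model)
        assert spec.weights == {
            "low_pdc": 7.7, "high_cd4": 9.6, "short_pre_art": 8.9, "male": 6.3
        }
        assert spec.max_score == pytest.approx(32.5)

    def test_zero_coefficients_zero_weights(self):
        spec = build_risk_score(_binary_model(pd.Series({"a": 0.0, "b": 0.0})))
        assert set(spec.weights.values()) == {0.0}

    def test_non_binary_design_rejected(self):
        m = _binary_model(pd.Series({"x": 1.0}))
        m.binary_design = False
        with pytest.raises(ValueError):
            build_risk_score(m)

    def test_apply_score_all_factors(self):
        spec = _paper_spec()
        row = {"pdc": 0.70, "baseline_cd4": 300.0, "pre_art_days": 100, "male": True}
        assert apply_risk_score(spec, row) == pytest.approx(32.5)

    def test_apply_score_no_factors(self):
        spec = _paper_spec()
        row = {"pdc": 0.95, "baseline_cd4": 150.0, "pre_art_days": 400, "male": False}
        assert apply_risk_score(spec, row) == 0.0

    def test_apply_score_male_only(self):
        spec = _paper_spec()
        row = {"pdc": 0.95, "baseline_cd4": 150.0, "pre_art_days": 400, "male": True}
        assert apply_risk_score(spec, row) == pytest.approx(6.3)

    def test_missing_inputs_count_as_absent(self):
        spec = _paper_spec()
        row = {"pdc": np.nan, "baseline_cd4": np.nan, "pre_art_days": np.nan,
               "male": True}
        assert apply_risk_score(spec, row) == pytest.approx(6.3)

    def test_score_preserves_linear_predictor_ranking(self):
        rng = np.random.default_rng(10)
        n = 2000
        df = pd.DataFrame(
            {
                "low_pdc": rng.random(n) < 0.4,
                "high_cd4": rng.random(n) < 0.3,
                "short_pre_art": rng.random(n) < 0.4,
                "male": rng.random(n) < 0.4,
            }
        )
        lin = (
            0.77 * df["low_pdc"] + 0.96 * df["high_cd4"]
            + 0.89 * df["short_pre_art"] + 0.63 * df["male"]
        )
        df["y"] = (rng.random(n) < special.expit(-1.6 + lin)).astype(int)
        model = fit_logistic(df, "y", list(df.columns[:-1]))
        spec = build_risk_score(model)
        scores = df.iloc[:, :4].astype(float).to_numpy() @ np.array(
            [spec.weights[c] for c in df.columns[:4]]
        )
        fitted_lin = df.iloc[:, :4].astype(float).to_numpy() @ np.array(
            [model.coefficients[c] for c in df.columns[:4]]
        )
        rho = stats.spearmanr(scores, fitted_lin).statistic
        assert rho > 0.999


class TestRiskGroups:
    def test_uniform_scores_give_balanced_tertiles(self):
        scores = pd.Series(np.arange(300, dtype=float))
        groups, cuts = assign_risk_groups(scores, scores)
        counts = groups.value_counts()
        assert all(abs(c - 100) <= 1 for c in counts)

    def test_ties_go_to_lower_group_and_monotone(self):
        rng = np.random.default_rng(11)
        scores = pd.Series(rng.choice([0, 6.3, 8.9, 16.6, 24.2, 32.5], 500))
        groups, cuts = assign_risk_groups(scores, scores)
        order = {"low": 0, "medium": 1, "high": 2}
        g = groups.map(order)
        for a, b in ((0, 1), (1, 2)):
            lo_max = scores[g == a].max()
            hi_min = scores[g == b].min()
            assert lo_max < hi_min or math.isnan(hi_min)

    def test_degenerate_distribution_warns(self):
        scores = pd.Series([5.0] * 40)
        with pytest.warns(UserWarning):
            groups, _ = assign_risk_groups(scores, scores)
        assert set(groups) == {"low"}

    def test_validation_uses_derivation_cuts(self):
        deriv = pd.Series([0.0, 10.0, 20.0, 30.0])
        val = pd.Series([5.0, 15.0, 25.0])
        groups, cuts = assign_risk_groups(val, deriv)
        assert list(groups) == ["low", "medium", "high"]


class TestHosmerLemeshow:
    def test_observed_equals_expected_gives_zero(self):
        p = np.full(100, 0.5)
        y = np.tile([0, 1], 50)
        res = hosmer_lemeshow(p, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_groups_partition_all_subjects(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.05, 0.95, 537)
        y = (rng.random(537) < p).astype(int)
        res = hosmer_lemeshow(p, y)
        assert res.table["n"].sum() == 537

    def test_gross_miscalibration_detected(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.05, 0.3, 2000)
        y = (rng.random(2000) < p + 0.3).astype(int)
        assert hosmer_lemeshow(p, y).p_value < 1e-6


class TestScreening:
    def test_signal_only_through_pdc_selects_pdc(self):
        rng = np.random.default_rng(14)
        n = 3000
        df = pd.DataFrame(
            {
                "mpr": rng.random(n),
                "pdc": rng.random(n),
                "tvr": rng.random(n),
                "vas_mean": rng.random(n),
                "pct_no_md": rng.random(n),
            }
        )
        df["failed"] = (
            rng.random(n) < special.expit(-2.0 + 2.5 * (df["pdc"] < 0.5))
        ).astype(int)
        tab = screen_measures(df)
        assert tab.loc[tab["winner"], "measure"].iloc[0] == "pdc"
        assert (tab["n"] <= n).all()

    def test_all_noise_flags_nonsignificant_winner(self):
        rng = np.random.default_rng(15)
        n = 1500
        df = pd.DataFrame({m: rng.random(n) for m in
                           ("mpr", "pdc", "tvr", "vas_mean", "pct_no_md")})
        df["failed"] = (rng.random(n) < 0.2).astype(int)
        tab = screen_measures(df)
        assert not tab.loc[tab["winner"], "significant"].iloc[0]

    def test_no_leakage_between_halves(self):
        """A fixed scoring rule shows no derivation/validation AUC gap on
        null data (the split itself leaks nothing)."""
        gaps = []
        for r in range(60):
            rng = np.random.default_rng(300 + r)
            n = 600
            df = pd.DataFrame(
                {"s": rng.normal(size=n), "y": (rng.random(n) < 0.3).astype(int)}
            )
            d, v = split_sample(df, seed=r)
            if d["y"].nunique() < 2 or v["y"].nunique() < 2:
                continue
            auc_d = compute_auc(d["s"], d["y"]).auc
            auc_v = compute_auc(v["s"], v["y"]).auc
            gaps.append(auc_d - auc_v)
        assert abs(float(np.mean(gaps))) < 0.02


def _binary_model(coefs: pd.Series):
    from artrisk.riskmodel import FittedModel

    params = pd.concat([pd.Series({"const": -2.0}), coefs])
    return FittedModel(
        covariates=list(coefs.index),
        design_columns=list(coefs.index),
        params=params,
        aic=0.0,
        n=0,
        fitted=np.array([]),
        binary_design=True,
        llf=0.0,
    )


def _paper_spec() -> RiskScoreSpec:
    return RiskScoreSpec(
        weights={"low_pdc": 7.7, "high_cd4": 9.6, "short_pre_art": 8.9, "male": 6.3},
        thresholds=dict(DEFAULT_THRESHOLDS),
    )
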