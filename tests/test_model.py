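"""Logistic MLE, best-subsets search and epsilon-stratified refits."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from apoescore.genotypes import UndefinedStatisticError, ValidationError
from apoescore.model import (
    DesignSpec,
    Predictor,
    best_subsets,
    build_features,
    cohort_logistic_fit,
    logistic_fit,
    stratified_fits,
)
from apoescore.simulate import default_config, simulate_cohort

# a fixed two-predictor dataset (n=40): x1 binary, x2 numeric
TOY_X1 = np.array([0, 1] * 20, dtype=float)
TOY_X2 = np.array([(i % 7) - 3 for i in range(40)], dtype=float)
TOY_Y = np.array([0, 0, 0, 1, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 1,
                  0, 1, 0, 1, 1, 1, 0, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 1, 0, 1],
                 dtype=float)


def _toy_features():
    return pd.DataFrame({"case": TOY_Y, "x1": TOY_X1, "x2": TOY_X2})


def _neg_loglik(beta, X, y):
    eta = X @ beta
    return float(np.sum(np.log1p(np.exp(eta))) - y @ eta)


class TestLogisticFit:
    def test_single_binary_predictor_closed_form(self, study_cohort):
        feats = build_features(study_cohort)
        fit = logistic_fit(feats, "case", [Predictor("e4_carrier", "binary")])
        tab = pd.crosstab(feats["case"], feats["e4_carrier"]).to_numpy()
        # saturated 2x2: slope = ln OR, intercept = ln odds among non-carriers
        ln_or = np.log(tab[1, 1] * tab[0, 0] / (tab[1, 0] * tab[0, 1]))
        assert fit.coefficients["e4_carrier"] == pytest.approx(ln_or, abs=1e-6)
        assert fit.coefficients["intercept"] == \
            pytest.approx(np.log(tab[1, 0] / tab[0, 0]), abs=1e-6)
        assert fit.or_per_term["e4_carrier"] == \
            pytest.approx(np.exp(ln_or), rel=1e-6)

    def test_intercept_only_is_logit_case_fraction(self, study_cohort):
        feats = build_features(study_cohort)
        fit = logistic_fit(feats, "case", [])
        frac = feats["case"].mean()
        assert fit.coefficients["intercept"] == \
            pytest.approx(np.log(frac / (1 - frac)), abs=1e-8)
        assert fit.loglik == pytest.approx(fit.loglik_null, abs=1e-8)

    def test_toy_fixture_matches_independent_optimizer(self):
        fit = logistic_fit(_toy_features(), "case",
                           [Predictor("x1"), Predictor("x2")])
        X = np.column_stack([np.ones(40), TOY_X1, TOY_X2])
        res = optimize.minimize(_neg_loglik, np.zeros(3), args=(X, TOY_Y),
                                method="BFGS", options={"gtol": 1e-10})
        got = np.array([fit.coefficients["intercept"],
                        fit.coefficients["x1"], fit.coefficients["x2"]])
        assert np.allclose(got, res.x, atol=1e-4)
        # local optimality at 1e-4 resolution on each axis
        base = _neg_loglik(got, X, TOY_Y)
        for k in range(3):
            for delta in (-1e-4, 1e-4):
                trial = got.copy()
                trial[k] += delta
                assert _neg_loglik(trial, X, TOY_Y) >= base - 1e-10

    def test_or_equals_exp_coefficient(self, study_cohort):
        fit = cohort_logistic_fit(
            study_cohort, DesignSpec(predictors=[Predictor("score")]))
        for term, beta in fit.coefficients.items():
            assert fit.or_per_term[term] == pytest.approx(np.exp(beta))
            lo, hi = fit.ci_per_term[term]
            assert lo <= fit.or_per_term[term] <= hi

    def test_affine_recoding_transforms_or_exactly(self, study_cohort):
        feats = build_features(study_cohort)
        feats["half_score"] = feats["score"] / 2.0
        f1 = logistic_fit(feats, "case", [Predictor("score")])
        f2 = logistic_fit(feats, "case", [Predictor("half_score")])
        assert f2.coefficients["half_score"] == \
            pytest.approx(2 * f1.coefficients["score"], rel=1e-6)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-8)

    def test_column_order_irrelevant(self, study_cohort):
        feats = build_features(study_cohort)
        f1 = logistic_fit(feats, "case", [Predictor("score"),
                                          Predictor("male")])
        f2 = logistic_fit(feats, "case", [Predictor("male"),
                                          Predictor("score")])
        assert f1.coefficients["score"] == pytest.approx(
            f2.coefficients["score"], abs=1e-9)

    def test_permuted_outcome_near_null(self, big_cohort, rng):
        feats = build_features(big_cohort)
        feats["case"] = rng.permutation(feats["case"].to_numpy())
        fit = logistic_fit(feats, "case",
                           [Predictor("e4_carrier"), Predictor("score")])
        for term in ("e4_carrier", "score"):
            assert abs(fit.coefficients[term]) < 0.12  # ~3 SE at n=10 000

    @pytest.mark.parametrize("n", [500, 5_000, 50_000])
    def test_parameter_recovery_from_known_model(self, n, rng):
        x1 = rng.binomial(1, 0.3, n).astype(float)
        x2 = rng.normal(0, 1, n)
        eta = -0.4 + 0.8 * x1 - 0.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        feats = pd.DataFrame({"case": y, "x1": x1, "x2": x2})
        fit = logistic_fit(feats, "case", [Predictor("x1"), Predictor("x2")])
        tol = 12.0 / np.sqrt(n)
        assert fit.coefficients["x1"] == pytest.approx(0.8, abs=tol)
        assert fit.coefficients["x2"] == pytest.approx(-0.5, abs=tol)

    def test_separation_flagged_not_silent(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        feats = pd.DataFrame({"case": x, "x": x})
        fit = logistic_fit(feats, "case", [Predictor("x")])
        assert fit.separation_flagged

    def test_singular_design_names_terms(self, study_cohort):
        feats = build_features(study_cohort)
        feats["score_copy"] = feats["score"]
        with pytest.raises(ValidationError, match="score"):
            logistic_fit(feats, "case",
                         [Predictor("score"), Predictor("score_copy")])

    def test_too_few_rows_rejected(self):
        feats = pd.DataFrame({"case": [0.0, 1.0], "x": [0.0, 1.0]})
        with pytest.raises(UndefinedStatisticError):
            logistic_fit(feats, "case", [Predictor("x")])


class TestBestSubsets:
    def test_single_candidate_two_models(self, study_cohort):
        feats = build_features(study_cohort)
        search = best_subsets(feats, [Predictor("score")])
        assert len(search.ranking) == 2

    def test_nine_candidates_512_models(self, study_cohort):
        feats = build_features(study_cohort)
        for i in range(6):
            feats[f"extra{i}"] = feats["age"] * 0 + float(i == 0)
        cands = [Predictor(n) for n in
                 ("score", "male", "education", "e4_carrier", "apoe_level",
                  "large_city", "age", "rs449647_dosage", "rs440446_dosage")]
        search = best_subsets(feats, cands)
        assert len(search.ranking) == 512

    def test_budget_guard(self, study_cohort):
        feats = build_features(study_cohort)
        cands = [Predictor(f"c{i}") for i in range(21)]
        with pytest.raises(ValidationError):
            best_subsets(feats, cands)

    def test_nesting_monotonicity_of_loglik(self, study_cohort):
        feats = build_features(study_cohort)
        search = best_subsets(feats, [Predictor("score"), Predictor("male"),
                                      Predictor("e4_carrier")])
        by_terms = {frozenset(t): f for t, f in search.ranking}
        for terms, fit in search.ranking:
            for sub in by_terms:
                if sub < frozenset(terms):
                    assert fit.loglik >= by_terms[sub].loglik - 1e-6


def _synthesize_outcome(cohort, beta, rng):
    """Replace the group label by a draw from a known logistic model."""
    feats = build_features(cohort)
    eta = np.full(len(feats), beta.get("intercept", 0.0))
    for name, b in beta.items():
        if name != "intercept":
            eta = eta + b * feats[name].to_numpy()
    y = rng.random(len(feats)) < 1 / (1 + np.exp(-eta))
    data = cohort.data.copy()
    data["group"] = np.where(y, "case", "control")
    data.loc[data["group"] == "control", "age_at_onset"] = np.nan
    from apoescore.genotypes import Cohort
    return Cohort(data, list(cohort.panel))


class TestRecovery:
    def test_best_subsets_recovers_true_predictors(self):
        """True effects on E4 carriership and the score only: the selected
        subset contains both and no noise term in >=90 % of replicates."""
        hits = 0
        n_rep = 50
        rng = np.random.default_rng(424242)
        for rep in range(n_rep):
            cohort = simulate_cohort(default_config(n_case=2000,
                                                    n_control=2000,
                                                    seed=5000 + rep))
            cohort = _synthesize_outcome(
                cohort, {"intercept": 0.0, "e4_carrier": 0.9, "score": -0.5},
                rng)
            feats = build_features(cohort)
            feats["noise1"] = rng.normal(0, 1, len(feats))
            feats["noise2"] = rng.binomial(1, 0.4, len(feats)).astype(float)
            search = best_subsets(
                feats,
                [Predictor("e4_carrier", "binary"), Predictor("score"),
                 Predictor("noise1"), Predictor("noise2")],
                criterion="bic")
            best = set(search.best_terms)
            hits += best == {"e4_carrier", "score"}
        assert hits >= 0.9 * n_rep


class TestStratifiedFits:
    def test_e3e3_stratum_size(self, study_cohort):
        fits = stratified_fits(study_cohort,
                               DesignSpec(predictors=[Predictor("score")]))
        eps = study_cohort.epsilon_genotypes().map(str)
        n_e3e3 = int((eps == "E3/E3").sum())
        assert fits["E3_E3_only"] is not None
        assert fits["E3_E3_only"].n_used == n_e3e3

    def test_stratum_without_controls_skipped(self, study_cohort):
        fits = stratified_fits(
            study_cohort, DesignSpec(predictors=[Predictor("score")]),
            strata={"cases_only": lambda c: c.data["group"] == "case"})
        assert fits["cases_only"] is None

    def test_score_protective_within_e4_carriers(self):
        """With a protective score effect built in, the E4-carrier stratum
        recovers OR < 1 for the score in >=80 % of replicates."""
        hits = 0
        n_rep = 50
        rng = np.random.default_rng(77)
        design = DesignSpec(predictors=[Predictor("score")])
        for rep in range(n_rep):
            cohort = simulate_cohort(default_config(n_case=2000,
                                                    n_control=2000,
                                                    seed=9000 + rep))
            cohort = _synthesize_outcome(
                cohort, {"intercept": 0.2, "e4_carrier": 0.9, "score": -0.4},
                rng)
            fits = stratified_fits(cohort, design,
                                   strata={"E4_carriers_only":
                                           lambda c: c.epsilon_carrier("E4")})
            fit = fits["E4_carriers_only"]
            if fit is not None and fit.or_per_term["score"] < 1:
                hits += 1
        assert hits >= 0.8 * n_rep
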