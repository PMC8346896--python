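"""Membership odds ratios, profile probabilities, and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest

import trajmix as tm
from trajmix.membership import (contrast, implied_odds_ratio, membership_effects,
                                pool_imputations, profile_probabilities)


def test_zero_coefficient_gives_unit_odds_ratio(covfit2000):
    eff = membership_effects(covfit2000)
    # construct: OR = exp(coef) for every row
    assert np.allclose(eff.table["odds_ratio"],
                       np.exp(eff.table["coef"]), atol=1e-12)
    assert ((eff.table["p_value"] >= 0) & (eff.table["p_value"] <= 1)).all()


def test_cohort_odds_ratio_recovery(covfit2000):
    """Generative medium-vs-low cohort OR is 2.972; recovery within [2.2, 4.0]."""
    eff = membership_effects(covfit2000)
    assert 2.2 < eff.odds_ratio(1, "cohort_older") < 4.0


def test_covariate_effect_signs_recovered(covfit2000):
    eff = membership_effects(covfit2000)
    for term, sign in [("cohort_older", 1), ("male", 1), ("tanf", 1),
                       ("self_control", -1)]:
        for g in (1, 2):
            assert np.sign(eff.table.loc[(g, term), "coef"]) == sign, (g, term)


def test_membership_effects_requires_covariates_and_se(fit1000):
    with pytest.raises(ValueError, match="no membership covariates"):
        membership_effects(fit1000)


def test_profile_probabilities_rows_sum_to_one(covfit2000):
    pp = profile_probabilities(covfit2000, [{"cohort_older": 0.0},
                                            {"cohort_older": 1.0},
                                            {"tanf": 1.0}])
    assert np.allclose(pp.probs.sum(axis=1), 1.0, atol=1e-12)
    pp_means = profile_probabilities(covfit2000, [{"tanf": 0.0}], at_means=True)
    assert np.allclose(pp_means.probs.sum(axis=1), 1.0, atol=1e-12)


def test_profile_probabilities_intercept_only(fit1000):
    pp = profile_probabilities(fit1000, [{}, {}])
    pi = fit1000.group_shares()
    assert np.allclose(pp.probs.to_numpy(), pi, atol=1e-12)


def test_unknown_profile_covariate_raises(covfit2000):
    with pytest.raises(KeyError, match="unknown covariate"):
        profile_probabilities(covfit2000, [{"zodiac": 1.0}])


def test_cohort_contrast_recovery(study_spec, covfit2000):
    """Low-group cohort contrast recovered within 0.05 of the generative value."""
    pp = profile_probabilities(covfit2000, [{"cohort_older": 0.0},
                                            {"cohort_older": 1.0}])
    got = contrast(pp.row(0), pp.row(1), 0)
    true = (tm.implied_membership(study_spec, "younger")[0]
            - tm.implied_membership(study_spec, "older")[0])
    assert got == pytest.approx(true, abs=0.05)
    assert got > 0  # younger cohorts more likely to be in the low group


def test_contrast_basics():
    assert contrast({"low": 0.881}, {"low": 0.721}, "low") == pytest.approx(0.160)
    assert contrast([0.5, 0.5], [0.5, 0.5], 0) == 0.0
    with pytest.raises(ValueError, match="mismatched"):
        contrast({"low": 0.5}, {"high": 0.5}, "low")


def test_implied_odds_ratio():
    # symmetric populations imply OR 1; doubling the odds doubles the OR
    assert implied_odds_ratio(0.2, 0.8, 0.2, 0.8) == pytest.approx(1.0)
    assert implied_odds_ratio(0.4, 0.8, 0.2, 0.8) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        implied_odds_ratio(0.0, 0.5, 0.2, 0.8)


def test_odds_ratio_invariant_to_recentering(study_spec):
    """Shifting a covariate moves intercepts, not slopes: ORs unchanged."""
    panel, cov, _ = tm.simulate_panel(study_spec, 600, seed=31)
    shifted = tm.CovariateTable(cov.data.assign(self_control=cov.data["self_control"] + 5.0))
    f1 = tm.GroupTrajectoryModel(panel, 3, covariates=cov).fit(
        n_starts=2, seed=3, compute_se=True)
    f2 = tm.GroupTrajectoryModel(panel, 3, covariates=shifted).fit(
        n_starts=2, seed=3, compute_se=True)
    e1, e2 = membership_effects(f1), membership_effects(f2)
    for g in (1, 2):
        assert e1.odds_ratio(g, "self_control") == pytest.approx(
            e2.odds_ratio(g, "self_control"), rel=5e-3)


def test_pool_single_imputation():
    out = pool_imputations([[1.5]], [[0.25]])
    assert out["estimate"].iloc[0] == 1.5
    assert out["total_variance"].iloc[0] == pytest.approx(0.25)
    assert np.isinf(out["df"].iloc[0])


def test_pool_identical_estimates():
    est = [[2.0, -1.0]] * 10
    var = [[0.1, 0.2]] * 10
    out = pool_imputations(est, var)
    assert np.allclose(out["between"], 0.0)
    assert np.allclose(out["total_variance"], [0.1, 0.2])


def test_pool_rubin_hand_example():
    """m=3, estimates (1,2,3), within variances 1: pooled 2, total 1 + (4/3)*1."""
    out = pool_imputations([[1.0], [2.0], [3.0]], [[1.0], [1.0], [1.0]])
    assert out["estimate"].iloc[0] == pytest.approx(2.0)
    assert out["total_variance"].iloc[0] == pytest.approx(1.0 + (1 + 1 / 3) * 1.0)
    assert out["total_variance"].iloc[0] >= out["within"].iloc[0]


def test_pool_name_mismatch_raises():
    a = pd.DataFrame({"x": [1.0]})
    b = pd.DataFrame({"y": [1.0]})
    with pytest.raises(ValueError, match="inconsistent|shapes"):
        pool_imputations(a, b)


def test_pooled_fit_workflow(study_spec):
    """Pooling theta across per-imputation fits: total variance >= mean within."""
    panel, cov, _ = tm.simulate_panel(study_spec, 400, seed=41)
    frames = []
    for m in range(2):
        d = cov.data.copy()
        d["imputation_id"] = m
        if m:  # perturb one covariate as a stand-in for imputation noise
            d["self_control"] = d["self_control"] + 0.1 * np.random.default_rng(m).standard_normal(len(d))
        frames.append(d)
    multi = tm.CovariateTable(pd.concat(frames, ignore_index=True))
    ests, vars_ = [], []
    for m in range(2):
        r = tm.GroupTrajectoryModel(panel, 3, covariates=multi, imputation_id=m).fit(
            n_starts=2, seed=5, compute_se=True)
        theta_names = [n for n in r.model.param_names if n.startswith("theta")]
        ests.append(r.params[theta_names])
        vars_.append(r.bse[theta_names] ** 2)
    pooled = pool_imputations(pd.DataFrame(ests).reset_index(drop=True),
                              pd.DataFrame(vars_).reset_index(drop=True))
    assert (pooled["total_variance"] >= pooled["within"] - 1e-12).all()
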