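"""Mixture likelihood, posterior, and fitting against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trajmix as tm
from trajmix.basis import TrajectorySpec
from trajmix.model import GroupTrajectoryModel, MixtureModel


def brute_force_loglik(mix, panel, covariates=None):
    """Direct per-person enumeration of the mixture likelihood (the oracle).

    Works in probability space on purpose: it shares no code with the
    log-space implementation it checks.
    """
    total = 0.0
    cov = covariates.for_imputation(0) if covariates is not None else None
    for pid, grp in panel.data.groupby("person_id"):
        if cov is not None:
            x = cov.loc[pid, list(mix.covariate_names)].to_numpy(dtype=float)
            pi = mix.membership_probabilities(x[None, :])[0]
        else:
            pi = mix.membership_probabilities()[0]
        person = 0.0
        for j in range(mix.n_groups):
            lik = 1.0
            for _, row in grp.iterrows():
                lam = mix.rate(j, int(row["age"]))
                lik *= stats.poisson.pmf(int(row["count"]), lam)
            person += pi[j] * lik
        total += np.log(person)
    return total


def two_group_mixture(b_low=-1.0, b_high=0.7, pi_high=0.3, degree=1, slope=0.2):
    tspec = TrajectorySpec(degree=degree)
    beta = (np.array([b_low] + [0.0] * degree),
            np.array([b_high] + [slope] * degree))
    theta = np.array([[np.log(pi_high / (1 - pi_high))]])
    return MixtureModel(specs=(tspec, tspec), beta=beta, theta=theta)


@pytest.fixture
def toy_panel():
    """3 persons x 4 periods with varied counts."""
    rows = []
    counts = {"A": [0, 1, 0, 2], "B": [3, 2, 4, 1], "C": [0, 0, 1, 0]}
    for pid, cs in counts.items():
        for age, c in zip(range(17, 21), cs):
            rows.append({"person_id": pid, "age": age, "count": c})
    return tm.Panel(pd.DataFrame(rows))


def test_loglik_matches_brute_force_oracle(toy_panel):
    mix = two_group_mixture()
    ours = tm.log_likelihood(mix, toy_panel)
    oracle = brute_force_loglik(mix, toy_panel)
    assert ours == pytest.approx(oracle, abs=1e-10)


def test_loglik_single_zero_observation():
    """One person, one period, y=0, lambda=1: loglik is exactly -1."""
    panel = tm.Panel(pd.DataFrame({"person_id": ["A"], "age": [20], "count": [0]}))
    mix = MixtureModel(specs=(TrajectorySpec(degree=0),), beta=(np.zeros(1),),
                       theta=np.zeros((0, 1)))
    assert tm.log_likelihood(mix, panel) == pytest.approx(-1.0, abs=1e-12)


def test_identical_components_collapse_to_single_group(toy_panel):
    tspec = TrajectorySpec(degree=2)
    beta = np.array([0.3, -0.1, 0.05])
    single = MixtureModel(specs=(tspec,), beta=(beta,), theta=np.zeros((0, 1)))
    double = MixtureModel(specs=(tspec, tspec), beta=(beta, beta),
                          theta=np.array([[0.7]]))
    assert tm.log_likelihood(double, toy_panel) == pytest.approx(
        tm.log_likelihood(single, toy_panel), abs=1e-10)
    # and the posterior rows equal the prior
    post = tm.posterior_probabilities(double, toy_panel).to_numpy()
    pi = double.membership_probabilities()[0]
    assert np.allclose(post, pi, atol=1e-12)


def test_posterior_concentrates_on_high_group():
    """20 arrests over 8 periods vs rates 0.01 / 5.0: direct Bayes says ~group 1."""
    rows = [{"person_id": "A", "age": a, "count": c}
            for a, c in zip(range(17, 25), [3, 2, 3, 2, 3, 2, 3, 2])]
    panel = tm.Panel(pd.DataFrame(rows))
    tspec = TrajectorySpec(degree=0)
    mix = MixtureModel(specs=(tspec, tspec),
                       beta=(np.array([np.log(0.01)]), np.array([np.log(5.0)])),
                       theta=np.array([[0.0]]))
    post = tm.posterior_probabilities(mix, panel).to_numpy()[0]
    # independent computation of the Bayes ratio
    lo = stats.poisson.logpmf([3, 2] * 4, 0.01).sum()
    hi = stats.poisson.logpmf([3, 2] * 4, 5.0).sum()
    expected_hi = 1.0 / (1.0 + np.exp(lo - hi))
    assert post[1] == pytest.approx(expected_hi, abs=1e-12)
    assert post[1] > 0.999999


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_posterior_rows_normalized(seed, toy_panel):
    rng = np.random.default_rng(seed)
    tspec = TrajectorySpec(degree=2)
    J = 3
    mix = MixtureModel(specs=(tspec,) * J,
                       beta=tuple(rng.normal(0, 0.5, 3) for _ in range(J)),
                       theta=rng.normal(0, 1, (J - 1, 1)))
    post = tm.posterior_probabilities(mix, toy_panel).to_numpy()
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)


def test_constant_rate_curve():
    mix = MixtureModel(specs=(TrajectorySpec(degree=3),),
                       beta=(np.array([np.log(2.0), 0, 0, 0]),),
                       theta=np.zeros((0, 1)))
    ages = np.arange(10, 34)
    assert np.allclose(mix.rate(0, ages), 2.0, atol=1e-12)
    with pytest.raises(IndexError):
        mix.rate(1, 19)


def test_relabeling_invariance(toy_panel):
    mix = two_group_mixture()
    flipped = mix.permute([1, 0])
    assert tm.log_likelihood(flipped, toy_panel) == pytest.approx(
        tm.log_likelihood(mix, toy_panel), abs=1e-10)
    pi = mix.membership_probabilities()[0]
    assert np.allclose(flipped.membership_probabilities()[0], pi[::-1], atol=1e-12)


def test_fit_output_in_ascending_rate_order(fit1000):
    ages = np.arange(10, 34)
    means = [np.mean(fit1000.mixture.rate(j, ages)) for j in range(3)]
    assert means == sorted(means)


def test_j1_fit_matches_glm_oracle(sim1000):
    """J=1 reduces to a Poisson log-linear model; compare with statsmodels IRLS."""
    sm = pytest.importorskip("statsmodels.api")
    panel, _, _ = sim1000
    res = tm.fit(panel, J=1, n_starts=1, seed=0)
    model = GroupTrajectoryModel(panel, 1)
    glm = sm.GLM(model._y, model._designs[0], family=sm.families.Poisson()).fit(tol=1e-12)
    assert np.max(np.abs(glm.params - res.mixture.beta[0])) < 1e-6
    assert res.loglik == pytest.approx(glm.llf, abs=1e-6)


def test_em_loglik_monotone(sim1000):
    panel, _, _ = sim1000
    res = tm.fit(panel, J=2, n_starts=1, seed=4, polish=False, em_tol=1e-10)
    path = np.asarray(res.em_loglik_path)
    assert len(path) > 5
    assert np.all(np.diff(path) >= -1e-7 * (np.abs(path[:-1]) + 1))


def test_best_of_starts_contract(sim1000):
    panel, _, _ = sim1000
    multi = tm.fit(panel, J=2, n_starts=3, seed=4)
    single = tm.fit(panel, J=2, n_starts=1, seed=4)
    assert multi.loglik >= single.loglik - 1e-8


def test_zero_coefficient_covariates_match_unconditioned(toy_panel):
    cov = tm.CovariateTable(pd.DataFrame({
        "person_id": ["A", "B", "C"], "x": [0.2, -1.0, 0.5]}))
    base = two_group_mixture()
    with_cov = MixtureModel(specs=base.specs, beta=base.beta,
                            theta=np.column_stack([base.theta, [0.0]]),
                            covariate_names=("x",))
    assert tm.log_likelihood(with_cov, toy_panel, cov) == pytest.approx(
        tm.log_likelihood(base, toy_panel), abs=1e-12)
    post_c = tm.posterior_probabilities(with_cov, toy_panel, cov).to_numpy()
    post_u = tm.posterior_probabilities(base, toy_panel).to_numpy()
    assert np.allclose(post_c, post_u, atol=1e-12)


def test_all_zero_panel_is_handled():
    df = pd.DataFrame({"person_id": np.repeat([f"p{i}" for i in range(5)], 4),
                       "age": list(range(17, 21)) * 5, "count": 0})
    res = tm.fit(tm.Panel(df), J=1, n_starts=1, seed=0)
    assert np.isfinite(res.loglik)
    assert res.mixture.rate(0, 18) < 1e-6


def test_parameter_recovery(study_spec, fit1000):
    shares = fit1000.group_shares()
    implied = tm.implied_group_shares(study_spec)
    assert np.all(np.abs(shares - implied) < 0.03)
    for j, target in enumerate([0.02, 0.35, 1.44]):
        assert fit1000.mixture.rate(j, 19) == pytest.approx(target, rel=0.10, abs=0.01)


def test_fit_preconditions(tiny_panel):
    with pytest.raises(ValueError, match="at least J persons"):
        GroupTrajectoryModel(tiny_panel, 5).fit(n_starts=1)
    with pytest.raises(ValueError, match=">= 1"):
        GroupTrajectoryModel(tiny_panel, 0)


def test_missing_covariate_person_raises(toy_panel):
    cov = tm.CovariateTable(pd.DataFrame({"person_id": ["A", "B"], "x": [0.0, 1.0]}))
    with pytest.raises(tm.PanelValidationError, match="missing covariates"):
        GroupTrajectoryModel(toy_panel, 2, covariates=cov)


def test_spline_basis_fit(sim1000):
    panel, _, _ = sim1000
    spec = TrajectorySpec(kind="spline", knots=(15.0, 19.0, 25.0))
    res = tm.fit(panel, spec=spec, J=2, n_starts=1, seed=0)
    assert np.isfinite(res.loglik)
    assert res.mixture.rate(1, 19) > res.mixture.rate(0, 19)
    with pytest.raises(ValueError, match="strictly in"):
        TrajectorySpec(kind="spline", knots=(5.0,)).validate_for_range(10, 33)


def test_standard_errors_finite(covfit2000):
    se = covfit2000.bse
    assert np.isfinite(se).all()
    assert (se > 0).all()


def test_summary_renders(fit1000):
    text = fit1000.summary()
    assert "loglik" in text and "pi_hat" in text
    assert f"{fit1000.n_params}" in text
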