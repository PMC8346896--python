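"""Covariate-conditioned membership analysis.

Once group membership is modeled as a multinomial logit in baseline
covariates, three questions follow: how strongly does each covariate shift
the odds of belonging to a higher-rate group (odds ratios with Wald
tests), what membership probabilities does the model predict at chosen
covariate profiles (e.g. younger vs older cohort, TANF vs not, ±1 SD of
self-control), and how do estimates pool across multiply imputed
covariate datasets (Rubin's rules).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import GroupTrajectoryResults

__all__ = ["MembershipEffects", "ProfileProbabilities", "membership_effects",
           "profile_probabilities", "contrast", "pool_imputations",
           "implied_odds_ratio"]


@dataclass
class MembershipEffects:
    """Membership-logit estimates vs the reference (lowest-rate) group.

    ``table`` has one row per (group, term): coefficient, standard error,
    odds ratio exp(coef), Wald z and two-sided p-value.
    """

    table: pd.DataFrame
    reference_group: int = 0

    def odds_ratio(self, group: int, term: str) -> float:
        return float(self.table.loc[(group, term), "odds_ratio"])

    def __repr__(self) -> str:
        return f"MembershipEffects (reference group {self.reference_group}):\n{self.table.round(4)}"


def membership_effects(fit: GroupTrajectoryResults) -> MembershipEffects:
    """Odds ratios of group membership per covariate, against the low group.

    Requires a fit with membership covariates and standard errors
    (``compute_se=True``).  The odds ratio for a zero coefficient is
    exactly 1; Wald p-values use the normal approximation.
    """
    mix = fit.mixture
    if not mix.covariate_names:
        raise ValueError("fit has no membership covariates")
    if fit.se is None:
        raise ValueError("standard errors unavailable; refit with compute_se=True")
    if not (fit.assignments == 0).any():
        raise ValueError("reference group has no assigned members")

    terms = ("const",) + mix.covariate_names
    rows = []
    for j in range(1, mix.n_groups):
        for k, term in enumerate(terms):
            coef = float(mix.theta[j - 1, k])
            se = float(fit.se[f"theta[{j}][{term}]"])
            z = coef / se if se > 0 else np.nan
            rows.append({
                "group": j, "term": term, "coef": coef, "se": se,
                "odds_ratio": float(np.exp(coef)), "z": z,
                "p_value": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            })
    table = pd.DataFrame(rows).set_index(["group", "term"])
    return MembershipEffects(table=table)


@dataclass
class ProfileProbabilities:
    """Predicted membership probabilities at covariate profiles.

    ``probs`` is (profiles × groups); rows sum to one.  ``profiles``
    records the covariate overrides that defined each row.
    """

    probs: pd.DataFrame
    profiles: tuple = ()

    def row(self, i: int = 0) -> pd.Series:
        return self.probs.iloc[i]

    def __repr__(self) -> str:
        return f"ProfileProbabilities:\n{self.probs.round(4)}"


def profile_probabilities(fit: GroupTrajectoryResults, profiles,
                          at_means: bool = False) -> ProfileProbabilities:
    """Membership probabilities at each covariate profile.

    By default uses the average-predicted-probability convention: the
    focal covariates are overridden for every person in the estimation
    sample and the softmax probabilities are averaged, so unset covariates
    keep their observed joint distribution.  With ``at_means=True`` the
    unset covariates are fixed at their sample means instead
    (representative-profile convention).
    """
    mix = fit.mixture
    if not mix.covariate_names:
        # intercept-only model: every profile returns pi-hat
        pi = mix.membership_probabilities()[0]
        probs = pd.DataFrame([pi] * max(len(profiles), 1),
                             columns=range(mix.n_groups))
        return ProfileProbabilities(probs=probs, profiles=tuple(map(dict, profiles)))

    names = list(mix.covariate_names)
    base = fit.model._Xm[:, 1:]
    if at_means:
        base = base.mean(axis=0, keepdims=True)
    rows = []
    for prof in profiles:
        unknown = [k for k in prof if k not in names]
        if unknown:
            raise KeyError(f"unknown covariate(s) in profile: {unknown}")
        X = base.copy()
        for k, v in prof.items():
            X[:, names.index(k)] = float(v)
        rows.append(mix.membership_probabilities(X).mean(axis=0))
    probs = pd.DataFrame(rows, columns=range(mix.n_groups))
    return ProfileProbabilities(probs=probs, profiles=tuple(map(dict, profiles)))


def _as_prob_series(p, row: int = 0) -> pd.Series:
    if isinstance(p, ProfileProbabilities):
        return p.row(row)
    if isinstance(p, pd.Series):
        return p
    if isinstance(p, Mapping):
        return pd.Series(p)
    arr = np.asarray(p, dtype=float)
    return pd.Series(arr, index=range(len(arr)))


def contrast(prob_a, prob_b, group) -> float:
    """Difference prob_a - prob_b in the named group's membership probability.

    Accepts :class:`ProfileProbabilities` (first row), mappings, Series, or
    plain per-group probability vectors; the two sides must cover the same
    groups.
    """
    a, b = _as_prob_series(prob_a), _as_prob_series(prob_b)
    if set(a.index) != set(b.index):
        raise ValueError(f"mismatched group sets: {list(a.index)} vs {list(b.index)}")
    if group not in a.index:
        raise KeyError(f"group {group!r} not present")
    return float(a[group] - b[group])


def implied_odds_ratio(p_group_a: float, p_ref_a: float,
                       p_group_b: float, p_ref_b: float) -> float:
    """Odds ratio implied by two membership-probability pairs.

    (p_group_a / p_ref_a) / (p_group_b / p_ref_b): the relative odds of the
    group versus the reference group in population A versus population B.
    """
    for v in (p_group_a, p_ref_a, p_group_b, p_ref_b):
        if v <= 0:
            raise ValueError("probabilities must be positive")
    return (p_group_a / p_ref_a) / (p_group_b / p_ref_b)


def pool_imputations(estimates, variances) -> pd.DataFrame:
    """Combine per-imputation estimates by Rubin's rules.

    Parameters
    ----------
    estimates, variances : (m, k) arrays or DataFrames
        Point estimates and their squared standard errors from m fits on m
        imputed datasets, with aligned parameter columns.

    Returns
    -------
    DataFrame with columns estimate, within, between, total_variance, se,
    df, p_value.  Pooled estimate is the mean; total variance is the mean
    within-imputation variance plus (1 + 1/m) times the between-imputation
    variance; degrees of freedom and the two-sided p-value follow Rubin.
    """
    est = pd.DataFrame(estimates)
    var = pd.DataFrame(variances)
    if est.shape != var.shape:
        raise ValueError("estimates and variances have different shapes")
    if list(est.columns) != list(var.columns):
        raise ValueError("inconsistent parameter names across estimates and variances")
    m = len(est)
    if m < 1:
        raise ValueError("need at least one imputation")
    qbar = est.mean(axis=0)
    within = var.mean(axis=0)
    between = est.var(axis=0, ddof=1) if m > 1 else pd.Series(0.0, index=est.columns)
    total = within + (1.0 + 1.0 / m) * between
    se = np.sqrt(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * between / within
        df = (m - 1) * (1.0 + 1.0 / r) ** 2
    df = df.where((m > 1) & (between > 0), np.inf)
    t = qbar / se
    p = pd.Series(
        [2 * (stats.t.sf(abs(ti), dfi) if np.isfinite(dfi) else stats.norm.sf(abs(ti)))
         if np.isfinite(ti) else np.nan
         for ti, dfi in zip(t, df)],
        index=est.columns,
    )
    return pd.DataFrame({"estimate": qbar, "within": within, "between": between,
                         "total_variance": total, "se": se, "df": df, "p_value": p})
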