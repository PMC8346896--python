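"""Finite mixture of Poisson age-trajectories (group-based trajectory model).

The population distribution of longitudinal count sequences is modeled as a
finite mixture over J latent groups.  For person i with counts y_it at ages
a_it over the observation window,

    P(Y_i | Age_i) = sum_j  pi_j(x_i) * prod_t Poisson(y_it; lambda_j(a_it))

where lambda_j(a) = exp(beta_j . basis(a)) is group j's expected count at
age a and pi_j(x) follows a multinomial logit in an intercept plus optional
baseline covariates x (group 0 is the reference, theta_0 = 0).  Counts are
conditionally independent across ages given group membership.

Estimation is maximum likelihood via EM — the E-step computes posterior
group probabilities, the M-step solves posterior-weighted Poisson
regressions for each beta_j and a weighted multinomial-logit update for
theta — followed by a quasi-Newton (L-BFGS) polish of the full mixture
likelihood.  Multiple seeded starts guard against local maxima; fitted
groups are relabeled in ascending order of mean rate over the observed age
grid so that index 0 is always the lowest-rate ("low") group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .basis import TrajectorySpec
from .panel import CovariateTable, Panel

__all__ = [
    "MixtureModel",
    "GroupTrajectoryModel",
    "GroupTrajectoryResults",
    "fit",
    "rate",
    "log_likelihood",
    "posterior_probabilities",
]

_ETA_MAX = 30.0        # cap on the log rate: exp(30) ~ 1e13 counts/year
_RATE_FLOOR = 1e-10    # floor inside the Poisson log-pmf (all-zero groups)


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureModel:
    """Parameters of a J-group Poisson trajectory mixture.

    ``beta`` holds one coefficient vector per group over that group's age
    basis; ``theta`` holds the membership-logit coefficients of groups
    1..J-1 against reference group 0, over an intercept plus
    ``covariate_names`` (empty for the unconditioned model).
    """

    specs: tuple
    beta: tuple
    theta: np.ndarray
    covariate_names: tuple = ()
    age_range: tuple = (10.0, 33.0)

    def __post_init__(self):
        object.__setattr__(self, "beta", tuple(np.asarray(b, dtype=float) for b in self.beta))
        th = np.atleast_2d(np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "theta", th)
        if len(self.specs) != len(self.beta):
            raise ValueError("one TrajectorySpec per group required")
        if th.shape != (self.n_groups - 1, 1 + len(self.covariate_names)):
            raise ValueError(
                f"theta shape {th.shape} inconsistent with J={self.n_groups}, "
                f"covariates {self.covariate_names}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.beta)

    @property
    def n_params(self) -> int:
        return int(sum(len(b) for b in self.beta) + self.theta.size)

    def rate(self, group: int, age) -> np.ndarray | float:
        """Expected count lambda_group(age) = exp(beta . basis(age))."""
        if not 0 <= group < self.n_groups:
            raise IndexError(f"group {group} out of range for J={self.n_groups}")
        D = self.specs[group].design(age, age_range=self.age_range)
        out = np.exp(np.minimum(D @ self.beta[group], _ETA_MAX))
        return float(out[0]) if np.ndim(age) == 0 else out

    def membership_logits(self, covariates: np.ndarray | None = None) -> np.ndarray:
        """(n, J) logits with the reference group pinned at zero."""
        q = 1 + len(self.covariate_names)
        if covariates is None:
            X = np.ones((1, 1))
            if q != 1:
                raise ValueError("model has membership covariates; values required")
        else:
            covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
            X = np.column_stack([np.ones(len(covariates)), covariates])
            if X.shape[1] != q:
                raise ValueError(f"expected {q - 1} covariates, got {X.shape[1] - 1}")
        L = X @ self.theta.T
        return np.column_stack([np.zeros(len(L)), L])

    def membership_probabilities(self, covariates: np.ndarray | None = None) -> np.ndarray:
        """pi_j(x): softmax of the membership logits; rows sum to one."""
        L = self.membership_logits(covariates)
        P = np.exp(L - logsumexp(L, axis=1, keepdims=True))
        return P

    def permute(self, order) -> "MixtureModel":
        """Relabel groups; logits are re-expressed against the new reference."""
        order = list(order)
        if sorted(order) != list(range(self.n_groups)):
            raise ValueError("order must be a permutation of the groups")
        logits = np.vstack([np.zeros((1, self.theta.shape[1])), self.theta])
        newlog = logits[order] - logits[order[0]]
        return replace(
            self,
            specs=tuple(self.specs[j] for j in order),
            beta=tuple(self.beta[j] for j in order),
            theta=newlog[1:],
        )

    def mean_rates(self, ages) -> np.ndarray:
        """Mean lambda_j over an age grid; used for canonical group order."""
        return np.array([float(np.mean(self.rate(j, np.asarray(ages)))) for j in range(self.n_groups)])


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class GroupTrajectoryModel:
    """Poisson trajectory-mixture model bound to a panel.

    Parameters
    ----------
    panel : Panel
    n_groups : int
        Number of latent trajectory groups J (>= 1).
    trajectory_spec : TrajectorySpec or sequence of TrajectorySpec
        Shared basis, or one per group.
    covariates : CovariateTable, optional
        Baseline covariates entering the membership logit.  Must cover
        every person in the panel.
    covariate_names : sequence of str, optional
        Subset/order of covariate columns to use (default: all).
    imputation_id : int
        Which imputation of the covariate table to bind.
    """

    def __init__(self, panel: Panel, n_groups: int,
                 trajectory_spec: TrajectorySpec | list | tuple = TrajectorySpec(),
                 covariates: CovariateTable | None = None,
                 covariate_names=None, imputation_id: int = 0):
        if n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if panel.n_persons == 0:
            raise ValueError("panel is empty")
        self.panel = panel
        self.n_groups = int(n_groups)
        if isinstance(trajectory_spec, TrajectorySpec):
            specs = (trajectory_spec,) * n_groups
        else:
            specs = tuple(trajectory_spec)
            if len(specs) != n_groups:
                raise ValueError("one TrajectorySpec per group required")
        self.specs = specs

        df = panel.data
        self.persons = panel.persons
        codes = pd.Categorical(df["person_id"], categories=self.persons).codes
        self._pidx = np.asarray(codes, dtype=np.intp)
        self._y = df["count"].to_numpy(dtype=float)
        ages = df["age"].to_numpy(dtype=float)
        self.age_range = (float(ages.min()), float(ages.max()))
        self._uages, inv = np.unique(ages, return_inverse=True)
        for s in specs:
            s.validate_for_range(*self.age_range)
        self._designs = [s.design(self._uages, age_range=self.age_range)[inv] for s in specs]
        self._udesigns = [s.design(self._uages, age_range=self.age_range) for s in specs]
        self._n = len(self.persons)
        self._nobs = len(self._y)
        self._loggamma = gammaln(self._y + 1.0)

        if covariates is not None:
            names = tuple(covariate_names) if covariate_names is not None else covariates.covariate_names
            Xc = covariates.matrix(self.persons, names, imputation_id=imputation_id)
            self.covariate_names = names
            self._Xm = np.column_stack([np.ones(self._n), Xc])
        else:
            if covariate_names:
                raise ValueError("covariate_names given without a covariate table")
            self.covariate_names = ()
            self._Xm = np.ones((self._n, 1))
        self._q = self._Xm.shape[1]

    # -- likelihood machinery ----------------------------------------------

    def _component_loglik(self, beta) -> np.ndarray:
        """(n_persons, J) log P(Y_i | group j) under conditional independence."""
        out = np.empty((self._n, self.n_groups))
        for j in range(self.n_groups):
            eta = np.minimum(self._designs[j] @ beta[j], _ETA_MAX)
            lam = np.exp(eta)
            ll = self._y * np.log(np.maximum(lam, _RATE_FLOOR)) - lam - self._loggamma
            out[:, j] = np.bincount(self._pidx, weights=ll, minlength=self._n)
        return out

    def _log_pi(self, theta) -> np.ndarray:
        L = np.column_stack([np.zeros(self._n), self._Xm @ theta.T])
        return L - logsumexp(L, axis=1, keepdims=True)

    def loglike(self, mixture: MixtureModel) -> float:
        """Mixture log-likelihood, computed stably in log space."""
        comp = self._component_loglik(mixture.beta)
        return float(np.sum(logsumexp(self._log_pi(mixture.theta) + comp, axis=1)))

    def posterior(self, mixture: MixtureModel) -> np.ndarray:
        """(n_persons, J) posterior membership probabilities (rows sum to 1)."""
        M = self._log_pi(mixture.theta) + self._component_loglik(mixture.beta)
        return np.exp(M - logsumexp(M, axis=1, keepdims=True))

    def _loglike_grad(self, beta, theta):
        """Log-likelihood and its gradient in packed order (betas, thetas)."""
        comp = self._component_loglik(beta)
        logpi = self._log_pi(theta)
        M = logpi + comp
        lse = logsumexp(M, axis=1, keepdims=True)
        W = np.exp(M - lse)
        ll = float(lse.sum())
        gparts = []
        for j in range(self.n_groups):
            lam = np.exp(np.minimum(self._designs[j] @ beta[j], _ETA_MAX))
            w_obs = W[self._pidx, j]
            gparts.append(self._designs[j].T @ (w_obs * (self._y - lam)))
        pi = np.exp(logpi)
        for j in range(1, self.n_groups):
            gparts.append(self._Xm.T @ (W[:, j] - pi[:, j]))
        return ll, np.concatenate(gparts), W

    # -- parameter packing --------------------------------------------------

    def _pack(self, beta, theta) -> np.ndarray:
        return np.concatenate([*beta, theta.ravel()])

    def _unpack(self, x):
        beta, pos = [], 0
        for s in self.specs:
            beta.append(x[pos:pos + s.n_basis])
            pos += s.n_basis
        theta = x[pos:].reshape(self.n_groups - 1, self._q)
        return beta, theta

    @property
    def param_names(self) -> list[str]:
        names = []
        for j, s in enumerate(self.specs):
            names += [f"beta[{j}][{k}]" for k in range(s.n_basis)]
        mem = ("const",) + self.covariate_names
        for j in range(1, self.n_groups):
            names += [f"theta[{j}][{c}]" for c in mem]
        return names

    # -- M-step solvers ------------------------------------------------------

    def _weighted_poisson(self, D, w_obs, beta0, tol=1e-10, max_iter=60):
        """Newton solve of the w-weighted Poisson log-linear regression."""
        beta = np.asarray(beta0, dtype=float).copy()

        def obj(b):
            lam = np.exp(np.minimum(D @ b, _ETA_MAX))
            return float(np.sum(w_obs * (self._y * np.log(np.maximum(lam, _RATE_FLOOR)) - lam)))

        f = obj(beta)
        for _ in range(max_iter):
            lam = np.exp(np.minimum(D @ beta, _ETA_MAX))
            g = D.T @ (w_obs * (self._y - lam))
            H = D.T @ (D * (w_obs * lam)[:, None])
            H[np.diag_indices_from(H)] += 1e-10
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            norm = np.max(np.abs(step))
            if norm > 5.0:  # trust region for near-degenerate groups
                step *= 5.0 / norm
            t = 1.0
            for _ in range(40):
                f_new = obj(beta + t * step)
                if f_new >= f - 1e-13 * (abs(f) + 1):
                    break
                t *= 0.5
            beta = beta + t * step
            improved = f_new - f
            f = f_new
            if np.max(np.abs(t * step)) < tol and improved < 1e-12 * (abs(f) + 1):
                break
        return beta

    def _mlogit_update(self, W, theta0, max_iter=50):
        """Weighted multinomial-logit M-step: max_theta sum_ij W_ij log pi_j(x_i)."""
        if self._q == 1:
            p = np.maximum(W.mean(axis=0), 1e-12)
            return (np.log(p[1:] / p[0]))[:, None]
        J, q, X = self.n_groups, self._q, self._Xm
        theta = theta0.copy()

        def obj(th):
            return float(np.sum(W * self._log_pi(th)))

        f = obj(theta)
        for _ in range(max_iter):
            logpi = self._log_pi(theta)
            pi = np.exp(logpi)
            g = np.concatenate([X.T @ (W[:, j] - pi[:, j]) for j in range(1, J)])
            H = np.zeros(((J - 1) * q, (J - 1) * q))
            for a in range(1, J):
                for b in range(1, J):
                    wab = pi[:, a] * ((a == b) - pi[:, b])
                    H[(a - 1) * q:a * q, (b - 1) * q:b * q] = -X.T @ (X * wab[:, None])
            H[np.diag_indices_from(H)] -= 1e-10
            try:
                step = np.linalg.solve(H, -g).reshape(J - 1, q)
            except np.linalg.LinAlgError:
                break
            t, f_new = 1.0, None
            for _ in range(40):
                f_new = obj(theta + t * step)
                if f_new >= f - 1e-13 * (abs(f) + 1):
                    break
                t *= 0.5
            theta = theta + t * step
            improved = f_new - f
            f = f_new
            if np.max(np.abs(t * step)) < 1e-10 and improved < 1e-12 * (abs(f) + 1):
                break
        return theta

    # -- initialization ------------------------------------------------------

    def _initial_weights(self, rng, noisy: bool) -> np.ndarray:
        """Quantile strata of per-person mean counts, optionally jittered."""
        totals = np.bincount(self._pidx, weights=self._y, minlength=self._n)
        spans = np.bincount(self._pidx, minlength=self._n).astype(float)
        score = totals / np.maximum(spans, 1.0)
        if noisy:
            score = score * np.exp(0.5 * rng.standard_normal(self._n))
        score = score + 1e-9 * rng.random(self._n)  # break ties among zeros
        order = np.argsort(score, kind="stable")
        strata = np.empty(self._n, dtype=int)
        for j, block in enumerate(np.array_split(order, self.n_groups)):
            strata[block] = j
        W = np.full((self._n, self.n_groups), 0.1 / max(self.n_groups - 1, 1))
        W[np.arange(self._n), strata] = 0.9
        if self.n_groups == 1:
            W[:] = 1.0
        return W / W.sum(axis=1, keepdims=True)

    # -- fitting -------------------------------------------------------------

    def fit(self, n_starts: int = 20, seed: int = 0, max_em_iter: int = 500,
            em_tol: float = 1e-8, gtol: float = 1e-5, polish: bool = True,
            compute_se: bool = False) -> "GroupTrajectoryResults":
        """Maximum-likelihood fit; best of ``n_starts`` seeded initializations.

        Convergence requires relative log-likelihood change below ``em_tol``
        in EM and a small scaled gradient after the quasi-Newton polish
        (inf-norm below ``gtol * (1 + |loglik|)``).
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self._n < self.n_groups:
            raise ValueError("need at least J persons to fit J groups")
        best = None
        for start in range(n_starts):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), start]))
            W = self._initial_weights(rng, noisy=start > 0)
            beta = [np.zeros(s.n_basis) for s in self.specs]
            # seed each beta from its stratum's mean rate
            for j in range(self.n_groups):
                w_obs = W[self._pidx, j]
                mean_rate = max(float(np.sum(w_obs * self._y) / max(np.sum(w_obs), 1e-12)), 1e-6)
                beta[j][0] = np.log(mean_rate)
            theta = np.zeros((self.n_groups - 1, self._q))

            path = []
            ll_old = -np.inf
            for _ in range(max_em_iter):
                for j in range(self.n_groups):
                    beta[j] = self._weighted_poisson(self._designs[j], W[self._pidx, j], beta[j])
                theta = self._mlogit_update(W, theta)
                M = self._log_pi(theta) + self._component_loglik(beta)
                lse = logsumexp(M, axis=1, keepdims=True)
                ll = float(lse.sum())
                W = np.exp(M - lse)
                path.append(ll)
                if np.isfinite(ll_old) and ll - ll_old <= em_tol * (abs(ll_old) + 1.0):
                    break
                ll_old = ll

            if polish and self.n_groups > 1:
                x0 = self._pack(beta, theta)

                def negf(x):
                    b, t = self._unpack(x)
                    ll_, g, _ = self._loglike_grad(b, t)
                    return -ll_, -g

                res = minimize(negf, x0, jac=True, method="L-BFGS-B",
                               options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8})
                if -res.fun >= ll:
                    beta, theta = self._unpack(res.x)
                    ll = -res.fun
                    path.append(ll)

            ll_final, grad, W = self._loglike_grad(beta, theta)
            cand = (ll_final, start, [b.copy() for b in beta], theta.copy(), W, path, grad)
            if best is None or cand[0] > best[0] + 1e-12:
                best = cand

        ll, start_idx, beta, theta, W, path, grad = best
        mixture = MixtureModel(specs=self.specs, beta=tuple(beta), theta=theta,
                               covariate_names=self.covariate_names, age_range=self.age_range)
        order = np.argsort(mixture.mean_rates(self._uages), kind="stable")
        mixture = mixture.permute(order)
        W = W[:, order]
        _, grad, _ = self._loglike_grad(mixture.beta, mixture.theta)
        gnorm = float(np.max(np.abs(grad))) if grad.size else 0.0
        converged = gnorm < gtol * (1.0 + abs(ll))
        if not converged:
            warnings.warn(f"fit did not reach gradient tolerance (|g|={gnorm:.2e})",
                          RuntimeWarning, stacklevel=2)

        se = None
        if compute_se:
            se = self._standard_errors(mixture)

        return GroupTrajectoryResults(
            model=self, mixture=mixture, loglik=ll, posterior_matrix=W,
            converged=bool(converged), n_starts_used=n_starts,
            gradient_norm=gnorm, em_loglik_path=tuple(path), se=se,
        )

    def _standard_errors(self, mixture: MixtureModel) -> pd.Series:
        """Observed-information SEs via central differences of the score."""
        x0 = self._pack(list(mixture.beta), mixture.theta)
        k = len(x0)

        def score(x):
            b, t = self._unpack(x)
            return self._loglike_grad(b, t)[1]

        Jac = np.empty((k, k))
        for i in range(k):
            h = 1e-5 * (1.0 + abs(x0[i]))
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            Jac[:, i] = (score(xp) - score(xm)) / (2 * h)
        info = -(Jac + Jac.T) / 2.0
        info[np.diag_indices_from(info)] += 1e-8
        try:
            cov = np.linalg.inv(info)
            d = np.diag(cov)
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        return pd.Series(se, index=self.param_names)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class GroupTrajectoryResults:
    """Fitted trajectory mixture: estimates, diagnostics, and accessors."""

    def __init__(self, model, mixture, loglik, posterior_matrix, converged,
                 n_starts_used, gradient_norm, em_loglik_path, se=None):
        self.model = model
        self.mixture = mixture
        self.loglik = float(loglik)
        self._posterior = np.asarray(posterior_matrix, dtype=float)
        self.converged = converged
        self.n_starts_used = n_starts_used
        self.gradient_norm = gradient_norm
        self.em_loglik_path = em_loglik_path
        self.se = se

    @property
    def n_groups(self) -> int:
        return self.mixture.n_groups

    @property
    def n_params(self) -> int:
        return self.mixture.n_params

    @property
    def bic(self) -> float:
        """BIC with n = number of persons (the independent units)."""
        return -2.0 * self.loglik + self.n_params * np.log(self.model._n)

    @property
    def bic_obs(self) -> float:
        """BIC with n = number of person-period observations."""
        return -2.0 * self.loglik + self.n_params * np.log(self.model._nobs)

    @property
    def posterior(self) -> pd.DataFrame:
        return pd.DataFrame(self._posterior, index=self.model.persons,
                            columns=range(self.n_groups))

    @property
    def assignments(self) -> pd.Series:
        """Hard classification: maximum-posterior group (ties to lowest index)."""
        return pd.Series(np.argmax(self._posterior, axis=1),
                         index=self.model.persons, name="group")

    @property
    def params(self) -> pd.Series:
        packed = self.model._pack(list(self.mixture.beta), self.mixture.theta)
        return pd.Series(packed, index=self.model.param_names)

    @property
    def bse(self) -> pd.Series:
        if self.se is None:
            raise ValueError("standard errors not computed; refit with compute_se=True")
        return self.se

    def group_shares(self) -> np.ndarray:
        """Estimated membership probabilities pi-hat (sample-averaged priors)."""
        Xc = self.model._Xm[:, 1:] if self.model.covariate_names else None
        return self.mixture.membership_probabilities(Xc).mean(axis=0) \
            if Xc is not None else self.mixture.membership_probabilities()[0]

    def rate_curve(self, ages=None) -> pd.DataFrame:
        """Expected count per group on an age grid (trajectory-plot points)."""
        if ages is None:
            lo, hi = self.mixture.age_range
            ages = np.arange(int(lo), int(hi) + 1)
        ages = np.asarray(ages)
        return pd.DataFrame(
            {f"group_{j}": self.mixture.rate(j, ages) for j in range(self.n_groups)},
            index=pd.Index(ages, name="age"),
        )

    def summary(self) -> str:
        lines = [
            "Group-based trajectory model (Poisson mixture)",
            f"  persons: {self.model._n}   person-ages: {self.model._nobs}   groups: {self.n_groups}",
            f"  loglik: {self.loglik:.4f}   BIC(n=persons): {self.bic:.2f}   params: {self.n_params}",
            f"  converged: {self.converged}   |grad|: {self.gradient_norm:.2e}   starts: {self.n_starts_used}",
            "",
        ]
        shares = self.group_shares()
        assigned = np.bincount(self.assignments.to_numpy(), minlength=self.n_groups) / self.model._n
        lines.append("  group   pi_hat   assigned   peak_rate")
        ages = self.model._uages
        for j in range(self.n_groups):
            peak = float(np.max(self.mixture.rate(j, ages)))
            lines.append(f"  {j:5d}   {shares[j]:6.3f}   {assigned[j]:8.3f}   {peak:9.3f}")
        lines.append("")
        se = self.se if self.se is not None else pd.Series(np.nan, index=self.model.param_names)
        lines.append(f"  {'parameter':<24s} {'estimate':>10s} {'std err':>10s}")
        for name, val in self.params.items():
            lines.append(f"  {name:<24s} {val:10.4f} {se.get(name, np.nan):10.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable fit summary (coefficients + metadata)."""
        return {
            "n_groups": self.n_groups,
            "loglik": self.loglik,
            "bic_persons": self.bic,
            "bic_observations": self.bic_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "gradient_norm": self.gradient_norm,
            "n_starts_used": self.n_starts_used,
            "covariate_names": list(self.mixture.covariate_names),
            "beta": [list(map(float, b)) for b in self.mixture.beta],
            "theta": [list(map(float, row)) for row in self.mixture.theta],
            "group_shares": [float(v) for v in self.group_shares()],
        }


# ---------------------------------------------------------------------------
# functional API
# ---------------------------------------------------------------------------

def fit(panel: Panel, spec: TrajectorySpec | list = TrajectorySpec(), J: int = 3,
        covariates: CovariateTable | None = None, n_starts: int = 20,
        seed: int = 0, **kwargs) -> GroupTrajectoryResults:
    """Fit a J-group trajectory mixture to a panel (convenience wrapper)."""
    return GroupTrajectoryModel(panel, J, spec, covariates=covariates).fit(
        n_starts=n_starts, seed=seed, **kwargs)


def rate(model: MixtureModel, group: int, age):
    """Expected count of ``group`` at ``age`` under the mixture parameters."""
    return model.rate(group, age)


def log_likelihood(model: MixtureModel, panel: Panel,
                   covariates: CovariateTable | None = None) -> float:
    gm = GroupTrajectoryModel(panel, model.n_groups, model.specs,
                              covariates=covariates,
                              covariate_names=model.covariate_names or None)
    return gm.loglike(model)


def posterior_probabilities(model: MixtureModel, panel: Panel,
                            covariates: CovariateTable | None = None) -> pd.DataFrame:
    gm = GroupTrajectoryModel(panel, model.n_groups, model.specs,
                              covariates=covariates,
                              covariate_names=model.covariate_names or None)
    return pd.DataFrame(gm.posterior(model), index=gm.persons,
                        columns=range(model.n_groups))
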