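"""Model selection over the number of groups and classification diagnostics.

Selection compares BIC across candidate models differing in the number of
latent groups and/or trajectory basis.  Classification adequacy follows the
standard trajectory-modeling diagnostics: estimated membership
probabilities should track the shares actually assigned by maximum
posterior, and the average posterior probability among persons assigned to
each group (AvePP) should clear 0.7.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import TrajectorySpec
from .model import GroupTrajectoryModel, GroupTrajectoryResults
from .panel import CovariateTable, Panel

__all__ = ["SelectionGrid", "AdequacyReport", "bic", "select_model",
           "assign_groups", "adequacy"]

logger = logging.getLogger(__name__)

AVEPP_MINIMUM = 0.7


def bic(loglik: float, n_params: int, n: int) -> float:
    """Bayesian information criterion, -2*loglik + n_params*ln(n); lower is better."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    return -2.0 * loglik + n_params * np.log(n)


@dataclass
class Candidate:
    """One grid point: J groups with a given basis, and its fit."""

    J: int
    spec: TrajectorySpec
    result: GroupTrajectoryResults

    @property
    def bic(self) -> float:
        return self.result.bic

    @property
    def converged(self) -> bool:
        return self.result.converged


@dataclass
class SelectionGrid:
    """Fitted candidate grid with the BIC-chosen model.

    The chosen candidate minimizes BIC among converged fits; exact ties go
    to the smaller J, then to the lower total polynomial order, then to
    grid position.
    """

    candidates: list
    chosen_index: int
    bic_convention: str = "persons"

    @property
    def chosen(self) -> Candidate:
        return self.candidates[self.chosen_index]

    def table(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.candidates):
            rows.append({
                "J": c.J,
                "basis": c.spec.kind,
                "order": c.spec.total_order,
                "loglik": c.result.loglik,
                "n_params": c.result.n_params,
                "bic_persons": c.result.bic,
                "bic_observations": c.result.bic_obs,
                "converged": c.converged,
                "chosen": i == self.chosen_index,
            })
        return pd.DataFrame(rows)


def select_model(panel: Panel, covariates: CovariateTable | None = None,
                 J_range=(1, 2, 3, 4), bases=(TrajectorySpec(),), seed: int = 0,
                 n_starts: int = 5, bic_convention: str = "persons",
                 **fit_kwargs) -> SelectionGrid:
    """Fit every (J, basis) candidate with shared settings and pick by BIC.

    Each candidate is fitted with the same seed and number of starts, so
    the grid is deterministic given (panel, grid, seed).  Non-converged
    candidates stay in the grid, flagged, but are never chosen unless no
    candidate converged.
    """
    J_range = list(J_range)
    bases = list(bases)
    if not J_range or not bases:
        raise ValueError("selection grid is empty")
    if bic_convention not in ("persons", "person-periods"):
        raise ValueError("bic_convention must be 'persons' or 'person-periods'")

    candidates = []
    for J in J_range:
        for spec in bases:
            res = GroupTrajectoryModel(panel, J, spec, covariates=covariates).fit(
                n_starts=n_starts, seed=seed, **fit_kwargs)
            candidates.append(Candidate(J=J, spec=spec, result=res))
            logger.info("select_model: J=%d %s loglik=%.3f bic=%.2f converged=%s",
                        J, spec.kind, res.loglik, res.bic, res.converged)

    def crit(c: Candidate) -> float:
        return c.bic if bic_convention == "persons" else c.result.bic_obs

    pool = [i for i, c in enumerate(candidates) if c.converged] or list(range(len(candidates)))
    if len(pool) < len(candidates):
        warnings.warn("some candidates did not converge; chosen only among converged",
                      RuntimeWarning, stacklevel=2)
    chosen = min(pool, key=lambda i: (round(crit(candidates[i]), 10),
                                      candidates[i].J,
                                      candidates[i].spec.total_order,
                                      i))
    return SelectionGrid(candidates=candidates, chosen_index=chosen,
                         bic_convention=bic_convention)


def assign_groups(posterior) -> np.ndarray:
    """Maximum-posterior hard assignment; ties resolve to the lowest index."""
    P = np.asarray(posterior, dtype=float)
    if np.isnan(P).any():
        raise ValueError("posterior matrix contains NaN")
    return np.argmax(P, axis=1)


@dataclass
class AdequacyReport:
    """Per-group classification diagnostics.

    ``pi_hat`` is the model's estimated membership probability (sample
    average of the prior), ``assigned_share`` the fraction hard-assigned to
    the group, ``avepp`` the mean posterior among those assigned, and
    ``occ`` the odds of correct classification
    (avepp/(1-avepp)) / (pi_hat/(1-pi_hat)).
    """

    table: pd.DataFrame

    @property
    def flagged(self) -> list:
        t = self.table
        return list(t.index[t["avepp"].fillna(0.0) < AVEPP_MINIMUM])

    def __repr__(self) -> str:
        return f"AdequacyReport:\n{self.table.round(4)}"


def adequacy(fit: GroupTrajectoryResults) -> AdequacyReport:
    """Classification-adequacy diagnostics for a converged fit.

    An empty assigned group yields a missing AvePP (with a warning) rather
    than a fabricated value.
    """
    P = fit.posterior.to_numpy()
    J = fit.n_groups
    hard = assign_groups(P)
    pi_hat = fit.group_shares()
    rows = []
    for j in range(J):
        members = hard == j
        if members.any():
            avepp = float(P[members, j].mean())
            occ = (avepp / (1 - avepp)) / (pi_hat[j] / (1 - pi_hat[j])) \
                if 0 < avepp < 1 and 0 < pi_hat[j] < 1 else np.nan
        else:
            warnings.warn(f"group {j} has no assigned members; AvePP undefined",
                          RuntimeWarning, stacklevel=2)
            avepp, occ = np.nan, np.nan
        rows.append({"pi_hat": pi_hat[j],
                     "assigned_share": float(members.mean()),
                     "avepp": avepp,
                     "occ": occ})
    table = pd.DataFrame(rows, index=pd.RangeIndex(J, name="group"))
    return AdequacyReport(table=table)
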