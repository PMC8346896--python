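"""Within-group arrest-rate tables and counterfactual cohort decomposition.

Cohorts differ in their overall arrest rate both because they belong to
trajectory groups in different proportions (composition) and because
members of the same group are arrested at different rates (intensity).
The decomposition separates the two by swapping one cohort's group shares
or within-group rates for the other's and comparing the implied overall
rate with the observed one.  A permutation test provides a distribution-
free check on within-group cohort contrasts in cell means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CHARGE_CATEGORIES, Panel

__all__ = ["RateTable", "DecompositionResult", "rate_table", "percent_excess",
           "decompose", "cohort_gap", "permutation_test"]

logger = logging.getLogger(__name__)

_SHARE_TOL = 0.01  # printed shares are rounded; tolerate rounding slack


@dataclass
class RateTable:
    """Mean arrests per person by (group, cohort) over a stated age window.

    ``table`` is indexed by (group, cohort) with columns ``n_persons`` and
    ``rate`` plus per-category rates when requested.  Offense-category
    rates need not sum to the total: one arrest can carry several charge
    types.  Cells with no persons are absent, not zero.
    """

    table: pd.DataFrame
    window: tuple
    n_excluded: int = 0

    def cell(self, group, cohort, column: str = "rate") -> float:
        return float(self.table.loc[(group, cohort), column])

    def __repr__(self) -> str:
        lo, hi = self.window
        return f"RateTable (ages {lo}-{hi}):\n{self.table.round(3)}"


def rate_table(panel: Panel, assignments, window: tuple,
               by_offense: bool = False, on_partial: str = "exclude") -> RateTable:
    """Per-(group, cohort) mean arrest counts inside ``window``.

    ``assignments`` maps person_id to group (a Series or dict).  Persons
    whose observation window does not fully cover ``window`` are excluded
    with a logged count, or raise when ``on_partial="error"``.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"inverted window [{lo}, {hi}]")
    if on_partial not in ("exclude", "error"):
        raise ValueError("on_partial must be 'exclude' or 'error'")
    assign = pd.Series(assignments)
    assign.index = assign.index.astype(str)

    w = panel.windows
    covered = w.index[(w["min_age"] <= lo) & (w["max_age"] >= hi)]
    n_excluded = panel.n_persons - len(covered)
    if n_excluded and on_partial == "error":
        raise ValueError(f"{n_excluded} person(s) lack full coverage of ages [{lo}, {hi}]")
    if n_excluded:
        logger.info("rate_table: excluded %d person(s) without full [%d, %d] coverage",
                    n_excluded, lo, hi)

    df = panel.data
    df = df[df["person_id"].isin(covered) & (df["age"] >= lo) & (df["age"] <= hi)]
    missing = [p for p in df["person_id"].unique() if p not in assign.index]
    if missing:
        raise KeyError(f"no group assignment for person(s): {missing[:5]}")

    value_cols = ["count"] + ([f"n_{c}" for c in CHARGE_CATEGORIES]
                              if by_offense and panel.has_charges else [])
    per_person = df.groupby(["person_id", "cohort"])[value_cols].sum().reset_index()
    per_person["group"] = per_person["person_id"].map(assign)
    agg = per_person.groupby(["group", "cohort"]).agg(
        n_persons=("person_id", "size"),
        **{("rate" if c == "count" else c.replace("n_", "rate_")): (c, "mean")
           for c in value_cols},
    )
    return RateTable(table=agg, window=(lo, hi), n_excluded=n_excluded)


def percent_excess(rate_a: float, rate_b: float) -> float:
    """Percent by which ``rate_a`` exceeds ``rate_b``: 100*(a/b - 1)."""
    if rate_b <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * (rate_a / rate_b - 1.0)


def cohort_gap(rate_young: float, rate_old: float) -> float:
    """Older-minus-younger difference in overall arrest rates."""
    return rate_old - rate_young


@dataclass
class DecompositionResult:
    """Actual and counterfactual cohort arrest rates with attributions.

    Counterfactuals for the younger cohort:

    * ``rate_swap`` — own group shares, the older cohort's within-group rates;
    * ``composition_swap`` — the older cohort's group shares, own rates;
    * ``targeted_swap[j]`` — own shares and rates except group j's rate
      replaced by the older cohort's.

    ``pct_*`` fields express each counterfactual as a percent difference
    from the younger cohort's actual rate.
    """

    actual_young: float
    actual_old: float
    rate_swap: float
    composition_swap: float
    targeted_swap: dict
    gap: float = field(init=False)

    def __post_init__(self):
        self.gap = self.actual_old - self.actual_young

    def pct(self, counterfactual: float) -> float:
        return percent_excess(counterfactual, self.actual_young)

    @property
    def pct_rate_swap(self) -> float:
        return self.pct(self.rate_swap)

    @property
    def pct_composition_swap(self) -> float:
        return self.pct(self.composition_swap)

    def to_dict(self) -> dict:
        return {
            "actual_young": self.actual_young,
            "actual_old": self.actual_old,
            "gap": self.gap,
            "rate_swap": self.rate_swap,
            "composition_swap": self.composition_swap,
            "targeted_swap": {str(k): v for k, v in self.targeted_swap.items()},
            "pct_rate_swap": self.pct_rate_swap,
            "pct_composition_swap": self.pct_composition_swap,
        }


def decompose(shares_young, rates_young, shares_old, rates_old) -> DecompositionResult:
    """Counterfactual decomposition of the cohort difference in arrest rates.

    Each cohort's overall rate is the share-weighted sum of its within-group
    rates; swapping shares or rates between cohorts attributes the gap to
    composition versus within-group intensity.  Group order must be aligned
    across all four inputs; shares must each sum to 1 (within rounding
    slack, since published shares are rounded).
    """
    sy = np.asarray(shares_young, dtype=float)
    so = np.asarray(shares_old, dtype=float)
    ry = np.asarray(rates_young, dtype=float)
    ro = np.asarray(rates_old, dtype=float)
    if not (len(sy) == len(so) == len(ry) == len(ro)):
        raise ValueError("inputs must share one group axis")
    for name, s in (("young", sy), ("old", so)):
        if abs(s.sum() - 1.0) > _SHARE_TOL:
            raise ValueError(f"{name} shares sum to {s.sum():.4f}, not 1")
    targeted = {}
    for j in range(len(sy)):
        r = ry.copy()
        r[j] = ro[j]
        targeted[j] = float(sy @ r)
    return DecompositionResult(
        actual_young=float(sy @ ry),
        actual_old=float(so @ ro),
        rate_swap=float(sy @ ro),
        composition_swap=float(so @ ry),
        targeted_swap=targeted,
    )


def permutation_test(panel: Panel, assignments, group, window: tuple,
                     n_perm: int = 999, seed: int = 0,
                     cohorts: tuple | None = None) -> float:
    """Two-sided permutation p-value for the cohort difference in cell means.

    Within the named group, person-level window totals are compared between
    the two cohorts via the difference in means; cohort labels are permuted
    across persons.  p = (1 + #{|perm diff| >= |observed diff|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    assign = pd.Series(assignments)
    assign.index = assign.index.astype(str)
    members = assign.index[assign == group]
    if not len(members):
        raise ValueError(f"group {group!r} is empty")
    totals = panel.person_totals(window=window).reindex(members)
    coh = panel.cohorts.reindex(members)
    labels = sorted(coh.unique()) if cohorts is None else list(cohorts)
    if len(labels) != 2:
        raise ValueError(f"need exactly two cohorts, found {labels}")
    a = totals[coh == labels[0]].to_numpy(dtype=float)
    b = totals[coh == labels[1]].to_numpy(dtype=float)
    if not len(a) or not len(b):
        raise ValueError(f"a cohort is absent from group {group!r}")

    obs = b.mean() - a.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_b = len(b)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[:n_b].mean() - perm[n_b:].mean()
        if abs(diff) >= abs(obs) - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)
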