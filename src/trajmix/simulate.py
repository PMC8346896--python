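"""Synthetic multicohort arrest panels from a fully specified generative model.

The study data this package is designed around are restricted-access, so a
seeded generator produces panels with the same structure: several birth
cohorts observed over unbalanced, partially overlapping age windows; a
small number of latent trajectory groups with cubic log-polynomial Poisson
rate curves peaking in late adolescence; group membership following a
multinomial logit in cohort and baseline covariates; and per-arrest charge
categories (drugs/violence/property/other) whose mix differs by group and
cohort.

``default_study_spec`` returns the calibrated default: three groups whose
expected arrest counts at age 19 are roughly 0.02 / 0.35 / 1.44 (the high
group declining to 0.55 by age 30), marginal membership near
0.787 / 0.168 / 0.045, and older-vs-younger cohort odds ratios of about
2.97 (medium vs low) and 1.58 (high vs low).  Calibration details live in
``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

from .basis import TrajectorySpec
from .model import MixtureModel
from .panel import CHARGE_CATEGORIES, CovariateTable, Panel

__all__ = [
    "CohortSpec",
    "CovariateModel",
    "GenerativeSpec",
    "simulate_panel",
    "default_study_spec",
    "implied_group_shares",
    "implied_membership",
    "trajectory_from_landmarks",
]


@dataclass(frozen=True)
class CohortSpec:
    """One birth cohort: label, population share, inclusive age window."""

    label: str
    share: float
    window: tuple


@dataclass(frozen=True)
class CovariateModel:
    """Distributions of baseline covariates: Bernoulli binaries, normal scales."""

    binaries: dict = field(default_factory=dict)   # name -> P(=1)
    normals: dict = field(default_factory=dict)    # name -> (mean, sd)

    @property
    def names(self) -> tuple:
        return tuple(self.binaries) + tuple(self.normals)


@dataclass(frozen=True)
class GenerativeSpec:
    """Complete generative description of a multicohort trajectory panel.

    ``mixture`` carries the trajectory coefficients beta_j and the
    membership-logit coefficients theta_j; its ``covariate_names`` may
    include the derived indicator ``cohort_older`` (1 for cohorts listed in
    ``older_labels``) alongside names drawn from ``covariate_model``.
    ``charge_mix`` maps (group index, "younger"/"older") to per-category
    inclusion probabilities applied independently to each simulated arrest,
    with the "other" category forced when no category fires.
    ``rate_multipliers`` optionally scales a group's rate curve within a
    cohort class, emulating within-group cohort differences in offending
    intensity; the default (all 1.0) leaves rates purely group-and-age
    determined.
    """

    mixture: MixtureModel
    cohorts: tuple
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    older_labels: tuple = ()
    charge_mix: dict | None = None
    rate_multipliers: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        shares = np.array([c.share for c in self.cohorts], dtype=float)
        if len(shares) == 0:
            raise ValueError("at least one cohort required")
        if abs(shares.sum() - 1.0) > 1e-8:
            raise ValueError(f"cohort shares sum to {shares.sum()}, not 1")
        if (shares < 0).any():
            raise ValueError("cohort shares must be nonnegative")
        known = set(self.covariate_model.names) | {"cohort_older"}
        unknown = [n for n in self.mixture.covariate_names if n not in known]
        if unknown:
            raise ValueError(f"membership covariates without a generative law: {unknown}")
        if self.charge_mix is not None:
            for key, probs in self.charge_mix.items():
                p = np.array([probs[c] for c in CHARGE_CATEGORIES], dtype=float)
                if ((p < 0) | (p > 1)).any():
                    raise ValueError(f"charge inclusion probabilities for {key} outside [0, 1]")

    def cohort_class(self, label: str) -> str:
        return "older" if label in self.older_labels else "younger"

    def multiplier(self, group: int, label: str) -> float:
        return float(self.rate_multipliers.get((group, self.cohort_class(label)), 1.0))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_panel(spec: GenerativeSpec, n_persons: int, seed: int | None = None):
    """Draw a panel, covariate table, and true group labels from ``spec``.

    For each person: cohort by birth share, covariates from the covariate
    model, latent group from the membership logit, then an independent
    Poisson count at every in-window age with rate lambda_group(age) (times
    any cohort-class multiplier).  Charge categories are drawn per arrest.
    Fully reproducible: the same (spec, n_persons, seed) gives the same
    panel bit for bit.
    """
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mix = spec.mixture
    J = mix.n_groups

    person_id = np.array([f"p{i:06d}" for i in range(n_persons)])
    shares = np.array([c.share for c in spec.cohorts])
    cidx = rng.choice(len(spec.cohorts), size=n_persons, p=shares)
    labels = np.array([spec.cohorts[i].label for i in cidx])

    cov = {}
    for name, p in spec.covariate_model.binaries.items():
        cov[name] = rng.binomial(1, p, size=n_persons).astype(float)
    for name, (m, s) in spec.covariate_model.normals.items():
        cov[name] = m + s * rng.standard_normal(n_persons)
    cov_df = pd.DataFrame(cov, index=person_id)
    cov_df["cohort_older"] = np.isin(labels, spec.older_labels).astype(float)

    if mix.covariate_names:
        X = cov_df[list(mix.covariate_names)].to_numpy()
        pi = mix.membership_probabilities(X)
    else:
        pi = np.tile(mix.membership_probabilities(), (n_persons, 1))
    u = rng.random(n_persons)
    group = (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)
    group = np.minimum(group, J - 1)

    # long frame: one row per in-window person-age
    wins = np.array([spec.cohorts[i].window for i in cidx])
    spans = (wins[:, 1] - wins[:, 0] + 1).astype(int)
    pidx = np.repeat(np.arange(n_persons), spans)
    ages = np.concatenate([np.arange(lo, hi + 1) for lo, hi in wins])

    uages = np.unique(ages)
    rate_table = np.column_stack([mix.rate(j, uages) for j in range(J)])
    aidx = np.searchsorted(uages, ages)
    lam = rate_table[aidx, group[pidx]]
    mult = np.array([spec.multiplier(g, l) for g, l in zip(group, labels)])
    lam = lam * mult[pidx]
    counts = rng.poisson(lam)

    data = pd.DataFrame({
        "person_id": person_id[pidx],
        "cohort": labels[pidx],
        "age": ages.astype(np.int64),
        "count": counts.astype(np.int64),
    })

    if spec.charge_mix is not None:
        cat_counts = _draw_charges(rng, spec, counts, group[pidx],
                                   np.array([spec.cohort_class(l) for l in labels])[pidx])
        for k, cat in enumerate(CHARGE_CATEGORIES):
            data[f"n_{cat}"] = cat_counts[:, k].astype(np.int64)

    windows = pd.DataFrame({"person_id": person_id,
                            "min_age": wins[:, 0], "max_age": wins[:, 1]})
    panel = Panel(data, windows=windows)
    cov_out = cov_df.reset_index(names="person_id")
    cov_out.insert(1, "imputation_id", 0)
    covariates = CovariateTable(cov_out)
    true_labels = pd.Series(group, index=person_id, name="group")
    return panel, covariates, true_labels


def _draw_charges(rng, spec, counts, row_group, row_class):
    """Per-arrest independent category inclusions with a forced fallback.

    An arrest can carry several charge types; one with none of
    drugs/violence/property/other is recorded as "other".
    """
    n_rows = len(counts)
    total = int(counts.sum())
    out = np.zeros((n_rows, len(CHARGE_CATEGORIES)), dtype=np.int64)
    if total == 0:
        return out
    row_of_arrest = np.repeat(np.arange(n_rows), counts)
    probs = np.empty((total, len(CHARGE_CATEGORIES)))
    for (g, cls), mixp in spec.charge_mix.items():
        mask = (row_group[row_of_arrest] == g) & (row_class[row_of_arrest] == cls)
        if mask.any():
            probs[mask] = [mixp[c] for c in CHARGE_CATEGORIES]
    fired = rng.random((total, len(CHARGE_CATEGORIES))) < probs
    none = ~fired.any(axis=1)
    fired[none, CHARGE_CATEGORIES.index("other")] = True
    for k in range(len(CHARGE_CATEGORIES)):
        out[:, k] = np.bincount(row_of_arrest, weights=fired[:, k], minlength=n_rows)
    return out


# ---------------------------------------------------------------------------
# the calibrated default
# ---------------------------------------------------------------------------

def trajectory_from_landmarks(spec: TrajectorySpec, ages, rates,
                              age_range=(10.0, 33.0)) -> np.ndarray:
    """Coefficients whose log-rate curve passes through (ages, log rates).

    Exact interpolation when the number of landmarks equals the basis
    dimension, least squares otherwise.
    """
    D = spec.design(ages, age_range=age_range)
    target = np.log(np.asarray(rates, dtype=float))
    if D.shape[0] == D.shape[1]:
        return np.linalg.solve(D, target)
    return np.linalg.lstsq(D, target, rcond=None)[0]


# age/rate landmarks for the three default curves: near-zero low group,
# a medium group peaking at 0.35, a high group peaking at 1.44 at age 19
# and declining to 0.55 by age 30
_LANDMARK_AGES = (10.0, 19.0, 25.0, 30.0)
_LANDMARK_RATES = {
    "low": (0.001, 0.02, 0.012, 0.006),
    "medium": (0.010, 0.35, 0.180, 0.080),
    "high": (0.200, 1.44, 1.000, 0.550),
}

#: per-arrest charge-category inclusion probabilities by (group, cohort class),
#: set to the offense-specific / total rate ratios of the emulated tables; the
#: older high group's drug inclusion is markedly above the younger's
_DEFAULT_CHARGE_MIX = {
    (0, "younger"): {"drugs": 0.30, "violence": 0.20, "property": 0.20, "other": 0.50},
    (0, "older"): {"drugs": 0.25, "violence": 0.19, "property": 0.25, "other": 0.50},
    (1, "younger"): {"drugs": 0.167, "violence": 0.270, "property": 0.218, "other": 0.512},
    (1, "older"): {"drugs": 0.270, "violence": 0.201, "property": 0.250, "other": 0.406},
    (2, "younger"): {"drugs": 0.157, "violence": 0.207, "property": 0.281, "other": 0.570},
    (2, "older"): {"drugs": 0.336, "violence": 0.141, "property": 0.219, "other": 0.442},
}

# membership-logit targets (see docs/methods.md): cohort odds ratios for the
# older cohorts, covariate effects calibrated to the published profile
# contrasts, and younger-cohort average membership (0.877, 0.086, 0.037)
_YOUNG_TARGET = np.array([0.877, 0.086, 0.037])
_COHORT_LOGODDS = (np.log(2.972), np.log(1.575))     # medium, high vs low
_EFFECTS = {
    "male": (0.8, 1.2),
    "tanf": (0.45, 0.45),
    "self_control": (-0.40, -0.40),
}


def _covariate_cells(cm: CovariateModel, n_nodes: int = 31):
    """Quadrature cells over the covariate distribution: (weights, values)."""
    names = list(cm.names)
    cells = [({}, 1.0)]
    for name, p in cm.binaries.items():
        cells = [({**c, name: v}, w * (p if v else 1 - p))
                 for c, w in cells for v in (1.0, 0.0)]
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_nodes)
    wts = wts / wts.sum()
    for name, (m, s) in cm.normals.items():
        cells = [({**c, name: m + s * z}, w * wz)
                 for c, w in cells for z, wz in zip(nodes, wts)]
    return names, cells


def _average_pi(mix: MixtureModel, cm: CovariateModel, cohort_older: float,
                cells=None) -> np.ndarray:
    """Covariate-averaged membership probabilities at a fixed cohort value."""
    if not mix.covariate_names:
        return mix.membership_probabilities()[0]
    _, cells = cells or _covariate_cells(cm)
    X = np.array([[{**c, "cohort_older": cohort_older}[n] for n in mix.covariate_names]
                  for c, _ in cells])
    w = np.array([w for _, w in cells])
    return w @ mix.membership_probabilities(X)


def default_study_spec(seed: int = 0) -> GenerativeSpec:
    """The calibrated three-group, four-cohort default generative model.

    Trajectories are cubic (in a centered, rescaled age) interpolating the
    landmark rates above.  Membership intercepts are solved numerically so
    that the covariate-averaged younger-cohort membership equals
    (0.877, 0.086, 0.037); combined with the cohort odds ratios and the
    cohort birth shares this yields marginal group shares near
    0.787 / 0.168 / 0.045.  Cohort windows: cohort 0 observed ages 10–25,
    cohort 9 ages 10–33, cohorts 12 and 15 ages 17–33.
    """
    tspec = TrajectorySpec(kind="polynomial", degree=3)
    beta = tuple(
        trajectory_from_landmarks(tspec, _LANDMARK_AGES, _LANDMARK_RATES[g])
        for g in ("low", "medium", "high")
    )
    cm = CovariateModel(binaries={"male": 0.5, "tanf": 0.3},
                        normals={"self_control": (0.0, 1.0)})
    cov_names = ("cohort_older", "male", "tanf", "self_control")

    def theta_for(intercepts):
        th = np.zeros((2, 1 + len(cov_names)))
        th[:, 0] = intercepts
        th[:, 1] = _COHORT_LOGODDS
        for k, name in enumerate(cov_names[1:], start=2):
            th[:, k] = _EFFECTS[name]
        return th

    cells = _covariate_cells(cm)

    def gap(intercepts):
        mix = MixtureModel(specs=(tspec,) * 3, beta=beta, theta=theta_for(intercepts),
                           covariate_names=cov_names)
        return _average_pi(mix, cm, 0.0, cells=cells)[1:] - _YOUNG_TARGET[1:]

    x0 = np.log(_YOUNG_TARGET[1:] / _YOUNG_TARGET[0])
    sol = root(gap, x0, tol=1e-12)
    if not sol.success:  # pragma: no cover - well-conditioned 2-d solve
        raise RuntimeError("membership intercept calibration failed")

    mixture = MixtureModel(specs=(tspec,) * 3, beta=beta, theta=theta_for(sol.x),
                           covariate_names=cov_names, age_range=(10.0, 33.0))
    # younger-cohort share solved from the mixing identity so that the
    # marginal low-group share lands at 0.787 given the younger (0.877) and
    # covariate-averaged older (~0.746) low-group probabilities; the
    # remaining mass splits evenly over the three older cohorts
    cohorts = (
        CohortSpec("0", 0.3125, (10, 25)),
        CohortSpec("9", 0.2292, (10, 33)),
        CohortSpec("12", 0.2292, (17, 33)),
        CohortSpec("15", 0.2291, (17, 33)),
    )
    return GenerativeSpec(
        mixture=mixture,
        cohorts=cohorts,
        covariate_model=cm,
        older_labels=("9", "12", "15"),
        charge_mix=dict(_DEFAULT_CHARGE_MIX),
        seed=seed,
    )


def implied_membership(spec: GenerativeSpec, cohort_class: str) -> np.ndarray:
    """Covariate-averaged membership probabilities within a cohort class."""
    if cohort_class not in ("younger", "older"):
        raise ValueError("cohort_class must be 'younger' or 'older'")
    return _average_pi(spec.mixture, spec.covariate_model,
                       1.0 if cohort_class == "older" else 0.0)


def implied_group_shares(spec: GenerativeSpec) -> np.ndarray:
    """Marginal group shares implied by theta: cohort-share-weighted average."""
    young = _average_pi(spec.mixture, spec.covariate_model, 0.0)
    old = _average_pi(spec.mixture, spec.covariate_model, 1.0)
    s_old = sum(c.share for c in spec.cohorts if c.label in spec.older_labels)
    return (1.0 - s_old) * young + s_old * old
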