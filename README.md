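# trajmix

Group-based trajectory modeling (GBTM) of longitudinal count panels —
finite mixtures of Poisson age-trajectories with multinomial-logit group
membership — plus the downstream analyses that make multicohort designs
useful: BIC model selection, classification diagnostics, covariate-
conditioned membership (odds ratios, profile probabilities, Rubin pooling
across imputations), within-group rate tables, and the counterfactual
decomposition of cohort differences in overall rates.

The package is aimed at researchers in criminology, epidemiology, and
life-course studies who observe integer event counts (arrests, symptoms,
claims) per person per year of age, over windows that differ across birth
cohorts, and who want to ask both *who follows which trajectory* and *how
much of a between-cohort difference is composition versus within-group
intensity*.

## The model

For person $i$ with counts $y_{it}$ at ages $a_{it}$ over their
observation window, the population distribution of trajectories is a
finite mixture of order $J$:

$$P(Y_i \mid \mathrm{Age}_i) = \sum_{j=1}^{J} \pi_j(x_i)\,
  \prod_t \mathrm{Poisson}\!\left(y_{it};\ \lambda_j(a_{it})\right),$$

with counts conditionally independent across ages given group $j$.  Each
group's expected count is log-linear in an age basis (cubic polynomial in
a rescaled age by default, B-splines optionally):
$\log \lambda_j(a) = \beta_j^\top b(a)$.  Membership follows a
multinomial logit, $\pi_j(x) \propto \exp(\theta_j^\top \tilde{x})$ with
group 1 as reference ($\theta_1 \equiv 0$), where $\tilde{x}$ is an
intercept plus optional baseline covariates (e.g. a cohort indicator, sex,
welfare receipt, self-control).

Estimation is maximum likelihood: EM (posterior-weighted Poisson
regressions for each $\beta_j$, a weighted multinomial-logit update for
$\theta$) followed by a quasi-Newton polish of the full likelihood, over
several seeded starts.  Groups are relabeled in ascending mean-rate order,
so index 0 is always the "low" group.  Standard errors come from the
observed information matrix.

Because real data of this kind are typically restricted-access, a fully
specified synthetic generator (`default_study_spec`) ships with the
package: three groups peaking at age 19 with expected counts about
0.02 / 0.35 / 1.44, marginal membership near 0.787 / 0.168 / 0.045, four
birth cohorts with unbalanced windows (ages 10–25, 10–33, and twice
17–33), cohort- and covariate-dependent membership, and per-arrest charge
categories whose mix differs by group and cohort.

## Worked example

```python
import trajmix as tm
from trajmix.selection import adequacy
from trajmix.membership import membership_effects

spec = tm.default_study_spec()
panel, covs, _ = tm.simulate_panel(spec, 1000, seed=7)
res = tm.GroupTrajectoryModel(panel, 3, covariates=covs).fit(
    n_starts=3, seed=1, compute_se=True)
print(res.summary())
```

```
Group-based trajectory model (Poisson mixture)
  persons: 1000   person-ages: 18239   groups: 3
  loglik: -3726.9883   BIC(n=persons): 7605.95   params: 22
  converged: True   |grad|: 6.81e-05   starts: 3

  group   pi_hat   assigned   peak_rate
      0    0.787      0.802       0.017
      1    0.174      0.160       0.347
      2    0.039      0.038       1.626
```

The fitted membership probabilities (0.787 / 0.174 / 0.039) and peak
rates recover the generative values, and the hard-assigned shares track
`pi_hat` closely — the first adequacy diagnostic.  The second is AvePP,
the mean posterior probability among persons assigned to each group:

```python
print(adequacy(res))
#        pi_hat  assigned_share   avepp         occ
# group
# 0      0.7872           0.802  0.9670      7.9120
# 1      0.1741           0.160  0.9222     56.2655
# 2      0.0387           0.038  0.9992  30738.0489
```

All three groups clear the conventional 0.7 floor.  With covariates in
the membership logit, odds ratios against the low group quantify, e.g.,
how much more likely the older cohorts are to follow the medium
trajectory:

```python
eff = membership_effects(res)
print(eff.table.loc[(1, "cohort_older")])
# coef          0.789
# odds_ratio    2.202   (generative value: 2.972)
# p_value       0.001
```

`trajmix.decompose` then splits a cohort difference in overall rates into
composition (group shares) and intensity (within-group rates) via
counterfactual swaps, and `trajmix.rate_table` builds the per-(group,
cohort) mean-count tables it consumes.

A `trajmix` console script exposes the same stages
(`simulate`, `fit`, `select`, `covariates`, `decompose`, `run`); `run`
executes the whole pipeline from a YAML config and writes a versioned
results JSON plus CSV tables that are byte-identical under a fixed seed.

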