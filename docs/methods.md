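# Methods

## Model

`trajmix` fits group-based trajectory models (GBTM): the population
distribution of a person's longitudinal count sequence is a finite
mixture over J latent groups. Conditional on group j, counts at
different ages are independent Poisson draws with rate
λ_j(a) = exp(β_j·b(a)); the marginal likelihood of person i sums the
group-conditional sequence likelihoods weighted by membership
probabilities π_j(x_i), a multinomial logit in an intercept plus optional
baseline covariates with the lowest-rate group as reference. The key
assumptions are (i) conditional independence of counts across ages given
group, (ii) a parametric (log-polynomial or log-spline) age profile per
group, and (iii) membership determined at baseline — covariates enter the
logit, never the rate curves. Unbalanced panels are handled naturally:
each person contributes only their observed ages, and every in-window age
is treated as observed (a missing row is an error unless the
`dense_windows` option fills it with a zero count).

## Age basis

The default basis is a cubic polynomial in the transformed age
a* = (age − 21.5)/10. Centering at the midpoint of the 10–33 range and
rescaling by a decade keeps the Vandermonde design well conditioned;
coefficients are therefore reported on the a* scale. A cubic B-spline
basis with user-chosen interior knots is available as a sensitivity
option (the cubic's forced late-age inflection is an artifact a spline
does not share); knots must lie strictly inside the observed age range.

## Estimation

Maximum likelihood via EM with a quasi-Newton finish:

* **E-step** — posterior membership probabilities, computed in log space
  (log-sum-exp) so rows sum to one within 1e-12.
* **M-step** — one posterior-weighted Poisson–Newton solve per group
  (step-halving line search, trust cap of 5 on the step inf-norm, ridge
  1e-10) and a weighted multinomial-logit Newton update for θ (closed
  form in the intercept-only case).
* **Polish** — L-BFGS on the full mixture likelihood with the analytic
  gradient, accepted only if it does not decrease the likelihood.
* **Starts** — `n_starts` (default 20) seeded initializations assigning
  persons to J quantile strata of per-person mean counts; start 0 is
  noise-free, later starts jitter the scores multiplicatively
  (σ = 0.5). Ties across equal-likelihood starts resolve to the lowest
  start index.

EM stops when the relative log-likelihood gain falls below `em_tol`
(1e-8 in final fits); the fit is flagged converged when the scaled score
inf-norm is below `gtol`·(1+|loglik|) with `gtol` = 1e-5. Non-convergence
is reported (`converged=False`, a warning), never silently ignored. A
rate floor of 1e-10 inside the Poisson log-pmf (with the log-rate capped
at ±30) keeps all-zero groups finite: a degenerate group's intercept
drifts to the cap instead of crashing. Groups are relabeled ascending by
mean rate over the observed age grid, so "low < medium < high" is a
guaranteed output convention and odds ratios are always reported against
the low group. Standard errors come from the observed information matrix,
obtained by central finite differences of the analytic score with a 1e-8
ridge before inversion; Wald tests use the normal approximation.

## Model selection and adequacy

BIC = −2·loglik + k·ln(n). The default n is the number of **persons**:
persons are the independent units of the mixture likelihood. Because the
alternative convention (person-period observations) is also defensible,
both are computed on every fit and the selection grid can rank by either.
Grid ties resolve to the smaller J, then the lower total basis order,
then grid position. Diagnostics follow standard GBTM practice: estimated
membership probabilities should track assigned shares, and AvePP (mean
posterior among persons assigned to a group) should exceed 0.7; the odds
of correct classification are reported alongside.

## The synthetic generator and its calibration

Real panels of this kind are restricted-access, so the generator is a
first-class module reproducing their structure. The calibrated default
(`default_study_spec`) encodes:

* **Trajectories** — cubic log-rate curves interpolated through landmark
  (age, rate) pairs at ages 10/19/25/30: peaks of 0.02, 0.35, and 1.44 at
  age 19 for the low/medium/high groups, the high group declining to 0.55
  by age 30. This is calibration to published curve landmarks, not
  estimation; the implied full curves are what the recovery tests target.
* **Cohorts** — four birth cohorts observed over unbalanced windows
  (10–25, 10–33, 17–33, 17–33), matching an analysis truncated at age 33.
  The younger cohort's share (0.3125) solves the mixing identity that
  makes the marginal low-group share 0.787 given the younger-cohort
  (0.877) and implied older-cohort (≈0.746) low-group probabilities;
  the remainder splits evenly across the three older cohorts.
* **Membership** — logit coefficients for the older-cohort indicator are
  the published odds ratios (2.972 medium vs low, 1.575 high vs low);
  effects for sex (+0.8/+1.2), TANF (+0.45) and self-control (−0.40 per
  SD) are chosen so the implied low-group profile contrasts sit near the
  published 0.073 (TANF) and 0.126 (±1 SD self-control). Intercepts are
  then solved numerically (Gauss–Hermite × binary-cell quadrature over
  the covariate distribution) so the covariate-averaged younger-cohort
  membership equals (0.877, 0.086, 0.037).
* **Charges** — per-arrest independent category inclusions
  (drugs/violence/property/other, "other" forced when none fires), with
  probabilities set to published offense-to-total rate ratios per group ×
  cohort class; the older high group's drug inclusion (0.336) is well
  above the younger's (0.157).
* **Rate multipliers** — an optional per-(group, cohort-class) multiplier
  on λ_j emulates within-group cohort differences in intensity. The
  default spec leaves all multipliers at 1, so its data-generating law is
  exactly the fitted model family; tests of the decomposition's
  within-group component construct multiplier variants explicitly.

What the generator does **not** emulate: attrition and out-of-state
migration, period (calendar-year) effects, measurement error between
offending and arrest, day-level arrest timing, or the covariance
structure of a full risk-factor battery (three covariates plus cohort
stand in for it). Passing recovery tests therefore demonstrate that the
estimator recovers the truth *when the model family is correctly
specified and membership is exogenous* — not that the model is correct
for any real population.

## Rate tables, decomposition, permutation test

Rate tables are per-(group, cohort) mean counts per person over a stated
window (default 17–24, the common-support ages); persons without full
window coverage are excluded with a logged count. Shares and rates feed
the decomposition as **hard assignments** (maximum posterior), matching
how such tables are conventionally built and guaranteeing the additive
identity share·rate = pooled mean exactly; a posterior-weighted variant
is available via the shares you pass in. The decomposition reports the
rate swap (own shares, other cohort's rates), the composition swap
(other cohort's shares, own rates), and targeted single-group swaps,
each also as a percent difference from the actual rate. Published
rounded inputs reproduce the composition-swap counterfactual to ~0.4%;
two other printed counterfactuals are rounding-limited (reconstructions
0.753 vs 0.774 and 0.707 vs 0.725) and are not treated as exact targets.

The significance of a within-group cohort contrast is assessed by a
two-sided permutation test on person-level window totals (cohort labels
permuted within the group; p = (1+#{|perm| ≥ |obs|})/(n_perm+1)). The
choice of test is this package's own — the emulated analyses do not
state theirs — and is labeled as such here.

Multiply imputed covariate tables are handled by fitting per imputation
and pooling with Rubin's rules (mean estimate; within + (1+1/m)·between
variance; Rubin degrees of freedom). The package pools; it does not
generate imputations.

## Profile probabilities

Predicted membership at a covariate profile uses the
average-predicted-probability convention by default: the focal covariates
are overridden for every sample member and the softmax is averaged, so
unset covariates keep their observed joint distribution. `at_means=True`
switches to the representative-profile convention. Neither is asserted
as "the" published method; both are exposed because the source of the
published profile figures is ambiguous.

## Problem sizes and numerical conventions in the test suite

Recovery and diagnostic tests simulate n = 1000 persons (≈18,000
person-ages) with 3 fitting starts; the covariate/odds-ratio checks use
n = 2000; selection-consistency runs 10 replicates of a J ∈ {2,3,4} grid
at n = 1000 with 2 starts; the permutation-calibration check uses 200
replicates of 60 persons with 299 permutations. These sizes were chosen
as the smallest at which the Monte-Carlo tolerances used (±0.03 on
shares, 10% on peak rates, KS < 0.1) are comfortably informative.
Exact-arithmetic assertions use 1e-10–1e-12 tolerances; oracle agreement
for the J=1 Poisson regression is required to 1e-6 in coefficients
against an independent IRLS implementation.

## Known limitations

* No zero-inflated or overdispersed count families; within-group
  heterogeneity beyond the cohort multiplier is out of scope, as are
  random effects and joint (dual-outcome) trajectories.
* Membership covariates are baseline-only; time-varying covariates do
  not enter either the logit or the rates.
* The observed-information SEs ignore classification uncertainty
  corrections beyond the joint likelihood itself and are not
  design-adjusted for complex sampling.
* The drug-only arrest filter works on per-age aggregates: it bounds the
  number of arrests carrying a non-drug charge by the sum of non-drug
  category counts, which is conservative when non-drug categories
  co-occur on one arrest.
* BIC selection with few high-group members (marginal share 0.045) is
  only reliable at several hundred persons and degrades below that.
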