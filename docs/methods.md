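# Methods

## Model and estimators

Observations (xᵢ, yᵢ), i = 1..N, with yᵢ ∈ {0, 1} and K covariates, follow
the logistic model logit πᵢ = β₀ + β₁xᵢ₁ + … + β_K xᵢ_K. The estimand
throughout is β₁, the coefficient of an unbalanced binary exposure.

Both estimators are exactly equivariant under affine reparametrization of
the covariates, so all fits run internally on centered, unit-variance
columns (critical for Newton conditioning when covariate scales span three
orders of magnitude) and map the coefficients, covariance and penalized
likelihood back to the raw scale afterwards. Newton steps are capped at 5
per component on the standardized scale to prevent overshoot on flat
likelihoods.

**Maximum likelihood** is fit by Newton–Raphson with step-halving on the
log-likelihood. Because the ML estimate does not exist under separation, the
separation check runs first and a separated dataset is reported as
`estimate_exists=False` rather than iterated to a pseudo-solution. On
nearly separated data the optimum can be numerically flat — the score
vanishes while the Newton step direction is noise — so convergence is also
accepted when the score is at tolerance and the likelihood has stalled. The
observed information equals the expected information X'WX (canonical link),
and 95% Wald intervals use z = 1.959964.

**Firth's correction** maximizes the Jeffreys-penalized likelihood
l*(β) = l(β) + ½ log det X'W(β)X via modified-score iterations: the score
contribution of observation i is (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢ with hᵢ the hat
diagonal of W^{1/2}X(X'WX)^{-1}X'W^{1/2}, with Newton steps, step-halving on
l*, and optional per-row weights (used for grouped/tabular data).
Convergence requires max |score| < 1e-6 and max |Δβ| < 1e-6 within 250
iterations (up to 10 halvings per step; the modified-score iteration
converges linearly, and near-degenerate fits — e.g. eight events against
eleven parameters — can legitimately need over a hundred). A trial step that
drives all
fitted probabilities to 0/1 makes X'WX numerically singular; such a state
has l* = −∞ and is treated as a rejected step, not an error.

**Profile penalized-likelihood CIs** for coefficient j solve
2(l*(β̂) − l*_profile(β_j)) = χ²₁(level), where the profile maximizes l*
over the other coefficients at fixed β_j (same modified-score iteration
restricted to the free coordinates, hat values and penalty from the full
model). Endpoints are bracketed outward from β̂_j in doubling steps scaled
by the Wald SE and solved by Brent's method (xtol 1e-6); evaluations are
memoized per offset because the nuisance maximizations warm-start from the
nearest solved profile point. If no sign change occurs within ±50 on the
logit scale the side is reported as unbounded and flagged — with an
intercept in the model this does not occur in practice. A fixed β_j so
extreme that the profile model degenerates is treated as lying beyond the
confidence limit.

**2×2 closed forms**: β̂_ML = log(f00·f11 / (f01·f10)) (undefined with any
zero cell), and Firth's estimate equals the same formula on counts + 0.5.
These serve as oracles for the iterative fits in the tests.

## Separation detection

A coefficient vector b (intercept included) weakly separates when
(2yᵢ − 1)(b·[1, xᵢ]) ≥ 0 for all i, with strict inequality somewhere;
complete separation requires strict inequality everywhere. Detection solves
a linear program: maximize the total slack subject to all slacks ≥ 0 and
box constraints |b_j| ≤ 1 (HiGHS); a positive optimum (max slack > 1e-6,
feasibility tolerance 1e-8) means separated. A second LP maximizing the
minimum slack distinguishes complete from quasi-complete; callers that only
need the yes/no decision (the escalation loop, the ML existence check) skip
it. Covariates are centered and max-abs scaled before the LP — the decision
is invariant to affine rescaling, which is also tested. Datasets with one
outcome level are completely separated by the intercept alone. A dense
direction-grid search (`brute_force_separation`) provides an independent
oracle on tiny problems; for binary covariates with grid step 0.25 it is
exact, because the vertices of the LP feasibility polytope then have
half-integer coordinates.

## Data-generating scheme

Ten latent standard-normal variables with a sparse correlation matrix Σ (14
nonzero pairs, e.g. corr(z₁, z₂) = 0.6; smallest eigenvalue 0.0286) are
transformed into: four binary covariates (indicators such as x₁ = I(z₁ <
0.84), giving the unbalanced exposure with E(x₁) = 0.8), two three-level
ordinal covariates (double indicators), and four continuous covariates — two
age-like (⌊10z + 55⌋) and two skewed lab-value-like (max(0, ⌊100eᶻ⌋ − 20)
and max(0, ⌊80eᶻ⌋ − 20)). Continuous covariates are truncated at
Q3 + 5·IQR of their marginal distribution. The floors make these marginals
integer-valued with closed-form CDFs, so the truncation caps
{x₇: 126, x₈: 906, x₉: 722, x₁₀: 126} are frozen from exact discrete
quantiles rather than sampled ones (x₉'s Q3 sits on a CDF jump,
P(x₉ ≤ 136) = 0.74998, where sampled quantiles are unstable); a Monte-Carlo
quantile oracle cross-checks them in the tests. Truncation touches only the
upper tail: ≈1.29% of x₈'s mass and ≈1.31% of x₉'s, and none of x₇/x₁₀'s
(their caps lie beyond ±7 latent standard deviations).

Nuisance effects are fixed: log 2 for binary, log √2 for ordinal covariates;
for continuous covariates the effect is calibrated so the log odds ratio
between the 1st and 5th sextile of the (truncated) covariate distribution is
log 2, i.e. β_k = log 2 / (q₅/₆ − q₁/₆) with exact sextile spans
{19, 225, 180, 19}. For K < 10, covariates x₁..x_K enter in scheme order
(x₁ is always the exposure); all ten latent variables are always drawn from
the full Σ and the unused columns discarded, so the exposure's joint
distribution with the retained confounders is identical across K. The
intercept is calibrated per (K, E(Y), β₁) by root-finding
mean(expit(β₀ + Xβ)) = E(Y) on a fixed calibration sample of 10⁶ covariate
draws (internal seed, shared across scenarios; tolerance 1e-4 on the event
rate). Outcomes are Bernoulli(πᵢ).

## The escalation loop (ISS)

When the original sample of size N is separated, observations are appended
one at a time from the same generating distribution until the detector
clears; the returned N_new is minimal on the sampling path. For efficiency
the loop caches the current separating direction: a new row weakly
consistent with it provably leaves the data separated (the previously
strict rows stay strict), so the LP is re-solved only when the new row
violates the cached direction. Rows are drawn from the replication's stream
in blocks of 64 for vectorization; the check itself remains per-observation.
A configurable batch size > 1 checks less often and then backtracks to the
smallest non-separated prefix. The loop aborts (and the replication is
excluded, counted, and surfaced — never silently dropped) at 100·N; the
worst observed mean inflation is ≈ 12·N, so the cap flags pathology without
truncating valid runs. Within a replication ML+ISS and FC+ISS share the
escalated dataset, so strategy contrasts are paired.

## Study design and measures

Full factorial: K ∈ {2, 5, 10} × N ∈ {80, 200, 500} × E(Y) ∈ {0.1, 0.25} ×
β₁ ∈ {0, 0.35, 1.39, 2.77} — 72 cells. Per replication: sample, detect,
run FC (profile CI), ML+ISS (Wald CI) and FC+ISS (profile CI); per cell:
bias, MSE, empirical coverage of the true β₁, rejection rate (the 95% CI
excluding 0 — type-I error when β₁ = 0, power otherwise), mean CI width,
mean N̄new, separation prevalence, and CARE = (MSE_ML+ISS · N̄new)/(MSE_FC · N).
Aggregates are unweighted means over scenario cells, never pooled
replications. The plausible interval for empirical coverage is
0.95 ± 2.57·√(0.95·0.05/n_reps). Every replication r of a cell draws from
`SeedSequence(master_seed, spawn_key=(K, N, E(Y), β₁, r))`, so runs are
deterministic, order-independent, and reproducible in isolation; the ISS
extension consumes the same stream.

## Problem sizes

The package defaults to 1000 replications per cell. The shipped study runs
(tests and `scripts/acceptance.py`) use 200 replications for the 18 null
cells and 150 elsewhere — enough that scenario-mean type-I error, power,
coverage and width are stable to a few tenths of a percentage point (the
per-cell binomial SE at 150–200 replications is 1.5–1.8 points; averaging 9–36
cells reduces it ~3–6-fold), while a full desk run stays in the minutes
range. Test tolerances reflect this: ±1.5 points on null rejection and
coverage means, ±5 points on power means, and a lower bound (> 5×) plus
location check on the peak N̄new/N ratio, whose per-cell distribution is
heavy-tailed.

## What the generator does and does not emulate

The scheme produces realistic marginals (unbalanced exposure, skewed
truncated lab values, correlated confounders) and event rates typical of
epidemiological cohorts, and it guarantees the population itself is never
separable (all πᵢ ∈ (0, 1)), which is what makes ISS terminate with
probability 1. It does not emulate measurement error, missing data,
model misspecification (the analysis model always matches the generating
model), clustered sampling, or covariate-dependent escalation costs.
Conclusions from passing tests therefore speak to separation as a sampling
artefact under a correctly specified model, not to robustness beyond it.

## Known limitations

* Only models with an intercept; no multinomial/ordinal outcomes, weights in
  the study pipeline, or alternative penalties (intercept-corrected or
  augmented-likelihood variants, log-F or Cauchy priors).
* The complete/quasi-complete label near numerical ties is taken from the LP
  at the stated tolerances; borderline rows within ~1e-8 of a separating
  hyperplane are classified by those tolerances.
* `brute_force_separation` is exact only for binary covariates; for general
  data it is a heuristic cross-check.
* CARE compares ML+ISS with FC only, mirroring the study's definition.
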