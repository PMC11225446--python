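# Methods

## Model and likelihood

Each patient *i* contributes two longitudinal outcome series: a CD4
T-lymphocyte count $Y^{(1)}_{ij}$ (cells/mm³) and a binary TB screening
result $Y^{(2)}_{ij}$, observed at integer visit indices $j = 1..10$. The
joint model couples the two through one latent subject effect:

* $b_i \sim N(0, \sigma_b^2)$;
* count channel: $Y^{(1)}_{ij} \mid b_i \sim \mathrm{Poisson}(\mu_{ij})$,
  $\log \mu_{ij} = x_{ij}^\top \beta_1 + b_i$ (loading fixed at 1);
* binary channel: $Y^{(2)}_{ij} \mid b_i \sim \mathrm{Bernoulli}(p_{ij})$,
  $\operatorname{logit} p_{ij} = x_{ij}^\top \beta_2 + \lambda b_i$.

Given $b_i$, all of a subject's rows are independent, so the marginal
likelihood is a product over subjects of one-dimensional integrals

$$L_i(\theta) = \int \Big[\prod_j f_1(y^{(1)}_{ij} \mid b)\Big]
\Big[\prod_j f_2(y^{(2)}_{ij} \mid b)\Big]\, \phi(b; 0, \sigma_b^2)\, db .$$

Conditional independence implies the marginal cross-outcome covariance
equals the covariance of the two conditional means — the generator test
suite verifies exactly this identity empirically.

Two structural alternatives are exposed because the literature on this
cohort is ambiguous about them:

* **Count family.** `count_family="gaussian-log"` replaces the Poisson
  channel by a Gaussian model of $\log(1+\mathrm{CD4})$ with residual SD
  $\sigma_e$ (some analyses log-transform CD4 to meet normality
  assumptions instead of modelling the count). Poisson is the default.
* **Random structure.** `shared_intercept` (default) has one variance
  $\sigma_b^2$ and a binary-channel loading $\lambda$ (free or fixed; fixed
  at 1 reproduces a single-variance-component model). A
  `correlated_intercepts` variant gives each channel its own intercept
  with a free 2×2 covariance; it uses the same machinery in two
  dimensions.

## Estimation

The integral is approximated per subject by **adaptive Gauss–Hermite
quadrature**: the integrand's mode $\hat b_i$ is found by a vectorised,
damped Newton iteration (the per-subject objective is strictly concave
for all supported families, so the mode is unique and the warm-start
cache used between likelihood evaluations cannot change results); nodes
are recentred at $\hat b_i$ and rescaled by the curvature there.
**Laplace** is the one-node special case and the default. For the
correlated-intercepts structure the quadrature grid is the tensor product
over a per-subject Cholesky transform. AGQ with 51 nodes agrees with
brute-force trapezoid integration (8σ span, 40k grid points) to 1e-6 on
the test fixtures; node refinement 5→11→21→51 is monotone with
|agq(21) − agq(51)| < 1e-6.

The marginal log-likelihood is maximised by BFGS on a transformed scale
($\log\sigma_b$, $\log\sigma_e$, $\operatorname{atanh}\rho$), with
channel-wise GLM fits as starting values (σ_b starts at 0.3) and
finite-difference gradients. Standard errors come from the inverse of a
central-difference observed information matrix; variance-parameter SEs are
delta-method transforms of the log-scale SEs. Wald z and normal-reference
p-values; no small-sample df correction.

**Convergence.** BFGS frequently terminates with "precision loss" at what
is numerically the optimum of an $O(10^4)$ objective, because an absolute
gradient-norm threshold is not meaningful at that scale with
finite-difference gradients. A fit is therefore declared converged when
the optimizer succeeds *or* the Newton decrement
$\tfrac12 g^\top H^{-1} g$ (the expected remaining improvement in
log-likelihood units) is below 1e-4. Non-convergence is flagged on the
result, never raised; a boundary estimate $\hat\sigma_b < 10^{-3}$ is
flagged and its SE reported as missing rather than fabricated. Binary
channels that are all-0 or all-1 are rejected explicitly (no silent
separation handling). Trial parameters that overflow the Poisson mean are
capped inside `exp` (linear predictor ≤ 40) so line searches receive
finite penalties rather than NaNs.

**Laplace vs AGQ accuracy.** With CD4-scale counts the posterior of $b_i$
is extremely concentrated, so Laplace is accurate to well below 1e-3 on
count-channel coefficients; for binary-channel coefficients it carries a
small genuine bias (~0.2% relative at $\sigma_b = 0.4$). Use
`method="agq"` when third-decimal accuracy of logistic coefficients
matters.

**Dispersion.** The Pearson generalized chi-square
$\sum (y-\hat\mu)^2 / V(\hat\mu)$, with $\hat\mu$ conditional on the
posterior modes and df = stacked rows − fixed parameters, is reported as
chi-square/df. It is near 1 for well-specified simulations, and far above
1 when Poisson is fitted to negative-binomial counts. By default SEs are
*not* rescaled by dispersion (`scale_se_by_dispersion` opts in).

## Data model

A cohort is a long-format patient-visit table with a fixed schema
(identifiers, the two outcomes, and 14 socio-demographic/clinical
covariates with integer-coded categorical levels). TB status is stored
0/1 with 1 = positive; source files coded 1 = negative / 2 = positive are
recoded on read via the schema map (`tb_coding`). Opportunistic-infection
status is stored 0 = no / 1 = yes with both common source codings
supported (`oi_coding`), because published tables for this cohort use both;
the schema map makes the choice explicit rather than assumed. Dummy
coding drops the **last** categorical code, matching the convention of
clinical tables where the last listed level is the zero reference; OI's
internal level order is (1, 0) so "no" is the reference and the reported
effect is yes-vs-no. Stacking emits up to two rows per visit; a visit
with exactly one observed outcome contributes only that channel (the
likelihood factorises over observed rows given $b_i$), and covariate
missingness is the imputation module's job.

## Synthetic cohorts

The generator realises exactly the model above, so every downstream stage
is testable without external data. Defaults emulate the target cohort:
1,400 patients, up to 10 visits with per-visit retention 0.9 (geometric
dropout), categorical marginals from the published baseline table's count
totals, truncated-normal continuous marginals with the published
mean/SD/min/max (weight N(57.3, 10.4) on [24.9, 88] kg; hemoglobin uses
the published — physiologically implausible but faithful — N(30.3, 83.8)
on [9.1, 888] g/dl), σ_b = √0.1166 ≈ 0.3415, binary-channel effects
OI = 1.798, weight = log 1.14, hemoglobin = log 1.05, and channel
intercepts 5.30 / −7.8 calibrated once so the simulated marginal CD4 mean
(≈396) and TB-positive fraction (≈0.87) match the published summaries.
The regimen distribution is not published; a TDF-3TC-EFV-dominant mix was
chosen as typical of the study period. Weight and hemoglobin drift as
per-visit random walks (SD 0.5 kg and 1 g/dl); all other covariates are
time-constant. Optional switches generate Gaussian-log counts or
negative-binomial overdispersion (Gamma(k, 1/k) frailty on the Poisson
rate) for misspecification studies. Missingness injection supports MCAR
(i.i.d. cell blanking) and a simple MAR mechanism whose cell-blanking
probability depends on observed TB status (weight/hemoglobin; ×1.5 for
TB-positive vs ×0.5) or on the visit index, normalised to the nominal
rate.

What the generator does *not* emulate: the real covariates' joint
dependence (marginals are independent), irregular calendar visit times,
informative dropout, or measurement error in CD4. Passing recovery tests
therefore demonstrate correctness of the estimator under the model's own
assumptions, not robustness to their violation.

## Multiple imputation

Chained equations over the incomplete columns, three sweeps: continuous
columns by Bayesian linear regression on the complete predictor pool
(residual variance drawn from its scaled inverse-χ² posterior,
coefficients from their normal posterior, plus residual noise — so the
between-imputation variance is honest); a binary outcome by a logistic
working model with a normal posterior draw of its coefficients.
Predictive-mean matching is deliberately not implemented; the scheme is
the simplest defensible one and is isolated behind `multiple_impute` so it
can be swapped. m defaults to 5. Imputation runs on the long table before
stacking so both channels share one completed covariate. Pooling follows
Rubin's rules, with df = (m−1)(1 + W/((1+1/m)B))², infinite df and a
normal reference when B = 0.

## Descriptives

Cross-tabs are computed at the patient level using the first visit
(baseline-table convention) with a `per_visit` switch, cells as
percentages of all counted patients, rounded half away from zero to one
decimal — the rounding convention under which the published self-consistent
cells reproduce exactly. Continuous summaries use the sample SD (n−1).
Trajectory series return plot-ready tables (per-patient profiles,
per-visit mean CD4 and TB-positive fraction); rendering is optional.

## Problem sizes in the test suite

Oracle and closed-form checks run on 3–100-subject fixtures. The
parameter-recovery study uses 100 replicates of 300 patients × 5 visits at
the anchored truth (σ_b = 0.3415, OI effect 1.798, λ = 1), asserting ≥90%
Wald coverage per parameter and coefficient bias below 10%. The recovery
truth uses a balanced OI prevalence (0.35) and intercepts giving ~50%
TB prevalence: at the cohort's 3.5% OI prevalence a 300-patient replicate
has ~10 exposed patients and frequently quasi-separates, which stresses
the optimizer rather than measuring estimator calibration. Cross-checks
against an independent mixed-model implementation (lme4's `glmer`,
nAGQ = 25) agree to ~1e-4 on coefficients and SEs.

## Known limitations

* No within-channel serial correlation beyond the random intercept, no
  random slopes, no Bayesian estimation, no GEE.
* Laplace (the default) slightly biases binary-channel estimates at
  moderate σ_b; AGQ is the remedy.
* The pseudo-likelihood linearization used by some commercial mixed-model
  software is not implemented; −2 log-likelihood is reported instead of
  a pseudo-likelihood criterion, so those criteria are not comparable
  across software.
* The imputation model assumes the continuous columns are conditionally
  Gaussian; heavy-tailed labs are imputed only approximately.
* MNAR sensitivity analysis is out of scope.
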