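# jointglmm

Joint modelling of two correlated longitudinal outcomes from an HIV/ART
cohort — a CD4 cell count (cells/mm³, a count) and a tuberculosis screening
result (positive/negative, binary) — with a **mixed-family generalized
linear mixed model sharing one subject random intercept**, plus the
surrounding analysis pipeline: cohort schema and validation, a synthetic
cohort generator, descriptive tables, multiple imputation with Rubin's-rules
pooling, and odds-scale effect reporting. It is written for
biostatisticians and epidemiologists who analyse paired longitudinal
outcomes and want a likelihood-based joint fit they can test.

## Model

For patient *i* at visit *j* with covariates $x_{ij}$ and a latent subject
effect $b_i \sim N(0,\sigma_b^2)$:

$$Y^{(1)}_{ij} \mid b_i \sim \mathrm{Poisson}\!\left(e^{x_{ij}^\top\beta_1 + b_i}\right),\qquad
Y^{(2)}_{ij} \mid b_i \sim \mathrm{Bernoulli}\!\left(\operatorname{logit}^{-1}(x_{ij}^\top\beta_2 + \lambda b_i)\right)$$

The two channels are conditionally independent given $b_i$; the shared
intercept induces all cross-outcome correlation, and the marginal
covariance of the two outcomes equals the covariance of their conditional
means. The data are prepared by *stacking*: each complete patient-visit
becomes two rows, one per channel, with a `channel` indicator naming the
conditional family. The marginal likelihood integrates $b_i$ out per
subject; the engine evaluates that integral by the Laplace approximation
or by adaptive Gauss–Hermite quadrature (nodes recentred at each subject's
posterior mode), maximises it by quasi-Newton, and reports Wald standard
errors from the observed information plus the Pearson generalized
chi-square/df dispersion diagnostic. An alternative Gaussian-on-log(CD4)
count channel and a correlated-two-intercepts random structure are
available behind config switches.

## Worked example

```python
from jointglmm import (default_truth, simulate_cohort, stack_bivariate,
                       ModelSpec, fit_glmm, fit_statistics, effect_transforms)

truth = default_truth(seed=1)          # 1,400 patients, up to 10 visits
cohort, truth = simulate_cohort(truth) # long-format patient-visit table
stacked = stack_bivariate(cohort)      # two rows per complete visit
spec = ModelSpec(count_terms=("visit", "weight", "hemoglobin"),
                 binary_terms=("oi_status", "weight", "hemoglobin"))
fit = fit_glmm(stacked, spec)
print(fit.coef.round(4))
print(fit.random_effects)
print(fit_statistics(fit, stacked, spec))
print(effect_transforms(fit).table[["term", "or", "headline"]].round(3))
```

prints (abridged):

```
channel         term  estimate     se        z   p
  count        visit    0.0181 0.0002  86.0126 0.0
  count       weight    0.0032 0.0006   5.0609 0.0
  count   hemoglobin    0.0041 0.0002  26.8030 0.0
 binary oi_status[1]    1.3030 0.2966   4.3935 0.0
 binary       weight    0.1311 0.0047  27.9225 0.0
 binary   hemoglobin    0.0487 0.0016  29.8474 0.0
sigma_b^2 = 0.1169 +/- 0.0045
-2 log L = 92998.14   chi2/df = 0.942
        term   or               headline
oi_status[1] 3.68 2.68 times more likely
      weight 1.14 0.14 times more likely
  hemoglobin 1.05 0.05 times more likely
```

Reading: the generator's ground truth set the random-intercept variance to
0.1166 and per-unit TB log-odds effects of log(1.14) for weight (kg) and
log(1.05) for hemoglobin (g/dl); the fit recovers all of them (σ̂_b² =
0.1169; weight OR 1.14; hemoglobin OR 1.05). `chi2/df` near 1 says the
Poisson/Bernoulli dispersion assumptions match this data; fitting the same
model to overdispersed (negative-binomial) counts drives it far above 1.
A positive log-odds effect β is headlined as `exp(β) − 1` "times more
likely", a negative one as `(1 − exp(β))·100` "% less likely".

The same pipeline is scriptable from the shell:

```bash
jointglmm simulate --seed 42 --out cohort.csv --truth-out truth.json
jointglmm describe --data cohort.csv --out-dir desc/
jointglmm fit --data cohort.csv --method agq --nodes 21 --out fit.json
jointglmm report --fit fit.json --out effects.tsv
jointglmm pipeline --config pipeline.yaml --out-dir results/
```

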