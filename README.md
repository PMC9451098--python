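# metarelapse

Mechanistic analysis of **distant metastasis-free survival (DMFS)** curves.

DMFS curves are usually analyzed with the Kaplan–Meier estimator, log-rank
tests or Cox regression — methods that quantify *association* but say
nothing about *which biological process* (tumor growth or metastatic
dissemination) a prognostic marker acts on.  `metarelapse` implements a
mechanistic alternative aimed at biostatisticians and computational
oncologists: a model of primary-tumor growth and metastatic seeding whose
population parameters, and covariate effects on them, are estimated directly
from a DMFS curve.

## The model

Each patient's primary tumor grows from one cell with Gompertz kinetics

$$V(t) = \exp\!\Big(\tfrac{\alpha}{\beta}\big(1 - e^{-\beta t}\big)\Big),
\qquad K = e^{\alpha/\beta} = 10^{12}\ \text{cells},$$

where α (day⁻¹) is the specific growth rate at one cell.  Cells disseminate
at rate $d(t) = \mu V(t)$ (μ in cell⁻¹ day⁻¹), so the expected number of
metastases seeded by time $t$ is $N(t) = \mu \int_0^t V(s)\,ds$.  A
metastasis becomes visible after growing to a 5 mm sphere; the primary is
diagnosed and resected at volume $V_{diag}$.  The **time to relapse** is the
first post-diagnosis time a seeded metastasis becomes visible, $+\infty$ if
$N(t_{diag}) < 1$ (cure), and patients with a visible metastasis already at
diagnosis are counted in a separate fraction $m_{diag}$.

Across patients, $\log\alpha^i$ and $\log\mu^i$ are normal with means
$\log\alpha_{pop}, \log\mu_{pop}$ and SDs $\omega_\alpha, \omega_\mu$, and
$V_{diag}$ is lognormal.  The population survival function $S(t;\Theta)$ is
evaluated semi-analytically (the μ dimension integrates exactly through the
lognormal CDF; see `docs/methods.md`), and parameters are estimated by
Nelder–Mead least squares between $S(t;\Theta)$ and the empirical curve,
optionally anchored by the observed metastatic-at-diagnosis percentage $M$:

$$\hat\Theta = \arg\min_\Theta \sum_j (S_j - S(t_j;\Theta))^2
  + \big((M - m_{diag}(\Theta))\lambda\big)^2 .$$

Covariates enter as shifts of $\log\alpha_{pop}$ or $\log\mu_{pop}$ —
categorical ($b_k|\log \cdot|$ per level), threshold, linear, or
threshold-then-linear — and a multi-threshold objective (dichotomizing the
cohort at the 15th–85th covariate percentiles) identifies both the
functional form and the target process.  Replicate simulation–estimation
studies quantify practical identifiability by the relative standard error
$\mathrm{RSE} = 100\sqrt{\tfrac1K\sum_k(\theta^*-\hat\theta_k)^2}/\theta^*$.

## Worked example

Simulate a 1000-patient cohort with a categorical covariate acting on growth
(b = 0.3), recover the coefficient, and test the group difference:

```python
import numpy as np
from metarelapse import (
    PopulationParams, CovariateEffect, CovariateDistribution,
    simulate_cohort, FitSpec, fit_parameters, model_survival, log_rank,
)

pop = PopulationParams()  # alpha_pop = 0.005/day, mu_pop = 7e-12/cell/day
effect = CovariateEffect(covariate="group", target="alpha",
                         form="categorical", b_k={2: 0.3})
cohort = simulate_cohort(
    pop, [effect],
    {"group": CovariateDistribution(family="bernoulli", params={"p": 0.5})},
    n=1000, rng_seed=7,
)
print(f"events: {cohort.event.mean():.1%}, "
      f"metastatic at diagnosis: {cohort.mets_at_diag.mean():.1%}")

spec = FitSpec(free={"b_2": (0.2, 0.4)}, pop=pop, effect=effect, objective="ss")
result = fit_parameters(spec, cohort, rng_seed=1)
print(f"b_hat = {result.estimates['b_2']:.3f} (true 0.3), fval = {result.fval:.3f}")

g1, g2 = (cohort[(cohort.group == k) & (cohort.mets_at_diag == 0)] for k in (1, 2))
stat, p = log_rank(g1.time, g1.event, g2.time, g2.event)
print(f"log-rank between groups: chi2 = {stat:.1f}, p = {p:.2e}")

curve = model_survival(pop, time_grid=np.array([0.0, 1000.0, 2000.0, 4000.0]))
print("model S(t):", np.round(curve.survival, 3), f" m_diag = {curve.m_diag:.3f}")
```

Output:

```
events: 51.7%, metastatic at diagnosis: 29.5%
b_hat = 0.313 (true 0.3), fval = 0.116
log-rank between groups: chi2 = 70.5, p = 4.62e-17
model S(t): [1.    0.728 0.526 0.311]  m_diag = 0.325
```

The fitted coefficient lands within single-cohort sampling noise of the
truth; the baseline model curve shows ~31% of non-metastatic patients
relapse-free at 11 years and a 32.5% metastatic-at-diagnosis fraction under
the base parameters.

A `metarelapse` CLI wraps the same functionality
(`simulate | fit | select-covariate | identify | scan-significance |
calibrate-alpha`); each subcommand takes a JSON/YAML config, a `--seed`, and
writes JSON/CSV results.

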