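# psbart

Bayesian principal stratification with mixed-effects BART for two-arm
cluster-randomized trials (CRTs) whose quality-of-life outcome is
**truncated by death**.

## The problem

In pragmatic trials of older adults — the motivating design is a
~1,200-participant telecare trial randomized at the general-practice level —
some participants do not survive to the follow-up assessment.  Their
quality-of-life outcome is not merely missing, it is *undefined*: comparing
the survivors of each arm compares different subpopulations whenever
treatment affects survival.  The well-posed estimand conditions on the
**always-survivor** principal stratum, the individuals who would survive
under either assignment:

- **SACE** — survivor average causal effect:
  `E[Y(1) − Y(0) | G = 11]`
- **CSACE** — its covariate-conditional version:
  `E[Y(1) − Y(0) | X = x, G = 11]`, the object of interest when asking *who*
  benefits.

Stratum membership `G ∈ {00, 10, 11}` (never-survivor, protected,
always-survivor; the harmed stratum is excluded by monotonicity) is latent:
observed data identify it only for control survivors (11) and treated
non-survivors (00), leaving two mixtures.  The package resolves the
mixtures with a **nested-Probit membership model**

    p00 = 1 − Φ(mQ(x)),   p10 = Φ(mQ(x))(1 − Φ(mW(x))),   p11 = Φ(mQ(x))Φ(mW(x)),

arm-stratum Gaussian outcome models for the three cells where the outcome
exists, and — because linear models misspecify nonlinear effect surfaces —
**mixed-effects BART** mean functions: sums of shallow regression trees plus
a cluster random intercept, `m(x) = Σₖ gₖ(x) + bᵢ`, `bᵢ ~ N(0, σ²_b)`,
sampled by backfitting Metropolis–Hastings inside an outer Gibbs sampler.
Two layers of missingness (unrecorded survival status; missing outcomes
among recorded survivors) are handled by nested missing-at-random data
augmentation.  A fully conjugate linear mixed-model benchmark provides the
parametric comparator; mean functions are selectable per block, giving the
four engine variants **YBSB / YBSP / YPSB / YPSP** (Y = outcome model,
S = stratum model, B = BART, P = parametric).

Intended users: biostatisticians analysing CRTs with mortality-truncated
outcomes, and methodologists benchmarking principal-stratification
estimators.

## Worked example

Simulate one replicate of the built-in clustered design (200 practices of
6, nonlinear strata and outcome surfaces, ~16% mortality, nested-MAR
missingness), fit the fully nonparametric sampler, and evaluate against the
known truth:

```python
from psbart import (DgpConfig, SamplerConfig, generate_dataset, run_mcmc,
                    compute_metrics, summarize_csace)

data, truth = generate_dataset(DgpConfig(seed=102))
cfg = SamplerConfig(n_iter=2000, n_burn=1000, seed=102,
                    K_outcome=50, K_membership=50)
draws = run_mcmc(data, cfg)                      # YBSB engine by default

s = summarize_csace(draws)
print(f"SACE = {s.sace:.3f}  95% CrI [{s.sace_ci[0]:.3f}, {s.sace_ci[1]:.3f}]")
print("stratum proportions (00/10/11):", s.pi_mean.round(3))
m = compute_metrics(draws, truth, q=0.8)
print(m.as_dict())
```

Output from this exact configuration:

```
SACE = -0.259  95% CrI [-0.427, -0.067]
stratum proportions (00/10/11): [0.109 0.131 0.76 ]
{'PEHE': 0.632, 'AbsBias': 0.492, 'Regret': 0.116, 'Coverage': 0.936,
 'Power': 0.895, 'FDR': 0.037, 'N_G': 861}
```

Reading it: the posterior stratum composition (10.9% / 13.1% / 76.0%)
tracks the generating composition (10.7% / 10.6% / 78.7%), and the
posterior SACE of −0.26 (true value for this replicate: −0.32) correctly
signals a small average harm among always-survivors.  861 individuals have
posterior always-survivor probability ≥ 0.8; among them the
root-mean-squared error of the individual effect estimates (PEHE) is 0.63
outcome-SD units, 95% credible intervals cover the true effects for 93.6%
of them, and 89.5% of true always-survivors are correctly identified with
a 3.7% false discovery rate.  Longer chains sharpen the estimates (the
analysis default is 20,000 iterations with 10,000 burn-in).

Subgroup exploration among the likely always-survivors:

```python
from psbart import likely_always_survivors, fit_the_fit

members = likely_always_survivors(s, q=0.8)
tree = fit_the_fit(s, members, data.x, draws=draws,
                   covariate_names=data.covariate_names)
print(tree.describe())
```

which prints the subgroup tree, e.g. (first levels):

```
n=861  mean CSACE=-0.230  95% CrI [-0.408, -0.039]
  x2 <= -0.201: n=445  mean CSACE=0.036  95% CrI [-0.207, 0.269]
  x2 > -0.201: n=416  mean CSACE=-0.515  95% CrI [-0.734, -0.252]
```

Everything is also reachable from the CLI: `psbart simulate`, `psbart fit
--engine ybsb`, `psbart replicate`, each writing CSV/JSON artifacts plus a
run manifest.

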