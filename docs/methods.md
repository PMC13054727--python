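# Methods

`psbart` estimates survivor average causal effects in two-arm
cluster-randomized trials (CRTs) whose quality-of-life outcome is truncated
by death, using Bayesian principal stratification with flexible,
cluster-aware mean functions.  This note describes the model, the sampler,
the synthetic-data machinery and the numerical choices, in enough detail to
reproduce or audit any quantity the package computes.

## The estimand and why truncation needs special handling

Let $S_{ij}(z) \in \{0,1\}$ and $Y_{ij}(z)$ be potential survival and
outcome for individual $j$ in cluster $i$ under arm $z$.  When
$S_{ij}(z)=0$ the outcome is *undefined* (denoted $\star$) — not missing:
there is no quality-of-life value for someone who has died.  Comparing
treated and control survivors therefore compares different subpopulations.
Principal stratification classifies individuals by the joint pair
$(S_{ij}(1), S_{ij}(0))$: always-survivors (1,1), protected (1,0),
never-survivors (0,0); the harmed stratum (0,1) is excluded by the
monotonicity assumption $S_{ij}(1) \ge S_{ij}(0)$ and is unrepresentable in
the package's label type.  The causal contrast is well-defined only among
always-survivors:

$$\Delta_{\text{SACE}} = E[Y_{ij}(1) - Y_{ij}(0) \mid G_{ij} = 11], \qquad
  \Delta_{\text{CSACE}}(x) = E[Y_{ij}(1) - Y_{ij}(0) \mid X_{ij} = x,
  G_{ij} = 11].$$

Observed data identify labels for two cells (control survivors are 11;
treated non-survivors are 00) and leave two mixtures (treated survivors mix
{10, 11}; control non-survivors mix {10, 00}).

## Membership model

A nested-Probit construction drives membership.  Two independent latent
Gaussians with unit variance, $Q_{ij} \sim N(m_Q(x), 1)$ and
$W_{ij} \sim N(m_W(x), 1)$, define $G = 00$ if $Q \le 0$, $G = 10$ if
$Q > 0, W \le 0$, and $G = 11$ if $Q > 0, W > 0$, giving

$$p_{00} = 1 - \Phi(m_Q), \quad p_{10} = \Phi(m_Q)(1 - \Phi(m_W)), \quad
  p_{11} = \Phi(m_Q)\Phi(m_W).$$

Because the split rule constrains $W$ only within the survivor-capable
group, $W$ is drawn untruncated when $G = 00$, which preserves the correct
joint distribution.

## Outcome models

Arm-stratum Gaussian models exist exactly where the outcome is defined:
$(g,z) \in \{(11,1), (11,0), (10,1)\}$, each
$Y \sim N(m_{g,z}(x) + b^{(g,z)}_i, \sigma^2_{g,z})$ with its own cluster
random intercepts.  Requesting a density or an imputation for any other
cell raises an error; that guard is how truncation-by-death semantics are
enforced throughout.  Each $(g,z)$ model carries its own intercept set and
intercept variance: in a CRT every cluster is observed under one arm, so an
intercept shared across arms would be unidentified.

## Mixed-effects BART mean functions

Every mean function is, by default, a sum of $K$ shallow trees plus a
cluster random intercept

$$m(x_{ij}) = \sum_{k=1}^{K} g_k(x_{ij}; \mathcal{J}_k, \mathcal{M}_k)
  + b_i, \qquad b_i \sim N(0, \sigma_b^2).$$

Priors and sampling follow canonical BART practice:

- tree structure: a node at depth $d$ splits with probability
  $0.95\,(1+d)^{-2}$; split variables uniform; cutpoints uniform on a
  100-point quantile grid per covariate, fixed at model construction;
- leaf values $N(0, \sigma_\mu^2)$ with
  $\sigma_\mu = \text{range}(y) / (2k\sqrt{K})$ for Gaussian responses
  (centered) and $\sigma_\mu = 3/(k\sqrt{K})$ for probit latents, $k = 2$;
- structures move by Metropolis–Hastings GROW (0.25) / PRUNE (0.25) /
  CHANGE (0.50) proposals against the partial residual; because the
  (variable, cutpoint) proposal equals the uniform rule prior, those factors
  cancel and the acceptance ratio reduces to node-selection terms, the
  depth prior and the leaf-marginal likelihood ratio;
- minimum leaf size 5, for numerical stability in small stratum subsets;
- $\sigma^2 \sim \text{IG}(0.001, 0.001)$, updated conjugately in Gaussian
  mode and fixed at 1 in probit mode;
- $\sigma_b^2 \sim \text{IG}(1.5, 1.5\hat\lambda)$, the scalar reduction of
  an inverse-Wishart with 3 degrees of freedom, with data-based scale
  $\hat\lambda$ (a quarter of the response variance).

Tree counts default to $K = 200$ for Gaussian outcome models and $K = 50$
for the probit membership models (lower-signal surfaces).  The linear
engine replaces each tree sum with $x^\top\beta$,
$\beta \sim N(0, (0.01 I)^{-1})$, keeping the identical hierarchy; all its
full conditionals are conjugate, and the test suite verifies each one with
a Metropolis-ratio-equals-one check.  The four engine assemblies (BART or
linear, independently for outcome and membership blocks) are the
YBSB/YBSP/YPSB/YPSP variants compared in the simulation study.

## Missing data

Missingness is two-layered ("nested MAR"): recording of the survival
status may depend on arm and covariates; outcome missingness among recorded
survivors may additionally depend on observed survival.  Every row falls in
one of four patterns (complete survivor / death truncation /
survivor-outcome-missing / status-and-outcome-missing), and the sampler
treats the unrecorded quantities by data augmentation:

- unrecorded survival is *deterministic* given the current label and arm
  under monotonicity ($S = 1$ iff $G = 11$, or $G = 10$ and $z = 1$);
- missing outcomes of current survivors are drawn from their arm-stratum
  model; outcomes of current non-survivors are cleared, never imputed;
- survivors with missing outcomes use membership probabilities only in the
  label update — under the outcome-layer MAR assumption the missing
  outcome integrates out of the full conditional.

Missing *baseline covariates* are completed once, before sampling, by a
single mean/mode imputation with a stored mask (binary columns take the
mode, others the mean).  This is deliberately simpler than chained-equations
multiple imputation; with the low covariate missingness typical of the
target designs the approximation is secondary to the outcome/survival
augmentation, and the mask makes the imputed cells auditable.

## The Gibbs sampler

Each iteration updates, in fixed order: (i) the three outcome mean
functions on their current label subsets (observed plus currently imputed
outcomes — full data augmentation); (ii) their residual variances;
(iii) the membership mean functions regressed on the current latents;
(iv) the latent normals from truncated full conditionals given labels;
(v) labels from the pattern-specific full conditionals, which combine
membership probabilities with outcome likelihoods for treated survivors
with observed outcomes; and (vi) the missing data as above.  After (v) the
latents are refreshed under the new labels so that the next membership
regression conditions on a coherent state (the label draw marginalizes the
latents; redrawing them immediately is the standard partially-collapsed
ordering).

Initialization follows the identified cells (control survivors to 11,
treated non-survivors to 00), draws random admissible labels in the two
mixture cells, imputes unrecorded survival with a 20-sweep probit BART
classifier (logistic regression under the linear engine) thresholded at
0.5, seeds the membership means with probit-transformed logistic fits of
the initial labels, and warm-starts every mean model with 10 sweeps on its
initial subset.

Defaults are 20,000 iterations with 10,000 burn-in and no thinning; all
randomness flows from a single seeded generator, and identical data +
configuration + seed reproduce retained draws bitwise.

## Posterior summaries

Per draw, the package records labels, stratum proportions, the effect
surface $\tau(x) = m_{11,1}(x) - m_{11,0}(x)$ at every individual's
covariates, and the draw's SACE (the mean of $\tau$ over that draw's
always-survivors; a draw with no always-survivors is counted as degenerate
and skipped in SACE averaging).  $\tau$ deliberately excludes random
intercepts: the counterfactual arm's intercept is unidentified for a given
cluster, and the estimand conditions on covariates only.

Per-individual summaries (posterior mean, equal-tailed 95% credible
interval) average $\tau$ over **all** retained draws.  Conditioning on the
draws in which the individual is currently labelled 11 would select
iterations in which the outcome model happened to favor that individual's
own observed outcome — the label weights are $p_{11} f_{11,1}(y)$ — and
that feedback biases the estimate toward the individual's residual.
Individuals never labelled always-survivor in any retained draw are
reported as unavailable.  "Likely always-survivors" are individuals with
posterior membership probability $p^{(11)} \ge q$, default $q = 0.8$,
boundary included.

The exploratory fit-the-fit step regresses posterior-mean effects for the
likely always-survivors on baseline covariates with a shallow CART
(scikit-learn's exact greedy variance-reduction tree; depth 3, minimum leaf
20, no pruning).  Node credible intervals are posterior quantiles of the
node-average effect: each retained draw's $\tau$ averaged over the leaf's
members, then 2.5%/97.5% quantiles of that series.  Subgroups are
hypothesis-generating only; no multiplicity control is attempted.

## Synthetic data

Two generators are first-class, tested code:

**Simulation DGP** (`simulate.generate_dataset`): 200 clusters of 6, five
covariates (three standard normal, two Bernoulli(0.5)), cluster effects
$\sigma^2_{b,Q} = \sigma^2_{b,W} = 0.0204$, nonlinear latent means with
interactions and trigonometric terms, nonlinear outcome surfaces $f_{11},
\tau_{11}, f_{10}, \tau_{10}$, outcome noise $\sigma^2_{b,Y} = 0.02$,
$\sigma^2_{\varepsilon,Y} = 0.98$ (ICC $\approx 0.02$, marginal variance
$\approx 1$), balanced complete randomization, and logistic missingness
models for status recording and outcome response.  Under the defaults the
true composition averages ~10.7% never-survivors, ~10.6% protected and
~78.7% always-survivors, and the observed patterns ~13.5% both-missing,
~14.3% death truncation, ~67.7% complete survivors, ~4.4%
survivor-outcome-missing.  The protected-arm effect contains
$\log(0.5 + x_1 + 10^{-4})$, which is undefined for $x_1 \le -0.5001$; the
argument is clamped at $10^{-6}$ and occurrences are counted in the ground
truth.  An MNAR variant replaces two covariates in both missingness models
with latent $U_1, U_2 \sim N(0,1)$ that are withheld from the analysis
models, violating the nested-MAR assumption by construction.

**Trial-shaped fixture** (`data.generate_wsd_like`): emulates a ~1,200
participant, 204-practice telecare CRT — covariate marginals (age
74.13 (13.94); deprivation 28.13 (15.04) truncated to [1.89, 66.49];
mental/physical health scores; baseline EQ-5D-VAS 53.04 (22.02) on
[0, 100]; published binary/categorical frequencies; a negative-binomial
comorbidity count), cluster sizes uniform on 1–26, and configurable
missingness-pattern rates (defaults 19.9% / 10.7% / 5.2%).  Strata come
from a nested Probit on standardized age, deprivation and mental health
with intercepts calibrated to the target death-truncation rate.  The
fixture exercises the full pipeline at realistic dimensions; it does not
emulate covariate *correlations*, informative cluster sizes, or floor/
ceiling effects of bounded scores, so passing tests demonstrate mechanics
and calibration under the stated marginals, not performance on the real
(confidential) trial data.

## Evaluation metrics

For a fitted chain and the generator's truth, with
$\mathcal{A} = \{p^{(11)} \ge q\}$ the likely always-survivors:
PEHE $= \sqrt{\text{mean}_\mathcal{A} (\hat\tau - \tau)^2}$; absolute bias
$= \text{mean}_\mathcal{A} |\hat\tau - \tau|$; regret
$= \text{mean}_\mathcal{A} |\tau| \cdot I(\text{sign disagreement})$, where
"treat" requires $\hat\tau > 0$ strictly and $|\tau|$ keeps regret
nonnegative for harmful true effects; coverage is the fraction of
$\mathcal{A}$ whose true effect lies in the equal-tailed 95% interval
(widened by one float32 ulp, the storage precision of the draw matrix).
Because $\mathcal{A}$ contains some truly non-always-survivors (that is
what FDR measures), the "true effect" is the CSACE surface
$\tau_{11}(x)$ evaluated at each member's covariates.  Stratum power and
FDR compare $I(p^{(11)} \ge q)$ with the true labels over all individuals.
Replication studies compute these per replicate and report "mean (sd)";
replicate $r$ uses generator seed (base + r) and sampler seed (base + r).

## Problem sizes used by the test suite

The full protocol (100 replicates x 20,000 iterations x four engines) is a
multi-day single-CPU computation.  The package's own study defaults are the
full protocol; the shipped tests run the same code at reduced scale chosen
a priori to keep a complete run in minutes: composition checks use 100
fresh replicates of the full 200 x 6 design (generation only); the engine
comparison uses 3 YBSB replicates (2,000 iterations, 1,000 burn-in, K = 50)
against 2 linear-outcome replicates; the MNAR robustness check mirrors it
at 2 replicates; parameter recovery uses 50 linear-truth replicates of 40
clusters x 6 at 300 iterations.  The `replicate` CLI command runs the study
at any scale.

## Known limitations

- The tree sampler is a straightforward Python implementation of the
  canonical moves; its per-iteration adaptation is somewhat less efficient
  than mature C++ BART backends, which is visible as slightly higher PEHE
  at equal chain lengths, narrowing as chains lengthen.
- With very small protected strata the (10,1) model is weakly identified;
  its posterior then follows its prior and the membership model.
- A single chain is run; convergence diagnostics beyond trace export and
  seeded reproducibility are out of scope, as are harmed-stratum
  extensions, non-Gaussian outcomes and survey weights.
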