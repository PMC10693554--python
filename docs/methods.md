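# Methods

## The modeling problem

Enteric methane (CH4) output of ruminants is conventionally predicted from
feed- and animal-level covariates: dry matter intake (DMI, kg/d), body weight
(BW, kg), and rumen fermentation descriptors such as the acetate:propionate
(A:P) ratio. The rumen microbial community is the proximate source of the
methane, so its composition — the relative sequence abundances of several
hundred microbial genera — carries additional predictive information. The
obstacle is dimensional: with ~330 genus abundances and ~220 observations,
unregularized regression overfits badly, and repeated measurements on the
same animal violate the independence assumptions of ordinary least squares.

This package addresses both problems at once: sparsity-inducing variable
selection embedded in a random-intercept linear mixed model, evaluated under
a repeated-measures-aware train/test protocol.

## The model

For animal i at measurement round j,

    y_ij = x_ij' beta + alpha_i + eps_ij,
    alpha_i ~ N(0, sigma_alpha^2),    eps_ij ~ N(0, sigma^2),

with alpha_i a per-animal random intercept capturing the correlation between
the (at most two) records of one animal. Two model families share this form:

* **ANIM-B** predicts CH4 production (g/d) from DMI, BW, A:P and genus
  log-abundances;
* **DMI-B** predicts CH4 yield (g/kg DMI) from BW, A:P and genus
  log-abundances — DMI is excluded because it is the denominator of the
  response.

Sex and breed are never candidate predictors. Genus relative abundances are
filtered by a (threshold, prevalence) rule, log-transformed with a
pseudocount, and standardized (mean 0, sample SD 1, training statistics
only). The response is left in its original units, so intercepts are
interpretable as mean emissions.

### Estimation

`fit_lmm` profiles the marginal Gaussian likelihood over the variance ratio
theta = sigma_alpha^2/sigma^2: at fixed theta, the GLS coefficients and the
residual variance have closed forms, leaving a one-dimensional bracketed
minimization in ln(theta) (tolerance 1e-10 on the log scale; the boundary
sigma_alpha = 0 is always compared against the interior optimum and wins
ties, which also resolves the non-identifiable case of singleton groups).
REML is the default for reported coefficient tables; the ML optimum is
computed on every fit because AIC and BIC use the ML log-likelihood with
k = (#fixed effects incl. intercept) + 2 variance parameters. Counting both
variance components in k is a convention choice; it is configurable.

Predictions for held-out animals use fixed effects only — the random
intercept of an unseen animal has conditional mean zero.

## Penalized estimation (glmmLasso-style L1 and SCAD)

The penalized objective at regularization strength lambda is

    (1/2n) || W(theta)(y - b0 - X beta) ||^2 + sum_j p_lambda(beta_j),

where W(theta) = (I + theta Z Z')^(-1/2) whitens the within-animal
correlation blockwise and the intercept is unpenalized. p_lambda is either
the lasso penalty or SCAD (shape a = 3.7, the literature's standard default),
whose thresholding operator is soft thresholding near zero, a linear
interpolation for 2*lambda < |z| <= a*lambda, and the identity beyond — large
coefficients are not shrunk.

Fitting alternates, at each lambda of a 50-point log-spaced grid from
lambda_max down to 1e-3 lambda_max with warm starts:

1. coordinate descent with the penalty's thresholding operator on the
   whitened data (active-set sweeps, convergence when no coefficient moves
   more than 1e-6; sweeps are JIT-compiled, with an identical pure-Python
   fallback);
2. maximum-likelihood update of (sigma_alpha, sigma) on the residuals.

The whitener deliberately omits the 1/sigma scaling, so switching the random
effect off reduces the fitter exactly to plain lasso coordinate descent —
the reduction the test suite verifies against an independent oracle.

lambda is selected by BIC = -2 loglik + df ln(n) computed at the penalized
estimates, df = nonzero penalized coefficients + intercept + 2 variance
parameters; ties go to the larger lambda. Two numerical guards matter in the
p > n regime:

* **dfmax truncation.** When candidates outnumber observations, the
  smallest-lambda entries near-interpolate, the profiled sigma collapses and
  BIC degenerates toward the saturated model. Entries with more than dfmax
  nonzero coefficients (canonical choice: floor(n/ln n), the largest
  identifiable model order) are ineligible for selection, and the path stops
  once df exceeds dfmax — the same guard glmnet exposes as `dfmax`.
* **Non-converged entries** are flagged, logged and excluded from selection.

After selection the support is refit unpenalized (`refit_selected`) so that
reported coefficients and standard errors are not shrinkage-biased.

## Selection routes

* **conventional** — the fixed animal-only baseline (DMI, BW, A:P for
  ANIM-B; BW, A:P for DMI-B).
* **glmmLasso / SCAD** — sure independence screening (rank by |marginal
  correlation|, keep floor(n/ln n) columns), then an iterative VIF filter
  (drop the worst column until all VIF < 5; ridge-stabilized when candidates
  reach the observation count), then the BIC-tuned penalized LMM path.
* **LASSO** — same prescreen, then plain L1 least squares with lambda chosen
  by 10-fold cross-validation whose folds are *animal-grouped*, so records of
  one animal never straddle folds.
* **RF-B** — no prescreen; the union of the random-forest top-10 and
  gradient-boosting top-10 importance lists (RF: 500 trees, mtry 40;
  boosting: 100 depth-1 trees, learning rate 0.1). Importance is
  impurity-based by default — permutation importance is available
  (`importance="permutation"`) but costs two orders of magnitude more inside
  a replicated protocol, for selection lists that rarely differ on this kind
  of data. Ties in every ranking break by column label for reproducibility.

Screening runs inside each training split by default (`screen_scope="train"`);
`screen_scope="full"` reproduces the literal protocol ordering (screen once
on all data), which leaks test information and is provided for comparison
only.

## Evaluation protocol

Each of `n_replicates` (default 200) replicates: draw an animal-grouped
80/20 split, standardize with training statistics, select per method, refit
the LMM on the selected support, predict the held-out records fixed-effects
only, and archive every (observed, predicted) pair. Metrics are computed on
the pooled archive across replicates (per-replicate metrics are retained as
well, since the pooling convention is ambiguous in common practice):

    MSPE = mean (O - P)^2      RMSPE = sqrt(MSPE)      MAE = mean |O - P|
    CCC  = 2 s_OP / (s_O^2 + s_P^2 + (mean O - mean P)^2)

with 1/N moment conventions in the CCC (Lin's concordance correlation).
Percent changes vs the conventional baseline are computed from unrounded
metrics.

**Split rule.** Exact 20% test observations is unattainable when animals
contribute one or two records and must move as blocks. Animals are drawn
uniformly without replacement and accepted while acceptance moves the test
observation count closer to 0.2 * n_obs; the realized share is therefore
always within one observation of the target. Replicate seeds are
base_seed + replicate_index.

The full-data fitting comparison selects on all (standardized) data, refits,
and reports ML-based AIC/BIC, REML coefficients with SEs, sigma_alpha, and
reductions vs the conventional baseline. "Balancing" prediction and fitting
performance is not an algorithm; `final_model_choice` reports both rankings
and flags the minimal-BIC method among those within a configurable relative
RMSPE tolerance (default 5%) of the best predictor — a labeled convenience,
never a silent decision.

## Synthetic data generator

The generator reproduces the statistical structure the pipeline assumes,
with known ground truth:

* 117 sheep, 101 with two records and 16 with one (218 observations);
  330 genera partitioned 308/9/5/8 over bacteria/archaea/protozoa/fungi.
* BW ~ N(42, 6^2) kg; DMI = 0.033 BW + N(0, 0.12^2) kg/d (animals fed to an
  energy requirement based on BW); A:P ~ N(3.0, 0.5^2).
* Log genus abundances = genus baseline (SD 2.0 across genera, giving a
  realistic dominance-skewed rank-abundance curve) + animal-level component
  (SD 1.0) + record-level component (SD 0.15), exponentiated and closed to
  sum to one per record; structural zeros injected at rate 0.05 (causal
  genera exempt so the ground-truth effect scale stays defined).
* Response: intercept 21.9 g/d + effects on population-standardized causal
  features + bimodal animal intercept + N(0, sigma^2) residual. Defaults:
  sigma_alpha = sigma = 1.5 g/d; emitter-group offset 3.0 g/d at mix 0.5, so
  the marginal animal-level SD is sqrt(1.5^2 + 0.25 * 3^2) ~ 2.1 g/d; animal
  effects 1.2 (DMI), 1.2 (BW), 1.0 (A:P) g/d per SD; 8 causal bacterial
  genera drawn from the more abundant half with |beta| in [0.8, 1.2] g/d per
  SD and random signs. CH4 yield = production / DMI.

The genus effect magnitudes are a deliberate calibration: with weaker
effects (e.g. |beta| ~ 0.5–0.8) the microbial signal is too faint for *any*
selector to exploit — false selections absorb random-intercept variance and
make microbiota-aware models predict *worse* out of sample than the
conventional baseline — so the generator's defaults are set at the weakest
level where the conventional-vs-microbial RMSPE gap is reliably detectable
under the replicated protocol. The record-level abundance SD is kept small
so that within-animal response differences are residual-dominated
(variance ~ 2 sigma^2), matching the repeated-measures structure of real
chamber data.

Because a random-intercept model cannot separate the emitter-group offset
from the Gaussian animal intercept, the ground truth records
`sigma_alpha_marginal` = sqrt(sigma_alpha^2 + p(1-p) d^2); fitted sigma_alpha
values are compared against it.

### What the generator does not emulate

Phylogenetic correlation among genera, sequencing-depth variation,
read-count noise, diet shifts between rounds, and any association between
emitter group and microbiota composition (the offset is independent of the
abundance draws). Passing tests therefore demonstrate correctness of the
machinery and its behavior under the assumed model, not biological fidelity
of effect sizes, which are unknown.

## Known limitations

* **Selection power on animal-level features.** Genus abundances vary mostly
  between animals, so genus fixed effects compete with the random intercept:
  the effective sample size for selection is the number of animals, and the
  GLS whitening — statistically correct for estimation — downweights exactly
  the between-animal contrasts that carry the signal when sigma_alpha is
  inflated early on a sparse path. Combined with closure-induced proxy
  correlation (every log-ratio column shares the log-total component),
  BIC-tuned penalized selection recovers most but not all causal genera and
  admits proxies: measured over repeated study-shaped datasets, the SCAD
  route attains precision ~0.75 and recall ~0.65. Support lists from data of
  this shape should be read as candidate biomarkers, not as the causal set.
  The same feedback affects prediction: across repeated study-shaped
  datasets the plain-LASSO and SCAD routes beat the conventional baseline in
  pooled RMSPE nearly always (20/20 and 19/20 of generator seeds), while the
  whitened L1 (glmmLasso-style) route wins only on a majority of datasets
  (12/20) — its selections absorb more random-intercept variance. For
  prediction on data of this shape, the LASSO and SCAD routes are the
  recommended microbiota-aware methods.
* **p > n likelihood degeneracy** is handled by dfmax truncation rather than
  by a high-dimensional information criterion; an extended-BIC selector
  would be a natural extension.
* Single random intercept only; no crossed or nested random effects, no
  non-Gaussian responses.
* The dip-free bimodality check in the test suite uses a two- vs
  one-component Gaussian-mixture BIC comparison.

## Problem sizes used in the checks

The replicated-protocol tests and the acceptance script use 30–50 replicates
per experiment and 10–50 generator seeds; these sizes give stable pooled
metrics for the package's own regression testing. The protocol default for a
scientific run remains 200 replicates.
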