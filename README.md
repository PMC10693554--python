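# ch4pred

Predicting enteric methane (CH4) emissions of sheep from rumen-microbiota
profiles with penalized linear mixed models.

## The problem

Methane from ruminants is a major agricultural greenhouse-gas source, and
emission inventories need per-animal predictions. Conventional models use
only feed- and animal-level covariates — dry matter intake (DMI), body
weight (BW), the rumen acetate:propionate (A:P) ratio — and ignore the
microbial community that actually produces the methane. Adding microbiota
data is attractive but statistically hard: a typical dataset has ~330 genus
relative abundances against ~220 observations, and most animals are measured
twice, so observations are not independent.

`ch4pred` implements the full modeling pipeline for this setting:

* a random-intercept linear mixed model
  `y_ij = x_ij' beta + alpha_i + eps_ij` with per-animal intercepts
  `alpha_i ~ N(0, sigma_alpha^2)`, fitted by profiled ML/REML;
* sparsity-inducing selection of microbial predictors — glmmLasso-style L1
  and SCAD penalties on the mixed model (BIC-tuned over a lambda path),
  cross-validated plain LASSO, and a random-forest + gradient-boosting
  importance union — behind a sure-independence-screening + VIF prescreen;
* a repeated-measures-aware evaluation protocol: animal-grouped 80/20
  splits repeated (by default) 200 times, training-only standardization,
  per-split selection and mixed-model refit, pooled RMSPE / MAE / Lin's CCC;
* a full-data fitting comparison (ML-based AIC/BIC, REML coefficients);
* a synthetic-data generator that emulates the study design (218
  observations of 117 sheep, 101 measured twice; 330 compositional genus
  abundances; bimodal high/low-emitter structure) with known ground truth.

Two model families are supported: **ANIM-B** (CH4 production, g/d) and
**DMI-B** (CH4 yield, g/kg DMI; DMI excluded from the predictors).

See `docs/methods.md` for the model, the algorithms, all tunable parameters
and the generator's assumptions.

## Worked example

Generate a study-shaped synthetic dataset and compare the conventional
animal-only model with the penalized mixed model under the replicated
protocol (30 replicates here for speed; the scientific default is 200):

```python
from ch4pred import SyntheticConfig, generate, run_prediction_experiment

table, truth = generate(SyntheticConfig(seed=500))
report = run_prediction_experiment(
    table, "ANIM-B", ["conventional", "LASSO", "SCAD"],
    n_replicates=30, base_seed=0,
)
print(report.to_frame().round(3))
```

```
                        conventional   LASSO    SCAD
RMSPE                          4.493   3.345   3.402
Reduction of RMSPE (%)           NaN  25.556  24.290
MAE                            3.601   2.706   2.773
Reduction of MAE (%)             NaN  24.847  22.988
CCC                            0.405   0.738   0.736
Increase of CCC (%)              NaN  82.193  81.499
```

Selecting microbial predictors cuts the pooled root-mean-square prediction
error by ~25% and nearly doubles Lin's concordance correlation: the genus
abundances carry real predictive information beyond DMI, BW and the A:P
ratio. Gains vary by dataset — across 20 generator seeds the LASSO and SCAD
routes beat the baseline in 20/20 and 19/20 cases respectively.

The same pipeline is scriptable from the shell:

```bash
ch4pred simulate --seed 1 --out-dir run/
ch4pred evaluate-prediction --input run/dataset.csv \
    --methods conventional,glmmLasso,LASSO,SCAD,RF-B --out-dir run/pred
ch4pred evaluate-fitting --input run/dataset.csv \
    --methods conventional,glmmLasso --out-dir run/fit
ch4pred final-model --input run/dataset.csv \
    --methods conventional,glmmLasso,SCAD --out-dir run/final
```

Every run writes a `manifest.json` with the configuration, seeds and library
versions needed to reproduce it.

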