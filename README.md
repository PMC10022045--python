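# maihda

Intersectional multilevel analysis (MAIHDA) of binary health outcomes in
categorical survey microdata.

## The problem

Average associations between single social determinants of health (SDoH) and
an outcome miss how disadvantage compounds at the *intersections* of social
positions — e.g. a young child in a particular division whose mother is
unemployed and whose household disposes of garbage within the premises.
MAIHDA (multilevel analysis of individual heterogeneity and discriminatory
accuracy) treats every observed combination of selected determinants as an
**intersectional stratum** and models individuals as nested in strata. It was
developed for social epidemiology settings such as child-health surveys in
urban informal settlements, where outcomes like cough, fever and acute
respiratory infection (ARI) are common and strata number in the hundreds,
many of them tiny — exactly where multilevel partial pooling beats
fixed-effects cross-classification.

## The model

For child *i* in stratum *j*:

```
logit P(y_ij = 1) = β0 + x_ij'β + u_j ,   u_j ~ Normal(0, σ²_u)
```

Two models are fitted by MCMC with weakly informative priors:

* **Model 1 (null)** — intercept and stratum effect only. Its stratum
  variance captures *all* between-strata differences (additive and
  interactive), the ceiling of the strata's explanatory power.
* **Model 2 (main effects)** — adds treatment-coded indicators of the
  strata-defining variables. Its remaining stratum variance reflects
  interaction (multiplicative) effects only.

The readout:

* **VPC** = σ²_u / (σ²_u + π²/3) — the share of latent-scale variance lying
  between strata (π²/3 is the logistic individual-level variance); a Model 1
  VPC above 5% is conventionally an "acceptable" discriminatory accuracy.
* **PCV** = (V₁ − V₂)/V₁ — how much of the null model's stratum variance
  the main effects explain; 100% means purely additive effects, a shortfall
  signals intersectional interactions.
* **AUC-ROC** of each model's posterior-mean predicted probabilities
  (stratum effects included in both models).
* **Ranked stratum residuals** u_j with 95% credible intervals (caterpillar
  plots): positive = disadvantaged (higher risk than the main effects
  predict), negative = privileged.

## Worked example

No external microdata are required: the package ships survey-like synthetic
presets (3,183 children; outcome prevalences near 19% cough / 28% fever / 5%
ARI; the matching determinant sets). From Python:

```python
import maihda as m

cfg = m.PipelineConfig(outcome="cough", preset="cough", seed=7,
                       outdir="out", profile="desk")
bundle = m.run_pipeline(cfg)
print(bundle.da.vpc_model1, bundle.da.vpc_model2, bundle.da.pcv)
print(bundle.da.da_verdicts)
```

or from the shell:

```console
$ maihda report --config cfg.yaml --seed 7
report written to out
VPC model1 5.83%, model2 0.30%, PCV 95.17%; verdicts: acceptable DA, additive effects
```

Reading: between-strata differences account for 5.8% of latent-scale
variance in the null model (acceptable discriminatory accuracy); adding the
main effects collapses the stratum variance (VPC 0.3%, PCV 95%), so for this
generated dataset the intersectional differences are essentially additive —
as they should be, since this preset contains no interaction terms. The
output directory holds the screening table, the strata roster, a
Table-1-style CSV (odds ratios with 95% credible intervals, variance /
strata / observations / AUC-ROC / VPC / PCV footer), the DA summary JSON,
caterpillar CSVs for both models, convergence diagnostics (split R-hat,
effective sample size) and a run log with the seed and config hash.

The pipeline stages can also be driven separately (`maihda simulate`,
`screen`, `strata`, `fit`) or called as library functions
(`load_survey`, `complete_cases`, `select_determinants`, `build_strata`,
`fit`, `evaluate_da`, `stratum_effects`).

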