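# Methods

## Model

For individual *i* in intersectional stratum *j*:

logit P(y_ij = 1) = β0 + x_ij'β + u_j,  u_j ~ Normal(0, σ²_u).

Strata are the observed combinations of the selected categorical social
determinants; the covariates x are treatment-coded indicators of those same
variables, so they are constant within a stratum. Model 1 sets β = 0 (null
model); Model 2 includes the main effects. Only observed combinations enter
the model — empty cells of the cross-product contribute nothing to the
likelihood — and singleton strata are retained, relying on partial pooling.

Assumptions worth keeping in mind: a single level-2 classification (no
cross-classified or three-level structure), binary outcomes only, no survey
weights, and missingness handled exclusively by complete-case filtering
under a missing-completely-at-random assumption (no imputation, by design).

## Priors

Weakly informative and configurable (`PriorSpec`):

* β0 and each β: Normal(0, 10) on the log-odds scale. On this scale a
  standard deviation of 10 is effectively flat over any plausible odds
  ratio; doubling it moves the intercept posterior by well under 0.02
  (checked by test).
* σ_u: half-Student-t with 3 degrees of freedom and scale 2.5 — a standard
  weakly informative choice for a group-level standard deviation that keeps
  mass near zero without excluding large variances.

## Sampler

A gradient-free Metropolis-within-Gibbs sampler written in numpy, chosen so
the package has no compiled dependency. One iteration consists of:

1. random-walk updates of β0 and of each β_k on its support (only records
   with the indicator set contribute to the acceptance ratio);
2. likelihood-invariant **translation moves** that shift β0 (or a β_k)
   against the stratum effects of the affected strata — η is unchanged and
   only the normal priors enter. These break the strong posterior coupling
   between the fixed effects and u;
3. an element-wise block update of all u_j (each stratum's likelihood is
   independent given the rest, so all J proposals accept or reject
   independently in one vectorised step);
4. a random-walk update of log σ_u given u (with Jacobian), and
5. a joint (u, σ_u) **rescale move** (u' = c·u, σ' = c·σ) whose normal-prior
   terms cancel exactly, which decorrelates σ_u from the current u draw.

Proposal scales adapt by Robbins–Monro (target acceptance 0.44, step
(t+1)^-0.6) during burn-in only and are frozen afterwards, so the retained
chain satisfies detailed balance. Chains start from the empirical-logit
intercept with seeded jitter. Per-chain generators are spawned from the
config seed (`numpy.random.SeedSequence`), making fits bit-reproducible.

Run-length profiles: `desk` (default) uses 4 chains × 5,000 iterations with
1,000 burn-in — enough for split R-hat < 1.05 on all parameters at the
problem sizes this package targets (thousands of records, hundreds of
strata). A `paper` profile runs 50,000 iterations with 5,000 burn-in for
final analyses, and `reduced` (2 × 1,000, 400 burn-in) serves simulation
studies that need many fits. Convergence is assessed numerically — split
R-hat (implemented here, including the degenerate constant-chain case) and
bulk effective sample size (via arviz) — with trace data exportable for
visual checking; summarising an unconverged fit requires an explicit
override.

The log posterior is exposed as a plain function (`log_posterior`) with all
prior normalising constants included, and the test suite checks it against
an independent term-by-term recomputation; the sampler's incremental
updates are thereby anchored to an explicitly stated density.

## Discriminatory-accuracy metrics

The level-1 latent variance is fixed at π²/3 (logistic), giving
VPC = σ²_u/(σ²_u + π²/3). Because the VPC transform is nonlinear, VPC and
PCV are computed two ways: from posterior-summary variances (the tabular
convention) and per posterior draw summarised by the median — the package
default; the PCV default is computed from the posterior-median variances of
the two models. The Jensen gap between the per-draw mean VPC and the VPC of
the posterior-mean variance is reported alongside both.

AUC-ROC uses the rank-sum formulation with half credit for ties, applied to
posterior-mean predicted probabilities that include the stratum effects in
both models (the null model has no covariates, so its discrimination comes
entirely from the strata). Verbal verdicts follow the conventional rules:
Model 1 VPC above 5% is "acceptable DA"; a Model 2 VPC at or below 1% is
read as "additive effects", above as "presence of interactional effects" —
exact zero never occurs because the variance posterior has positive
support, so a 1% tolerance stands in for "approximately zero".

Stratum residuals are summarised by posterior mean with equal-tailed 95%
credible intervals, ranked ascending, flagged where the interval contains
zero, and exported as caterpillar-plot-ready CSV.

## Pipeline order

Complete-case filtering on the outcome plus all candidate determinants runs
*before* univariate screening, fixing each outcome's analysis sample before
any test statistic is computed; strata are rebuilt per outcome after that
filtering (the only ordering consistent with per-outcome sample sizes and
per-outcome strata counts). Screening uses the Pearson chi-square without
continuity correction at α = 0.05 by default — the test conventionally
shown in household-survey univariate tables — with a univariate logistic
likelihood-ratio test available as a sensitivity switch, and deliberately
applies no multiple-testing correction (selection is variable-at-a-time at
the nominal level; adjust α to change this). Small-cell rules are not
applied; a degenerate margin is an error naming the level.

## Synthetic data

The generator (`maihda.synthetic_data`) emulates the structure of a
child-health household survey: one row per child, a binary outcome, and
categorical determinants drawn independently from declared marginals.
Stratum effects are drawn per observed covariate combination; interaction
terms are specified as predicates over stratum profiles plus a log-odds
bonus — the concrete mechanism behind "multiplicative" intersectional
effects, recoverable as the stratum variance Model 2 cannot explain.
Missingness is completely at random. A `balanced` mode allocates the
cross-product evenly for simulation designs that want equal stratum sizes,
and a `profile_mixture` hook induces correlated determinants for stress
tests.

The presets (`uhs_like_preset`) fix the survey scale: 3,183 records;
outcome prevalences 19% (cough), 28% (fever), 5% (ARI) with the intercept
calibrated by quadrature so the *marginal* prevalence hits the target;
per-outcome determinant sets whose category counts give 192 / 1,536 / 576
potential strata; true odds ratios set to the values reported for the
survey the presets emulate; and residual (beyond-main-effects) stratum
variances of 0.05 / 0.02 / 0.04, matching the reported Model 2 scale.
Marginals are uniform — the survey's real marginals live in external
supplementary material — so preset strata are more evenly filled than real
survey strata, and the generator omits survey design features (clustering,
weights, correlated determinants by default). Passing tests therefore
demonstrate correctness of the method under a faithful *structural*
emulation, not agreement with the external survey's published estimates,
which are not recomputable without its microdata.

## Numerical choices and edge cases

* Softplus via `logaddexp` throughout; non-finite sampler states abort with
  a parameter dump.
* Equal-tailed 95% intervals (2.5/97.5 percentiles); odds ratios
  exponentiate the posterior median by default (mean available).
* Category labels match case-sensitively after whitespace trimming (silent
  case-folding would hide codebook errors); CSV/TSV dialects are
  autodetected from the header line.
* Stratum ordinals are 1-based, sorted lexicographically by codebook level
  order, so rankings are reproducible across record orderings.
* Ties in AUC get half credit; a single-class outcome is an error.
* σ²_u = 0 is accepted by the generator (effects exactly zero) but the
  model's variance posterior is always positive; VPC rejects negative
  input, PCV rejects a non-positive null-model variance.

## Simulation study sizes

The test suite's simulation studies use sizes chosen to exercise the
method's claims at survey scale while remaining desk-runnable: parameter
recovery uses 200 balanced strata of 30 children (σ²_u = 0.5, five seeds,
desk profile); additive-vs-interaction discrimination uses n = 10,000 over
100 strata with a 0.8 log-odds checkerboard interaction covering ~24% of
strata (20 matched seed pairs at the reduced profile — the checkerboard is
chosen to be orthogonal to the additive main effects, so the full bonus
variance lands in the Model 2 stratum variance rather than being partly
absorbed by the main effects); screening calibration uses 10,000 simulated
2×2 tables of n = 200.

## Known limitations

* The β recovery tolerance achievable at 200 strata × 30 children is bounded
  below by the realised stratum-effect noise projecting onto each contrast
  (standard error ≈ √(2(σ²_u + 1/(m·p̄(1−p̄)))/J_level) ≈ 0.18 log-odds for a
  five-level variable there), which no correct fitter can beat; see the test
  suite's recovery test for the measured behaviour.
* With few strata (tens), β0 and the mean of u are only weakly separated
  and the variance posterior is prior-sensitive — caterpillar intervals are
  honest about this, point estimates of σ²_u at small J carry upward bias.
* The random-walk sampler is not tuned for models with many highly
  correlated fixed effects beyond the treatment-coded sets used here; a
  plug-in gradient-based backend can replace it without touching the rest
  of the pipeline.
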