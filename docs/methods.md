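# Methods

## The staged likelihood-ratio model

`uhrbayes` models transition from the ultra-high-risk (UHR) state to
first-episode psychosis as a sequence of Bayesian updates. A subject
enters with a pretest probability *p* (by default the cohort's observed
transition rate), converted to odds *p*/(1 − *p*). Every retained
predictor, dichotomized at its threshold, contributes one multiplicative
update — LR+ = sens/(1 − spec) for a positive call, LR− =
(1 − sens)/spec for a negative call — and the odds are converted back to
a probability after each assessment group (historical → clinical →
biomarker by default, configurable). Because the updates commute, the
final posterior is invariant to group and within-group order; only the
intermediate trajectory depends on it.

The chain is exactly the naive-Bayes posterior under conditional
independence of the predictors given the outcome. That assumption is
the model's main scientific caveat: correlated predictors (e.g. the
three PANSS subscales) make the chained posterior overconfident. The
synthetic generator's `dependence` parameter exists precisely to let
users probe this failure mode.

Likelihood ratios are carried at full floating-point precision through
the chain; rounding to the conventional two decimals happens only in
display columns of exported tables. Chaining pre-rounded LRs changes
posteriors in the second decimal place and makes audits impossible.

## Fitting pipeline

`BayesChainClassifier.fit` performs, in order:

1. **Screen.** Per candidate predictor (with per-predictor pairwise
   deletion of missing values), the empirical ROC and the DeLong test of
   AUROC ≠ 0.5; candidates with p ≥ α (default 0.05) are dropped. An
   exact permutation test is available (`auroc_test_vs_chance(...,
   method="permutation")`) but the screen uses the DeLong normal
   approximation, which at n ≈ 40 is mildly liberal (its true type-I
   rate is nearer 7% than 5%) — users working at this scale who need
   strict error control should prefer the permutation option.
2. **Dichotomize.** Continuous predictors get the Youden-optimal cut;
   ties on *J* prefer the higher-sensitivity point (a missed transition
   costs more than a false alarm), then the less extreme threshold.
   Binary predictors are fixed at "value = 1 is a positive call". The
   calling inequalities are value > t for high-risk-when-high predictors
   and value ≤ t for high-risk-when-low ones (GAF, nervonic acid, total
   omega-3).
3. **Estimate.** Confusion counts at the chosen cuts give sensitivity,
   specificity and the LR pair. An empty cell (specificity or
   sensitivity exactly 1) makes an LR infinite; the default policy keeps
   the exact rates and flags the infinity, with a Haldane–Anscombe
   (+0.5 to every cell) opt-in. The default never silently alters
   values recomputed from published tables.
4. **Assemble.** The grouped `BayesModel`, with the pretest probability
   defaulting to the training outcome rate; `predict` applies the
   Youden-optimal cut on the training posteriors.

Missing data at prediction time follow whole-case exclusion by default
(the posterior is NaN and the case is flagged with the offending
predictors); a "skip" policy (missing predictor contributes no update)
is available but off by default.

## ROC machinery

AUROC is the tie-corrected Mann–Whitney statistic, computed from the
exact rank sum with a single division, so it is bit-identical to
exhaustive pair counting. Variances and covariances of correlated
AUROCs use placement values (per-case and per-control structural
components); the one-sample test against 0.5 and the paired two-sample
comparison are both normal-approximation z tests on that basis.
Operating points are enumerated over all distinct observed values plus
the two infinite endpoints, so the Youden search is exact.

## Evaluation

`evaluate_model` computes the ROC over posterior probabilities, the
Youden-optimal probability threshold, sensitivity/specificity there,
and PPV/NPV from the standard prevalence identities. At the published
full-model operating point (sens 72.73%, spec 96.43%, prevalence 28%)
those identities give PPV ≈ 88.8% and NPV ≈ 90.1%; the originally
reported 88.5%/90.3% differ slightly and their derivation is unstated,
so this package reports what the identities produce.

`bootstrap_sens_at_spec` resamples subjects with replacement
(unstratified by default; replicates that draw a single outcome class
are redrawn with a capped retry budget and a warning). Per replicate
the statistic is the largest sensitivity among operating points with
specificity ≥ the fixed value — equivalently the point with the
smallest specificity satisfying the constraint, the conservative
reading. The BCa interval uses the standard bias-correction constant
(proportion of replicates below the point estimate, ties counting half)
and jackknife-estimated acceleration; a percentile method is available
for comparison. At n ≈ 40 these intervals are very wide (median width
well above 0.3 across replicate cohorts, and occasionally degenerate at
[1, 1] when a cohort separates perfectly) — this is the honest picture
of internal validation at that sample size, not a defect.

## Synthetic cohorts

The generator emulates the analyzed study's structure: n = 40 subjects,
28% one-year transition prevalence, and seven informative predictors in
three assessment groups, each planted at its published sensitivity and
specificity. Outcomes are Bernoulli(prevalence) per subject (redrawn if
a class is empty, since downstream ROC analysis needs both classes).
Continuous predictors are class-conditional Gaussians with the class
means solved analytically so the targets hold exactly at the planted
threshold; binary predictors are class-conditional Bernoulli with
positivity rates sens (cases) and 1 − spec (controls). Targets implying
a negative Youden index are rejected as requiring a non-monotone cut.
Within-class dependence is an optional equicorrelated Gaussian copula
(default 0 = conditional independence); missingness is optional
per-cell MCAR (default none).

Default class SDs are set once on field-typical scales: PANSS positive
4, negative 5, general 8 (subscale score points), GAF 10 (0–100 scale),
nervonic acid 0.08 and total omega-3 1.2 (percent of total erythrocyte
fatty acids). Equal SDs per class are the minimal model admitting an
analytic mean solve; per-class SDs are supported (`case_sd`) since the
real data showed larger spread in some predictors among transitioned
subjects, but no published values exist to emulate.

One consequence of the equal-SD design: when a predictor's planted
sensitivity ≠ specificity, the *population* Youden-optimal cut is the
class-density crossing (the midpoint of the class means), not the
planted threshold. `PredictorGenSpec.population_youden_threshold()`
returns the analytic optimum, and parameter-recovery tests compare
fitted thresholds against it. The generator reproduces published
operating characteristics at the planted cuts; it does not claim the
planted cuts are optimal in its own population.

What passing tests on these cohorts do and do not show: they validate
the chain, the screening and the evaluation machinery under exactly the
model's assumptions (Gaussian class-conditionals, conditional
independence, MCAR missingness). Real UHR data violate all three to
unknown degrees, so synthetic performance says nothing about external
validity on a new cohort.

## Problem sizes and numerical choices

Large-sample checks use n = 10⁵ (operating-characteristic recovery,
calibration, dependence) and n = 10⁴ (parameter recovery).
Distributional checks use 200 study-scale cohorts for the
group-combination AUROC ordering (mean combined ≈ 0.97 > clinical
≈ 0.92 > fatty-acid ≈ 0.84 > historical ≈ 0.73, matching the published
ordering; the published resubstitution AUROC 0.919 for the combined
model falls between the clinical-only and combined means), 500 cohorts
with analytic truth for bootstrap coverage (n = 100, fixed specificity
0.75, a scale at which the sensitivity-at-specificity statistic has
enough resolution for a meaningful coverage check), and 1000 replicates
for screen error rates. Bootstrap draws are fully determined by a
single integer seed.

Degenerate inputs: constant scores give AUROC 0.5 with a zero-variance
flag and a limiting p-value under a warning; all-equal posteriors warn
and evaluate at chance; single-class outcomes raise errors naming the
missing class.

## Known limitations

- Conditional independence is assumed, not tested, by the chain; with
  correlated predictors the posteriors are miscalibrated even though
  the ranking (AUROC) degrades little.
- Resubstitution evaluation at n = 40 with seven predictors is heavily
  optimistic (refitting thresholds and LRs on the same cohort routinely
  yields AUROC 1.0); the bootstrap CI is an internal-validation aid,
  not a substitute for external validation.
- LRs are estimated from tiny confusion matrices (11 cases); their
  sampling error is not propagated into the posterior trajectories.
- The published Youden index for nervonic acid (0.5357) equals its
  printed specificity rather than sens + spec − 1 = 0.4448; the package
  treats it as a transcription slip and uses the value implied by the
  published sensitivity/specificity.
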