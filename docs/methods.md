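# Methods

This note documents the statistical models behind `maternalcv`, the
calibration mathematics of the synthetic cohort generator, the numerical
choices in the cross-validation engines, and what the shipped tests do
and do not establish about real survey data.

## 1. The estimand and the search

The outcome is a maternal mental-health composite (mean of 27 Likert
items, range 1–5).  Fifteen candidate factors are considered: seven
score-derived (resilience, pandemic life stress, work stress, the
job-change count, family conflict, father involvement, grandparental
support) and eight demographic (maternal age band, marital status,
education, employment, physical health, household income, number of
children, age of youngest child).  Categorical factors enter as
reference-coded dummy blocks that are included or excluded whole; with
levels 4+2+3+2+3 for the categoricals this yields 19 design columns
plus an intercept.

All 2¹⁵ = 32 768 subsets (intercept always present) are scored by the
root mean squared error of prediction under repeated k-fold
cross-validation (defaults k = 10, R = 200):

* one fold partition per repeat, shared by **all** models — winner
  comparisons on different partitions would conflate model quality with
  partition luck;
* per fold, OLS on the other k−1 folds, prediction of the held-out
  fold; RMSEp = √(mean over all n held-out squared errors);
* the per-repeat winner is the model with minimal RMSEp; ties within a
  floating-point tolerance (best + 1e−12 + 1e−9·best) are broken by
  fewest factors, then canonical (mask) order.  The tolerance matters in
  noise-free tests where a model and its supersets all fit exactly and
  differ only at machine precision.

The sentence describing the fold orientation in this family of designs
can be read either way; we default to the standard orientation (train
on k−1 folds, validate on 1) and expose `CVConfig.train_on_one` for the
inverted reading.  Ranking of the reported top-k table is by winner
percentage first, mean RMSEp second.

### Engines

`naive` refits every model on every training split via
`numpy.linalg.lstsq`.  `gram` computes X'X and X'y once per partition
and subtracts each fold's contribution, so a model/fold fit is a ≤20×20
linear solve independent of n; rank-deficient training blocks (e.g. a
dummy level absent from a training split) fall back to minimum-norm
least squares via the pseudoinverse of the normal equations, which
coincides with the minimum-norm solution of the raw least-squares
problem.  The two engines agree to well below 1e−8 in RMSEp on random
instances (property-tested).  Desk-scale problems (p ≤ 10, R ≤ 50) run
in seconds; the full p = 15, R = 200 sweep is a long unattended
single-CPU run and is not exercised by the test suite, whose scenarios
use p ≤ 8.

### What repeated-CV winner tallies can and cannot show

The probability that a fixed superset of the true model wins a repeat
does **not** vanish as n grows (k-fold CV with fixed k is not a
consistent selector); it is governed by the realization's spurious
correlations.  Consequently the winner percentage of the true model is
not monotone in n for a single dataset.  The selection-consistency test
therefore averages winner percentages over 25 replicate datasets with
true effects (0.4, 0.10, 0.055) against unit noise, sized so the weaker
effects cross their detection thresholds between n = 200 and n = 3200;
on that average the share rises from a few percent to roughly 40 %.
Similarly, "adding a true factor never increases RMSEp at zero noise"
holds only where the expected improvement dominates CV sampling noise;
at n = 200 a weak true factor can raise out-of-sample error through its
sampling covariance with the omitted-factor residual, so the nesting
property is asserted at n = 3000.

## 2. Transfer validation

A winning model travels as a **factor subset**: its coefficients are
re-estimated on the target cohort's training folds (frozen-coefficient
transfer would additionally require comparable score scales across
countries and is not implemented).  The same repeat seeds drive the
partitions for every source model on a given target, making the nine
RMSEp distributions a paired comparison.  Summaries are five-number
statistics plus a distribution-overlap coefficient (integral of the
pointwise minimum of two histogram densities on a shared grid).

## 3. Robust standardized refit and moderation

The final refit is OLS on the standardized outcome with standardized
continuous predictors (n−1 denominator); dummies stay 0/1, so their
coefficients are standardized mean differences.  Inference uses HC3
sandwich covariance with normal-reference Wald tests ("robust standard
OLS"); with n > 600 the z vs t distinction is negligible.  Adjusted R²
is reported from the classical OLS fit, which shares the point
estimates.  M-estimation is deliberately not used; HC0–HC2 are
available through the `cov_type` option.  No multiple-testing
correction is applied to the per-term p-values.

Moderation augments the selected model with products of the
standardized moderator (resilience) and standardized focal stressors;
because both are centered, the focal main effect is the simple slope at
the moderator mean, and slopes at ±1 sd are β_focal ∓/± β_interaction
by construction.  For a categorical focal term (maternal age) one
product per non-reference dummy is added and no simple slopes are
reported.

Descriptive group comparisons use one-way ANOVA for continuous
variables and Pearson chi-square without continuity correction for
categorical ones; a variable constant in all groups is reported as
undefined (NaN) rather than zero.

## 4. The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions.

**Demographics.**  Sampled independently per respondent from per-country
prevalence tables.  Grandparental-support prevalences (0.536 / 0.183 /
0.094) and sample sizes (922 / 641 / 900) are published values; the
remaining marginals (age bands, marital status, education, employment,
physical health, income quintile, number of children, youngest-child
age uniform on 1–10) are plausible synthetic defaults chosen once —
the source tables for those marginals are not reproduced here.  No
copula between demographics is imposed.

**Likert items.**  Each scale has a latent standard-normal trait; item j
is sqrt(ρ′)·trait + sqrt(1−ρ′)·noise, thresholded at equal-probability
normal quantiles into its 1–5 (or 1–4, 1–10) range.  The target
inter-item correlation ρ comes from inverting standardized alpha,
ρ = α / (k − α(k−1)), and the latent correlation is inflated,
ρ′ = ρ / λ², where λ = corr(z, discretize(z)) is computed exactly from
the bin edges (λ ≈ 0.942 for five levels).  Residual error from the
neglected higher-order Hermite terms shifts alpha by well under 0.01 at
these parameter values.  Configured latent means/sds (defaults 0/1)
shift the trait before thresholding.

**Mental-health items.**  A bifactor-style structure: the standardized
latent outcome is the general factor; four subscale factors
(somatization 6, depression 5, anxiety 6, post-traumatic stress 10
items) each load 0.98 on it; items load compound-symmetrically within
subscales.  The within-subscale item correlation is solved from the
standardized-alpha identity for the full 27-item composite (α = 0.96),
counting 85 within- and 266 between-subscale pairs, so full-scale alpha
and the subscale-score correlation band (observed ≈ 0.80–0.84, inside
the published 0.776–0.961) hold simultaneously.  The general loading of
0.98 was chosen to center that band.

**Job changes and work stress.**  Work stress is a 10-level
discretization of a standard normal w.  Indicator j of the job-change
block fires when a·w + b·u + sqrt(1−τ)·e_j exceeds the threshold for
30 % prevalence, with τ = a² + b².  τ is solved (Brent on bivariate
normal orthant probabilities) so the phi inter-indicator correlation
reproduces α = 0.83, and a is solved so the count index correlates 0.35
with the discretized work-stress item; defaults are τ ≈ 0.437,
a ≈ 0.272.

**Latent outcome.**  y = Σ β_f·x_f + Σ β_{mf}·x_m·x_f + σ·ε, where
continuous x are composite scores standardized by their *population*
moments (computable in closed form from the item structure, so
generation works at n = 1), dummies are 0/1, and the default σ is set
so Var(y) = 1, making the configured βs standardized effects.  Preset
effect signs follow the study's reported directions (conflict and
pandemic stress harmful everywhere, resilience protective; in China
grandparental support, marriage and more children protective while high
education, income and poor physical health are risks; in Italy younger
age and poor health are risks; in the Netherlands high education and
unemployment are risks); magnitudes (0.06–0.25) are free parameters
chosen once to give realistic adjusted R² ≈ 0.10–0.15.  Buffering
interactions default to −0.06 for resilience × work stress in CN and
resilience × life/work stress in NL.

y is exported as a ground-truth column (`latent_mental_health`).
Because the observed composite is a thresholded, noisy function of y
(corr ≈ 0.97 at defaults), regressions on the composite recover the
configured effects only up to that attenuation factor; exact-recovery
invariants are therefore asserted against the latent column, and all
search/transfer/moderation properties — which use the composite — are
qualitative (signs, ordering, error rates).

**Randomness.**  One integer seed, with the country label folded into
the entropy, is expanded into named substreams (demographics and one
per scale), so adding a scale never perturbs the others and identical
configs give byte-identical tables.

### What the generator does not emulate

Nonresponse and snowball-sampling network structure, regional
heterogeneity within countries, demographic dependence (e.g. age ×
parity), floor effects and skew of real symptom items (equal-probability
bins give symmetric item marginals), and country differences in scale
means (latent means default to 0).  Passing tests therefore demonstrate
the correctness and calibration of the *pipeline*, not substantive
conclusions about any real population.

## 5. Problem sizes used in the shipped checks

Unit and property tests run at n ≤ 3000 with p ≤ 8 factor subsets;
the selection-consistency check uses 25 datasets × 20 repeats at
n ∈ {200, 800, 3200}; transfer diagonal optimality uses 10 generator
seeds at n = 800; the moderation type-I check uses 200 replicates at
n = 400; subscale calibration uses one n = 50 000 cohort.  These sizes
were chosen to make the full suite run in a few minutes on one CPU
while leaving each check's Monte-Carlo margin well clear of its
threshold.
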