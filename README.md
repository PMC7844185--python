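# maternalcv

Cross-validated all-subsets model selection for multi-country maternal
mental-health survey cohorts, with a calibrated synthetic cohort
generator.

## The problem

During a pandemic lockdown, which combination of risk and protective
factors best *predicts* maternal mental-health symptoms — and does the
winning combination travel between countries?  This package implements
that analysis as a reusable, fully seeded pipeline for survey cohorts
from China (CN), Italy (IT), and the Netherlands (NL):

1. **Scoring.**  Likert questionnaires are turned into composites:
   a 27-item mental-health scale (mean, 1–5; four correlated symptom
   subscales), 14-item resilience (sum, 14–70), 7-item pandemic life
   stress (sum, 7–28), a single 1–10 work-stress item, a 13-indicator
   job-change count (0–13), 6-item family conflict (sum, 6–30) and
   20-item father involvement (mean, 1–5), plus Cronbach's α and
   Pearson correlations for reliability checks.
2. **All-subsets search.**  With p = 15 candidate factors, every one of
   the 2¹⁵ = 32 768 linear models is evaluated by repeated 10-fold
   cross-validation.  The criterion is the root mean squared error of
   prediction, RMSEp = √( (1/n) Σᵢ (yᵢ − ŷ₍₋fold₎ᵢ)² ), where each
   observation is predicted by a model fit on the other nine folds.
   Within a repeat all models share one partition; the model with the
   smallest RMSEp "wins" the repeat, and winner percentages over R = 200
   repeats measure selection stability.
3. **Transfer validation.**  Each country's winning factor subset is
   re-fitted (coefficients re-estimated) under repeated CV on the other
   countries' data, producing a 3×3 grid of RMSEp distributions.
4. **Robust refit.**  The winning model is refit on the full cohort as a
   standardized OLS regression with HC3 sandwich standard errors, Wald
   z-tests and the plain-OLS adjusted R²; a post-hoc moderation analysis
   adds resilience × stress interaction terms and reports simple slopes.

Because raw survey data of this kind are rarely shareable, the package
ships a **synthetic cohort generator** whose presets reproduce the
published statistical structure — sample sizes (922/641/900),
grandparental-support prevalences (53.6 % / 18.3 % / 9.4 %), scale
reliabilities (α = 0.96, 0.89, 0.85, 0.85, 0.83, 0.82), the
job-change–work-stress correlation (r ≈ 0.35), and the band of
subscale correlations (0.776 < r < 0.961) — so every stage is testable
end to end.

## Worked example

```python
import maternalcv as m

catalog = m.default_catalog(("grandparental_support", "n_children", "resilience",
                             "life_stress", "work_stress", "family_conflict"))
cohort = m.generate_cohort(m.country_preset("CN", n=400, seed=11))
scored = m.score_cohort(m.apply_inclusion_filter(cohort))

result = m.run_search(scored, catalog, m.CVConfig(folds=10, repeats=50, seed=1))
print(m.top_models_table(result, 3).to_string(index=False))
fit = m.fit_winning_model(scored, result.best_model(), catalog)
print(fit.table.round(3))
print(f"adjusted R2 = {fit.adj_r2:.3f}, n = {fit.n}")
```

prints

```
 rank  mask  n_factors                                                                                                           formula  mean_rmse  win_count  win_pct
    1    63          6 mental_health ~ 1 + n_children + grandparental_support + resilience + life_stress + work_stress + family_conflict   0.944178         31     62.0
    2    47          5               mental_health ~ 1 + n_children + grandparental_support + resilience + life_stress + family_conflict   0.944302         17     34.0
    3    62          5              mental_health ~ 1 + grandparental_support + resilience + life_stress + work_stress + family_conflict   0.945810          1      2.0

                        beta     se      z      p
intercept              0.117  0.068  1.729  0.084
n_children            -0.090  0.048 -1.872  0.061
grandparental_support -0.228  0.096 -2.378  0.017
resilience            -0.197  0.047 -4.204  0.000
life_stress            0.141  0.046  3.050  0.002
work_stress            0.072  0.048  1.485  0.138
adjusted R2 = 0.104, n = 400
```

The full six-factor model wins 62 % of the 50 cross-validation repeats
(a five-factor neighbour takes most of the rest), and the standardized
refit shows the generating structure of the Chinese preset: family
conflict and pandemic stress raise symptom levels, while resilience,
grandparental child-care support, and having more children lower them.
One standardized β unit is one outcome standard deviation per predictor
standard deviation (for the binary support indicator: the gap between
supported and unsupported mothers).

## Command line

```bash
matcv simulate --country CN --n 922 --seed 1 --out cn.csv
matcv score    --cohort cn.csv --out cn_scored.csv
matcv search   --cohort cn_scored.csv --country CN --folds 10 --repeats 200 \
               --seed 1 --engine gram --top 3
matcv transfer --cohorts CN=cn_scored.csv,IT=it_scored.csv,NL=nl_scored.csv \
               --models models.json --repeats 200 --seed 1 --out transfer.csv
matcv fit      --cohort cn_scored.csv --model model.json --robust hc3
matcv all      --config pipeline.yaml    # simulate→score→search→transfer→fit→report
matcv report   --dir out/
```

`matcv all` writes every artifact as CSV plus a `manifest.json` with a
SHA-256 per file; rerunning the same config reproduces identical hashes.

## Layout

- `src/maternalcv/synthetic.py` — seeded cohort generator and its
  reliability/correlation calibrations
- `src/maternalcv/psychometrics.py` — inclusion filter, composite
  scoring, Cronbach's α, correlations
- `src/maternalcv/model_search.py` — design coding, fold partitions,
  the gram/naive CV engines, the all-subsets search
- `src/maternalcv/transfer.py` — cross-country transfer validation
- `src/maternalcv/inference.py` — standardized HC3 refits, moderation,
  descriptive group comparisons
- `src/maternalcv/pipeline.py`, `cli.py` — orchestration, manifest,
  report, `matcv` entry point
- `docs/methods.md` — model assumptions, calibration math, numerical
  choices, and known limitations
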