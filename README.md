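# kittengrowth

Tools for analysing early postnatal growth and 0–2 month survival in kitten
cohorts, aimed at veterinary epidemiologists and feline-breeding researchers.
Mortality of live-born kittens over the first two months is high (commonly
around 7–10%), and both low birth weight (LBW) and slow growth over the first
week are major risk factors. This package implements the full analysis chain
from raw daily weighings to actionable early-growth alarm thresholds, plus a
synthetic-cohort generator so every stage can be exercised and validated
without access to proprietary cattery data.

## What it computes

Given a cohort table (one kitten per row: breed, litter, sex, daily weights
Day 0–7 in grams, status at 2 months, day of death when known) and a
breed-specific birth-weight threshold table:

1. **Selection and classification.** Kittens with a birth weight and a known
   2-month status are retained; each is classified LBW if its birth weight is
   strictly below its breed's threshold, NBW otherwise.
2. **Growth rates.** Five relative growth rates
   `GR x–y = 100 · (w_y − w_x) / w_x` over the intervals 0–1, 1–2, 0–2, 2–7
   and 0–7 days, plus the seven single-day rates. Kittens with any rate
   strictly outside the species-level Tukey fences
   `[Q25 − 1.5·IQR, Q75 + 1.5·IQR]` are excluded; missing rates never
   exclude.
3. **Descriptive comparisons.** Per-interval means/SDs overall and by
   birth-weight category, Welch *t*-tests with Cohen's *d* effect sizes,
   weight-loss fractions, daily-rate means with paired comparisons.
4. **Mortality modelling.** A saturated binomial GLM with logit link on the
   2×4 factorial (birth-weight category × species-level growth-rate quartile
   group), fitted by IRLS, for three survivor-conditioned windows (Day 1,
   Day 2 and Day 7 to 2 months); estimated marginal means with delta-method
   SEs, Tukey-adjusted pairwise contrasts and a compact letter display;
   per-period (0–2 / 3–21 / 22–60 days) chi-square comparisons of death
   timing; Wald/Wilson binomial CIs and mortality-rate ratios.
5. **Alarm thresholds.** For each category × growth interval, a
   cost-sensitive depth-1 CART (Gini criterion with the death-class prior
   inflated by the 10:1 false-negative : false-positive cost ratio) is fitted
   on the training side of each of 10 stratified folds; the alarm threshold
   is the median of the fold cutpoints, and screening performance
   (Se/Sp/PPV/NPV, mortality below vs at/above the threshold, multiplication
   term) is reported on the full subset.

The synthetic generator (`kittengrowth.simulate`) produces cohorts with
configurable litter structure, breed-specific birth weights, category-specific
multiplicative daily growth, logit-linear (or planted-step) mortality in
week-one growth, neonatal-concentrated death timing and missing weighings —
reproducibly from a single seed.

## Worked example

```python
from kittengrowth import SimConfig, simulate_cohort, breed_threshold_table, run_pipeline

cfg = SimConfig(seed=1)                      # ~5,500 kittens, default conditions
records = simulate_cohort(cfg)
report = run_pipeline(records, breed_threshold_table(cfg))

m = report["mortality"]
print(f"n = {m['n']} kittens, deaths = {m['deaths']} "
      f"({m['mortality_pct']:.1f}%, 95% CI [{m['ci_pct'][0]:.1f}, {m['ci_pct'][1]:.1f}])")
print(f"LBW vs NBW mortality: {m['by_category']['LBW']['mortality_pct']:.1f}% vs "
      f"{m['by_category']['NBW']['mortality_pct']:.1f}% (ratio {m['lbw_nbw_ratio']:.1f})")
g = report["growth"]["intervals"]["0-7"]
print(f"GR 0-7: LBW {g['LBW']['mean']:.1f}% vs NBW {g['NBW']['mean']:.1f}% "
      f"(Welch p = {g['welch']['p']:.2g}, d = {g['welch']['cohens_d']:.2f}, "
      f"{g['welch']['effect_label']})")
row = next(t for t in report["thresholds"]
           if t["bw_category"] == "LBW" and t["gr_interval"] == "0-7")
print(f"LBW GR 0-7 alarm threshold: {row['threshold']:.1f}% "
      f"(mortality below {row['mortality_below']:.1f}% vs above {row['mortality_above']:.1f}%, "
      f"Se {row['se']:.2f}, Sp {row['sp']:.2f})")
```

prints

```
n = 5436 kittens, deaths = 385 (7.1%, 95% CI [6.4, 7.8])
LBW vs NBW mortality: 19.5% vs 4.1% (ratio 4.8)
GR 0-7: LBW 97.4% vs NBW 86.9% (Welch p = 4.8e-26, d = 0.46, small)
LBW GR 0-7 alarm threshold: 110.0% (mortality below 11.4% vs above 3.0%, Se 0.90, Sp 0.32)
```

Overall mortality lands near the
configured 7.4% with LBW kittens dying at roughly 4–5× the NBW rate; LBW
kittens grow about 10 percentage points faster over week one (compensatory
growth), and the derived LBW alarm threshold flags slow growers whose
mortality is several-fold that of their fast-growing peers.

A command-line interface mirrors the library:

```bash
kittengrowth simulate --seed 1 --out cohort.csv
kittengrowth report --cohort cohort.csv --breeds cohort.breeds.csv --seed 1 --out report.json
```

(`describe`, `glm` and `thresholds` run individual stages.)

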