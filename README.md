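# mazetrait

Longitudinal cognitive phenotyping of mice: is cognitive ability a stable,
individually identifiable trait across the adult lifespan?  Longitudinal
studies track the same animals through repeated test batteries — open field,
novel-object recognition/location, and a nine-arm radial maze — at 4, 8, 12
and 18 months of age, and ask whether an individual's performance early in
life predicts its performance in old age.  `mazetrait` implements the full
analysis pipeline for such studies, plus a synthetic-cohort generator so that
every stage is testable without animal data.

## What it computes

**Radial-maze metrics** (per mouse, per 16-day session).  A trial ends after
10 minutes or nine arm entries.  From the ordered arm entries the pipeline
derives:

- mean decision-making time, `DMT = mean over days of T_trial / (n + 1)`
  (n = arm entries; the +1 keeps a zero-entry trial finite);
- mean daily errors, `E = entries − distinct arms`;
- the unique-sequence score.  Each trial's entry list is parsed greedily into
  maximal repeat-free segments ("unique sequences"); with `f_i` the number of
  segments of length `i`, `USS = Σ_i i·f_i²`, averaged over days;
- learning rate (negated slope of daily errors vs. day);
- exploration ratio (fraction of the maze's 27 non-centre regions entered);
- cumulative arm time and mean running speed;
- the circular offset histogram of consecutive arm choices (−4…+4; mice
  prefer moves of ±2 arms).

**Null model.**  A stochastic agent choosing arms uniformly at random (nine
entries per trial, re-entries allowed) yields a pooled unique-sequence length
distribution with mode **2** — the chance benchmark real mice beat.  An exact
closed form for the first-segment length distribution serves as the
simulator's analytic oracle.

**Trait statistics.**  Within each age, metrics are standardised
(`Z = (x − μ)/σ`, population σ; decision time and errors sign-inverted so
higher = better) and combined per mouse with Stouffer's method
`Z = Σ Z_i / √k`.  Cross-age prediction fits late-age on early-age combined
scores with an optionally slope-penalised least-squares line
(`loss = Σ residual² + λ·slope²`, λ = 0 by default) and reports Pearson's r,
R² and the F-test p-value.  An exhaustive search scores all
`2¹¹ − 1 = 2047` metric subsets by mean R² across age comparisons; a
resampling scheme (all subset sizes × n draws, 441 datasets for 21 mice) maps
the variance of r against degrees of freedom; and a consensus screen flags
mice showing concordant adverse trends in ≥ 3 of the five maze metrics.

**Synthetic cohorts.**  Each mouse carries a stable trait `g ~ N(0,1)`; its
session ability per behavioural channel at age t is
`a(t) = √ρ·g + √(1−ρ)·ε_t`, so any two ages correlate at the planted ρ
(maze 0.7, speed 0.3, object preference 0.0 by default).  Age effects
(weight gain, open-field slowing, rising outer-zone occupancy) and an
optional planted "decliner" mouse complete the study design.

## Worked example

```python
import mazetrait as mt

spec = mt.CohortSpec(seed=42, n_mice=22, ages=(4, 18))
data = mt.simulate_cohort(spec)
tables = mt.build_metric_tables(data.blocks.values(), data.bouts)

z4, z18 = mt.zscore(tables[4]), mt.zscore(tables[18])
fit = mt.predictive_correlation(z4, z18, ["USS"])
print(f"USS 4->18 months: r = {fit.r:.3f}, R^2 = {fit.r_squared:.3f}, "
      f"p = {fit.p_value:.2e}, n = {fit.n}")

ranking = mt.combination_search({4: z4, 18: z18}, list(mt.METRIC_NAMES),
                                age_pairs=((4, 18),))
print("subsets evaluated:", len(ranking))
```

prints

```
USS 4->18 months: r = 0.652, R^2 = 0.425, p = 1.01e-03, n = 22
subsets evaluated: 2047
```

The unique-sequence score of this 22-mouse synthetic cohort at 4 months
explains ~43 % of the variance in the same metric at 18 months — the planted
inter-age trait correlation (ρ = 0.7) recovered from 16 trials per age.  The
search enumerated every one of the 2047 possible metric combinations.

The same steps are available from the shell:

```sh
mazetrait simulate --seed 42 --out cohort/
mazetrait metrics --events cohort/events.csv --trials cohort/trials.csv \
                  --bouts cohort/bouts.csv --out metrics/ --seed 42
mazetrait stability --metrics-dir metrics/ --out stability/ --seed 42
mazetrait nullmodel --seed 0 --out null.tsv    # prints: modal length 2
```

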