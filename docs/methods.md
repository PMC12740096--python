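# Methods

## Radial-maze scoring conventions

A trial ends after 600 s or after **nine arm entries, revisits included**.
Reading the termination rule as nine *entries* (rather than nine distinct
arms) is what makes daily error counts of the observed magnitude possible at
all — with a nine-distinct-arms rule every trial would end error-free only at
the ninth distinct arm and errors would be unbounded in time, not in count.

**Decision-making time.** `DMT = mean over observed days of T_trial/(n+1)`.
The per-day quantity is divided by `n+1` so a day with zero arm visits still
yields a finite value (600 s).  When days are missing the mean divides by the
number of observed days, not 16.

**Unique-sequence decomposition.**  The entry list is parsed greedily left to
right.  A segment accumulates entries until one repeats an arm already inside
the segment; that repeated entry closes the segment *and* opens the next one,
so the segments partition the entry list and no unique sequence is nested in
another.  The trailing segment counts even when no repeat closed it
(otherwise error-free full trials could never contribute a length-9
sequence).  Identification is not limited to the start of the trial.
`[0,1,2,1,3]` parses to lengths `[3,2]`; `[0,0,0]` to `[1,1,1]`.

**USS.**  Per trial, `USS = Σ_i i·f_i²` over the per-trial length counts
`f_i`; the session score is the mean over days.  Per-trial (not
session-pooled) counts are used: pooling would square summed counts and
inflate the score far beyond the scale on which it is interpreted.  Note the
formula is *not* monotone in performance for all count configurations —
many equal-length segments score higher than their entry count — but the
printed formula is authoritative and is implemented literally.

**Adjacent-arm offsets.**  For consecutive entries a→b on nine arms,
`offset = ((b − a + 4) mod 9) − 4 ∈ {−4..+4}`; re-entry scores 0 and the
wrap-around means 8→1 is +2.

## Null model

The default kernel is uniform-iid over all nine arms with same-arm
re-entries allowed, nine entries per trial, 16 trials per agent, agent count
matching the compared cohort.  This is the simplest model consistent with
re-entries being a scored behaviour, and it reproduces the chance benchmark:
the pooled unique-sequence length histogram has mode 2 (checked over
multiple seeds).  A no-immediate-repeat kernel and an arbitrary
offset-weighted kernel are available for comparison; the no-repeat kernel
shifts mass upward but leaves the pooled mode at 2–3, so the benchmark does
not hinge on allowing re-entries.  The exact first-segment length law under
iid choice, `P(L=k) = [Π_{j<k}(n−j)/n]·k/n` (no-repeat event folded into
k = n), is implemented as an independent oracle; its mode for nine arms is 3,
which also documents that pooled-segment and first-segment statistics are
different quantities.

Mode ties are reported explicitly and broken toward the smaller length.

## Standardisation and combination

Z-scores use the **population** standard deviation (no n−1 correction) by
default, with a switch; the choice scales every Z by a common factor and is
recorded in the table metadata.  Decision time and errors are inverted
*after* standardisation.  Stouffer combination is `Σ Z_i/√k` with k the
per-mouse count of available metrics; mice with no available metric become
missing.  Undefined object preferences (zero exploration) propagate as
missing values with a logged warning — never as 0 — because near-zero
exploration is a real phenotype that must stay visible.

## Penalised linear fit

The stability fit minimises `Σ(y − (w0·x + w1))² + λ·w0²` with closed form
`w0 = Sxy/(Sxx + λ)`, `w1 = ȳ − w0·x̄`.  The intercept is unpenalised, so
λ = 0 is exactly OLS and λ→∞ gives the mean predictor.  λ defaults to 0 and
is a configuration knob, never silently nonzero.  Significance is the
F-test of the unpenalised simple regression (identical to the slope t-test);
r is the plain product-moment correlation, and R² = r² for these simple
fits.  Only the slope-penalty reading of "weighted" regression is
implemented; per-observation weighting is not.

## Combination search and resampling

The search enumerates every non-empty subset of the 11 registered metrics
(2047 with the full universe), scoring each by the mean R² over the age
comparisons 4→8, 4→12, 4→18 (configurable — the set of pairs entering the
average is a convention, not a derived fact).  Ranking ties break
lexicographically on sorted metric names, so the ordering is deterministic.

The resampling curve draws, for every subset size s = 1..n, n random mouse
subsets without replacement (n² resampled datasets in total — 441 for a
21-mouse cohort), fits each subset of size ≥ 3, and reports the variance of
r per degrees of freedom (dof = s − 2).  Sizes 1–2 are scheduled but
unfittable and excluded from the curve; at s = n only one subset exists, so
the variance there is exactly 0.  The exact scheme behind a "441-fit"
resampling analysis is a documented convention of this package.

## Decline screening

For each mouse and each of the five maze metrics (USS, errors, DMT,
exploration ratio, cumulative arm time), a day-level OLS regression against
age in months is fitted (up to 64 points: 16 days × 4 ages).  A metric
counts as adverse when

1. the slope has the metric's adverse sign (USS, exploration ratio, arm
   time: negative; errors, DMT: positive),
2. p < α/5 (Bonferroni over the five metrics; α = 0.05), and
3. the standardized slope — slope per mean age step, in units of the
   cohort's between-mouse population SD of that metric, estimated
   leave-one-out and pooled over ages — exceeds 0.60.

A mouse is flagged at ≥ 3 adverse metrics.  The effect-size threshold is
essential, not cosmetic: when the underlying trait genuinely fluctuates
between ages (inter-age correlation < 1) and day-level noise is modest,
*every* mouse's small real fluctuations reach statistical significance, so
raw p-values alone would flag most of a cohort.  Requiring a slope of at
least 0.6 population-SD per age step separates monotone decline from
ordinary trait wander; under the generator's defaults the screen flags a
planted decliner and nothing else in ≈ 98 % of cohorts and raises no flag
at all in ≈ 95 % of stable cohorts.  Raw-p behaviour is available via
`bonferroni=False, min_slope=0`.

## Synthetic cohort generator

The generator emulates the *design* of a longitudinal study — 22 female
mice (with an optional 58→46→31→22 attrition schedule), ages 4/8/12/18
months, 16 maze trials per age, four object tasks, open-field sessions and
weights — and the *structure* of its findings, so that pipeline properties
(trait recovery, decliner detection, predictive dissociation) are testable
against known ground truth.

**Latent model.**  One stable trait `g ~ N(0,1)` per mouse; per age and per
behavioural channel c ∈ {entry latency, arm choice, region exploration, arm
dwell}, ability `a_c(t) = √ρ·g + √(1−ρ)·ε_{c,t}` with ρ = 0.7 for all maze
channels.  This compound-symmetric form makes the correlation between *any*
two ages exactly ρ, which is the quantity the 4-vs-18-month analysis
estimates.  The per-age fluctuations are drawn independently per channel so
that the five maze metrics do not share one spurious age trend; decline, by
contrast, is planted at the trait level and therefore hits every channel
coherently — exactly the signature the consensus screen requires.  Speed
has its own trait (ρ = 0.3), object preference its own per-task latents
(ρ = 0.0), thigmotaxis ρ = 0.3.

**Mechanism.**  Ability acts primarily on entry latency: the median
inter-entry interval is `105 / max(0.12, 1 + 0.24·a_latency)` s with
lognormal (σ = 0.06) trial noise, so the expected number of entries within
the 600 s budget is approximately linear in ability and the session-mean USS
inherits that linearity across the whole ability range.  Revisit propensity
falls weakly with choice ability (already-visited arms are down-weighted by
`min(1, 0.06·e^(−0.2·a_choice))`), arm choices follow an offset kernel with
weights (0.15, 0.25, 0.9, 0.5, 0.1, 0.5, 0.9, 0.25, 0.15) over offsets
−4..+4 (peaked at ±2, trough at re-entry), per-visit dwell is
`18·e^(0.2·a_dwell)` s lognormal-jittered and capped by the inter-entry gap,
and bridge-only/outer-centre visits follow logistic functions of the
exploration channel.  An alternative in which ability acts mainly on revisit
propensity was piloted and rejected: per-trial USS variance from
segment-length collisions is so large, and the mean response so shallow and
non-monotone, that the planted correlation cannot be recovered from 16
trials per age (session reliability ≈ 0.3).  Identifiability of the planted
trait under the study's own design was the deciding criterion.

**Age effects.**  Weight starts at ≈ 22 g and grows strictly (increments
0.45 g/month, lognormal-jittered); open-field speed declines from
12.71 cm/s at 4 months by 0.26 cm/s/month; outer-zone occupancy rises from
72.9 % by 0.67 %-points/month.  Maze metrics carry no cohort-level age
trend — stability is the phenomenon under study.

**Decliner.**  When enabled (off by default), one mouse's abilities drop by
1.5 latent SD per age point on every channel from the onset age (default
mouse index 20, onset 8 months).  Its phenotype is the concordant one:
fewer entries, lower USS, longer decision times, shrinking exploration
ratio and arm time.  Because entries collapse, its *error count* falls
rather than rises — with few entries there is little left to revisit — so
errors is the one maze metric the screen cannot rely on; the consensus rule
(3 of 5) absorbs this.

**Randomness.**  All draws flow from one seed through named `SeedSequence`
streams: traits per mouse, age-level fluctuations per (mouse, age, channel),
within-trial draws per (mouse, day).  Adding a mouse therefore never
perturbs another mouse's data, regeneration is byte-identical, and because
the within-trial stream omits the age, a fully degenerate cohort (all
ρ = 1, `noise_scale = 0`, zero age slopes) produces *identical* trials — and
metric tables — at every age.

**What the generator does not emulate, and what passing tests show.**
There are no spatial trajectories, no oestrous or housing covariates, and no
attempt to match a real cohort's printed metric means: under the default
calibration mean USS is ≈ 5.2, daily errors ≈ 0.15 and decision time
≈ 100 s, whereas a real, maze-habituated cohort sits nearer 8.7, 3.2 and
64 s.  Matching a 3-errors/day regime is directly at odds with recovering
the planted correlation (collision noise destroys session reliability), and
the recovery calibration takes precedence.  Passing tests therefore
demonstrate that the *pipeline* is correct and well-calibrated under a
faithful study design — not that real mice have these particular parameter
values, and real-data correlation magnitudes are expressly outside what
synthetic data can certify.

## Problem sizes and numerics

The recovery study uses 200 replicate 22-mouse cohorts at two ages; the
decliner and false-flag studies use 60 and 40 four-age cohorts; the
dissociation summary uses 30.  These sizes put Monte-Carlo error well below
the decision margins (e.g. SE ≈ 0.009 on the mean recovered r).  Measured
under the defaults: mean recovered r ≈ 0.67–0.68 vs. planted 0.7 (the gap
is session-noise attenuation plus the small-sample bias of Pearson's r at
n = 22), Fisher-interval coverage 93–94 %, decliner-only flag rate ≈ 98 %.
Degenerate inputs fail loudly: empty blocks, constant metric columns,
constant regressors and zero exploration all raise or flag rather than
returning silent zeros.  Ranking and mode ties break deterministically
(lexicographic; smaller length), and every table writer records the seed,
package version and configuration hash in its header.

## Known limitations

- The penalised fit's p-value comes from the unpenalised model; for λ > 0
  it is a reference test, not an exact one.
- Decline screening assumes 16-day sessions at ≥ 3 ages; sparser designs
  lose most of their power at n = 4 points per metric.
- The generator's channel decomposition is one of several latent structures
  consistent with a single stability coefficient; it was chosen for
  identifiability and decliner specificity, not inferred from data.
- Open-field and object measures are generated but excluded from the
  cognitive combination by design; they serve as negative controls.
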