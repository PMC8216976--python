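# Methods

## The random-pairing null

Sampled two-animal associations are modeled as a pool of `m` males and
`n` females (derived from the pairs themselves, so `m + n = 2N`) paired
by a **uniform perfect matching** with an **independent fair
orientation** per pair (each animal equally likely to be marker/tracker,
or bottom/top).  The per-pair marginal of this model — two draws without
replacement and a coin for roles — gives the expected counts

    E[FM] = E[MF] = ½mn/(m+n−1),  E[MM] = ½m(m−1)/(m+n−1),
    E[FF] = ½n(n−1)/(m+n−1)

whose sum telescopes to `½(m+n)(m+n−1)/(m+n−1) = N` exactly; the code
computes the mixed term once so `E[FM] == E[MF]` holds to the bit.  Two
oracles check the implementation independently: exhaustive enumeration
of all matchings × orientations for pools of up to 12 individuals
(equal to the closed form within 1e−12), and a vectorized Monte-Carlo
simulation (means within three standard errors at 10,000 replicates).

Chains of three or more trail followers are represented by their two
leading animals only, which is how the field protocol sampled them, so
the pair model applies unchanged.

## Goodness of fit, degrees of freedom and calibration

Observed counts are tested with Pearson's χ² over the categories with
positive expectation; `df = retained − 1` (3 in the usual four-category
case).  Categories with zero expectation arise only for single-sex
pools, necessarily have zero observed count, and are dropped with the
df reduced.  Any expectation below 5 triggers a recorded warning and a
recommendation to use the Monte-Carlo p-value.

A structural subtlety matters for calibration.  Because the matching
conserves both sex totals, the four counts obey *two* linear
constraints (`ΣO = N` and `2·MM + FM + MF = m`), not one.  Writing `K`
for the number of mixed pairs, the statistic decomposes into a
`(K − E[K])²` term and an orientation term, i.e. roughly a chi-square
with **two** degrees of freedom.  Referring it to `chi2(df = 3)` —
the conventional choice, and the one used for all reported statistics —
is therefore *conservative* under this null: the simulated type-I error
at α = 0.05 is about 2% (the suite pins it in [0.005, 0.04] over 2,000
simulated null tables).  The Monte-Carlo p-value (rank of the observed
statistic in the simulated matching null, with the add-one estimator
`(1 + #{χ²_sim ≥ χ²_obs})/(1 + R)`) is calibrated by construction and
is the package's recommended inference route whenever exactness
matters; its type-I error sits inside the 95% binomial envelope of the
nominal level.  For the published tables the two routes agree on every
significance call, because the effects are either very large or clearly
absent.

Reported output mirrors field convention: expectations rounded to 1
decimal place, χ² to 2, significance annotated `< .001` / `< .05` /
`n.s.` at α = 0.05, with the raw p-value always retained.

## Incomplete tables

An aggregated input may declare a total `N` and omit exactly one
combination row; the missing count is inferred as `N` minus the others
and flagged in the table and every downstream report.  This is needed
for the packaged *E. radiata* falling-tide trail table, which is
published without its FF row (FF = 33 from N = 120).

## The preference model and its estimator

The alternative to the null is a single parameter θ ∈ [0, 1]: each pair
is, with probability θ, a *directed* event — one female (marker/bottom)
and one male (tracker/top) removed from the remaining pool — otherwise
a null pair (two uniform draws, fair orientation).  θ = 0 reduces
exactly to the matching null.  When a directed event is infeasible
because a sex is exhausted, the pair falls back to null formation and
the fallback is counted in the ground-truth record.

The moment estimator `θ̂ = (O_FM − E_FM)/(N − E_FM)` (clipped to
[0, 1]) is unbiased to first order because null pairs contribute
`≈ E_FM/N` each and directed pairs contribute 1.  Two effects bias it
downward as θ grows on pools that use up one sex: fallbacks replace
directed events, and late null pairs are drawn from a sex-skewed
residual pool.  An exact dynamic-programming recursion over the
(males, females) state — used in the suite as an independent oracle for
the generator — quantifies this: at the default table geometry
(m = 132, n = 120, N = 126) the mean estimate is within 0.02 of truth
for θ ≤ 0.6 but about 0.03 low at θ = 0.8.  This is a property of the
estimator/generator pair, not a sampling artifact; users probing strong
preference on nearly exhausted pools should prefer the simulated
ground-truth record (directed-event count) over θ̂.

`power_curve` estimates rejection rates over a θ grid with binomial
standard errors, using either the analytic p-value or the Monte-Carlo
critical value from a single shared simulated null (10,000 replicates
by default) — the latter is the calibrated option, for the reason above.

## Activity budgets

The ethogram maps nine behaviors to four fitness-associated categories
(mating, fighting → reproduction; moving, turning → foraging — any
movement is ascribed to foraging because grazing is unobservable;
in-crevice, towering, standing, aggregating → stress mitigation;
stationary → inactive).  Scoring follows two rules: within a category
an individual counts once per scan however many of its behaviors it
shows; across categories it may count several times, so hourly behavior
percentages and category allocations can exceed 100%.

Hours bin on the hour, half-open `[h, h+1)`, pooling quadrats within
the hour; hours without records are absent from output (missing, never
0%).  Seasonal allocation defaults to **pooled individual-scans**
(`100 × flagged scans / total scans`), which matches the quadrat-count
design and is robust to unequal per-hour abundance; an
`basis="hourly_mean"` alternative weights each hour equally.  Both are
exposed because published seasonal percentages do not state their
aggregation basis, and neither mode is claimed to reproduce them (the
raw survey records are not published).

## Temperature summaries

Seasonal range is the min/max over all loggers and sites.  "Percent of
days exceeding T" is operationalized as *daily maximum strictly greater
than T* on local calendar dates with data, pooling a site's loggers by
max (a day is hot if any logger saw it); both choices are configurable
(`strict=False`, `pool_loggers="mean"`, `daily_stat="mean"`), and a
reading-level alternative (`pct_readings_exceeding`) is provided since
the published percentages do not define their denominator.  The safety
margin is `LT50 − seasonal max`, with percent of hourly readings above
the ABT when one is supplied.  Gaps in hourly cadence are flagged, not
imputed.

## Synthetic generators

All generators are deterministic given a seed.

* **Pairs** — the preference process above, with full bookkeeping
  (directed events, fallbacks) emitted as truth.
* **Scans** — a pure sinusoidal semidiurnal tide (period 12.42 h)
  classifies each hour as awash-rising / awash-falling / emersed /
  submerged relative to a snail band height; behavior sets (including
  multifunctional combinations such as mating+moving at 10% of
  awash-rising scans) are drawn from per-phase categorical tables.  The
  default hot-season table allocates activity to foraging and
  reproduction while awash and shell-posturing/sheltering while
  emersed; the cool-season table has no reproduction, no standing or
  towering, and <1% foraging, dominated by crevices and aggregation —
  the qualitative seasonal contrast observed in the field.  Not
  emulated: spatial structure, wave action, abundance fluctuating with
  tide, between-individual persistence across hours; passing round-trip
  tests therefore validates the scoring arithmetic, not field realism.
* **Temperatures** — day `d` has peak `P_d ~ N(peak_mean, peak_sd)` at
  a fixed peak hour, with a cosine diurnal cycle of configurable range
  (default 18 °C) below it and optional reading noise (default 0, so
  daily maxima equal the drawn peaks exactly).
  `ThermalScenario.for_exceedance(T, f)` sets `peak_mean` from the
  normal quantile so daily maxima exceed `T` with long-run frequency
  `f`; realized frequencies land within binomial noise of the target at
  the default 79-/73-day season lengths.
  `ThermalScenario.from_envelope(lo, hi)` affinely rescales the
  realized season to hit a target min/max exactly (a rescale, never a
  clip).  Weather autocorrelation and multi-day heat waves are not
  modeled.

## Problem sizes and numerical choices

The validation suite runs at desk scale chosen to keep Monte-Carlo
error well inside the tolerances it asserts: 2,000 replicates for null
calibration, 1,000 per θ for estimator recovery, 10,000 for the
simulated null distribution, exhaustive enumeration up to 10–12
individuals, 24–48 h scan surveys of 30–200 snails, 73–79-day logger
seasons.  Ties in the Monte-Carlo p-value are broken conservatively
(`≥` comparison with a 1e−12 slack against float error); reports are
bit-stable for fixed inputs and seed.

## Known limitations

* The analytic df = 3 p-value is conservative under the matching null
  (above); published significance calls are unaffected.
* θ̂ under-recovers strong preference on sex-limited pools (above).
* The generators emulate marginal structure (phase-conditional
  behavior frequencies, daily peak distributions), not temporal or
  spatial dependence; published seasonal budget percentages and logger
  summaries rest on unpublished raw records and are therefore covered
  by envelope and round-trip tests, not numeric reproduction.
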