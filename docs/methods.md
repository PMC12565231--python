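# Methods

## Data model and conventions

The unit of observation is one adult female followed daily from
emergence (age 0) to death, with host-exposure events recorded as
(maternal age, hosts offered, daughters, sons).  Conventions:

- Ages are integer days, closed-open intervals [x, x+1).  A female with
  `age_at_death = d` is alive at the start of ages 0..d−1; the cohort
  schedule therefore runs over ages 0..x_max−1 (the last tabulated age
  always has at least one survivor) and survivorship is implicitly zero
  one age past the table.  With `T_x = Σ_{y≥x} l_y` this makes
  `e_0` equal the arithmetic mean lifespan exactly on integer-day data,
  which the tests assert.
- Daughters and sons are counted at their own adult emergence but
  attributed to the maternal age on the exposure day, so `m_x` is a
  per-day schedule with zeros on non-exposure days (exposures run every
  other day from day 2).  Semi-field trials stop exposures after day 19;
  `m_x` beyond that age is structurally zero while survival is still
  followed — no imputation.
- `p_x`/`q_x` at the final tabulated age are defined as 0/1 (the whole
  remaining cohort dies), avoiding a division by zero.
- `l50` (median survival) is the first whole-day age with `l_x ≤ 0.5`,
  not an interpolated value; for a fully observed (extinct) cohort whose
  tabulated `l_x` never reaches 0.5 it is the extinction age, and for a
  censored schedule it is reported as not reached (`None`).
- The offspring sex ratio is pooled daughters over pooled sons; a cohort
  with daughters but no sons returns an `ALL_FEMALE` sentinel rather
  than a number.

## Population-increase parameters

`R0 = Σ l_x m_x` and the cohort generation time `T = Σ x l_x m_x / R0`
are plain sums.  The intrinsic rate r is computed in two modes, recorded
in every result:

- **ratio** (default): `r = ln(R0)/T`.  The identity `r·T = ln R0` then
  holds exactly, which is the relation the printed parameter tables this
  package mirrors satisfy at two decimals in all eight rows; report
  rounding is half-up, and chaining ln → divide → exp → round can land
  one step of the 0.01 display grid away from rounding r first (three
  of the eight λ values differ by exactly 0.01 for this reason — the
  acceptance suite checks them at ±0.01 and the stable rows exactly).
- **lotka**: r solves the discrete renewal equation
  `ψ(r) = Σ e^(−r x) l_x m_x − 1 = 0`.  ψ is strictly decreasing
  whenever any reproduction occurs at age ≥ 1, so the root is unique; it
  is bracketed starting from ±5/day (far beyond any insect's daily rate)
  with geometric expansion, solved by Brent's method, and accepted only
  if `|ψ(r)| < 1e−10`.  Reproduction confined to age 0 is rejected as
  degenerate.  `e^r` equals the dominant eigenvalue of the
  prebreeding-census Leslie matrix (survival ratios `l_{x+1}/l_x` on the
  subdiagonal, fertilities `p_j·m_{j+1}` in the first row); the tests
  hold this to 1e−8 over random schedules.  In lotka mode T is reported
  as `ln(R0)/r` so the same identity links the printed quadruple.

The two modes agree closely when reproduction is concentrated near T and
diverge for spread-out schedules; both are first-class because printed
values of r in this literature are consistent with either derivation.

## Bootstrap inference

Stratified bootstrap with the cohort as stratum and the individual
female — lifespan plus her whole exposure history — as the resampling
unit, preserving the within-female longevity–fecundity correlation.
Each replicate redraws n females with replacement, rebuilds the life
table and recomputes (R₀, T, r, λ).  SE is the replicate standard
deviation (exactly 0 for a constant cohort, special-cased against mean
round-off) and the CI is the 2.5–97.5 percentile interval; percentile
rather than BCa because the reports this mirrors print plain lo–hi
bounds.  Replicates that happen to draw no reproducing female have
R₀ = 0 and no finite r, T, λ: they are retained for R₀, dropped for the
other three and counted in `n_degenerate`, because cold-season cohorts
with R₀ near zero would otherwise propagate −∞ into summaries that are
finite in practice.  Ratio-mode replicates are fully vectorised
(replicate × age arrays); lotka mode solves the renewal root per
replicate.  A fixed seed gives bit-identical results; cohorts are
processed in sorted label order so mapping order cannot change the
stream.

Significance letters come from the maximal cliques of the CI-overlap
interval graph: groups in a common clique share a letter, disjoint
groups share none, and letters are assigned to cliques in descending
order of their largest member estimate, so the highest estimate always
carries "a" (the convention of the printed tables).  A group bridging
two cliques carries both letters.

The log-rank test delegates to `lifelines` (all females are followed to
death, so there is no censoring); an independently hand-coded O−E/V
statistic serves as the oracle in the tests.  p-values are asymptotic
chi-square with df = 1, no continuity correction.

## Synthetic cohorts

The generator emulates the trial design — 25 (laboratory) or 20
(semi-field) singly caged females, 90 host larvae every other day from
day 2, day-19 exposure cutoff in semi-field settings — with simple,
fully documented mechanisms:

- **Survival**: a parametric baseline discretised to days (Gompertz
  default, h(x) = rate·e^(shape·x), the usual age-accelerating adult
  insect hazard; Weibull and geometric available, geometric for
  closed-form tests), times an extra daily death probability of
  `cold_hazard` per °C of daily Tmin below `t_cold` (10 °C, the
  published lower thermal threshold for this species).
- **Fecundity**: mean total offspring per exposure f(x) = a·x·e^(−b·x)
  (peak at age 1/b), multiplied by a piecewise-linear thermal modifier
  on daily Tmin (0 at/below `t_lo`, 1 at/above `t_hi`).  Clutch size is
  negative-binomial (dispersion configurable, Poisson in the limit) —
  parasitoid clutch data are overdispersed and this keeps bootstrap SEs
  non-trivial — truncated at the 90 hosts offered; daughters are
  binomial with probability `p_female`.
- **Weather**: daily values are seasonal mean + stationary AR(1) noise
  (coefficient 0.5) whose marginal variance is calibrated so the sample
  mean over the reference trial length reproduces the published seasonal
  SE; ordering invariants (Tmin ≤ Tmean ≤ Tmax, RH in [0, 100]) hold by
  construction since extremes are built from non-negative offsets around
  the mean series.

`true_schedules` returns the closed-form l_x (product of daily survival
probabilities under the realized weather), the true m_x
(f·modifier·p_female on exposure days) and the true (R₀, T, r, λ) in
both modes, ignoring only the host-count truncation (mean clutches in
the shipped presets stay far below 90, so the bias is negligible).

### Presets

Eight presets (wild-biparental `bip` and genetic-sexing `tsl` rearing
lines × laboratory, spring, summer, autumn) are calibrated so their
*true* parameters approximate the observed magnitudes: laboratory
R₀ ≈ 110 (bip) / 64 (tsl) with T ≈ 14 d; warm semi-field seasons
R₀ ≈ 20–23 with summer fecundity concentrated early (T ≈ 7 d, the
seasonal r maximum); autumn R₀ ≈ 1.56 (bip) and 0.36 (tsl) with median
survival of 2 days under Tmin ≈ 5 °C.  Sex-ratio parameters follow the
observed seasonal values (female-biased in warm seasons, male-biased in
autumn).  Two calibration choices are deliberate:

- The semi-field presets use a wide fecundity ramp (−2 to 18 °C on
  daily Tmin) rather than the default hard 10 °C threshold: exposures
  ran mid-morning, so oviposition integrated over the warmer hours of a
  day declines gradually with the daily minimum.  A hard Tmin threshold
  would zero out autumn reproduction entirely, contradicting the
  observed small-but-positive autumn rates; the 10 °C threshold instead
  anchors the cold-mortality term.  This is a modelling choice of this
  package, not a claim about the insect's physiology.
- Autumn mortality sits mostly in the baseline hazard with a moderate
  cold term, keeping the weather-to-weather spread of the true R₀
  modest; a cold-dominated parameterisation makes the true autumn R₀
  itself straddle 1 across weather draws, which no estimator could sort
  reliably.

Presets support qualitative checks (seasonal ordering around
replacement, recovery, coverage) — they do not claim to reproduce any
observed cohort's exact numbers, which would require the original raw
records.

### What the generator does not emulate

No between-female heterogeneity beyond the stochastic draws (no frailty
or quality variation), no within-day thermal biology, no host-quality or
handling effects, no male demography, no correlation between a female's
longevity and her fecundity level beyond the structural one (longer life
⇒ more exposures).  Passing recovery and coverage tests therefore shows
the estimators are correct for data of this structure, not that real
cohorts satisfy these assumptions.

## Problem sizes in the checks

The shipped validity checks use 200 simulated 25-female trials at 500
bootstrap replicates for CI coverage, 500 null pairs for the log-rank
type-I rate, 100 trials of 200 females for recovery, 200 paired
spring/autumn simulations for the seasonal ordering, and 100 random
schedules for the renewal-vs-eigenvalue comparison — sizes at which the
Monte-Carlo error of each reported rate is comfortably inside its
acceptance band while the whole suite runs in well under a minute.

## Known limitations

- Ratio-mode r inherits any bias of T as a stand-in for the renewal
  timescale; for strongly right-skewed reproduction schedules the two
  modes can differ by more than the bootstrap SE.  Both are reported;
  neither is asserted as "the" correct one.
- Percentile CIs on 20–25 females undercover slightly (empirically
  ~0.92–0.95 for r); BCa or studentized intervals are out of scope.
- The log-rank statistic assumes no censoring, which matches these
  trials (all females followed to death) but not truncated designs.
- Weather calibration targets the mean's SE only; day-to-day
  autocorrelation is fixed at 0.5 rather than estimated.
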