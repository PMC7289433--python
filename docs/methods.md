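# Methods

## Model structure

`sdbass` implements an aggregate (perfectly mixed) compartment model of new
food adoption with four stocks — potential adopters PA, potential tasters T,
adopters N, rejecters R — and three flows:

    tasting:    PA → T   at  PA · b · (f_p + s_w · F)
    adoption:   T  → N   at  T · L · S · a(t)
    rejection:  T  → R   at  T · (1 − L) · (1 − S) · a(t)

with F = (m − PA)/m the average familiarity of the population, b the barrier
towards tasting (a lookup on the average disgust level), f_p the promotional
tasting fraction, s_w the word-of-mouth strength, L the likelihood to adopt
(a lookup on the barrier towards adopting, which is 1 − (taste expectation +
appropriateness)/2 with both terms lookups on F), S the sensory-quality
adoption fraction (a lookup on the burger's average sensory quality), and
a(t) a unit step at the market-availability year. The population m is closed:
no births, deaths, migration or re-trial by rejecters, and no price,
branding, competition or negative word-of-mouth — deliberate boundary
choices of the underlying adoption theory, not omissions of this
implementation.

Note the adoption and rejection rates do not exhaust the tasters stock:
their sum is T·a·(LS + (1−L)(1−S)) < T·a in general, so a standing
population of undecided tasters remains. That is the printed model form and
is kept verbatim.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| total_population_census | 16,900,720 | people | Netherlands, 2015 |
| special_diet_fraction | 0.04 | – | excluded from the meat-eating market |
| average_disgust_level | 0.32 | – | fixes b = 0.93 (lookup breakpoint) |
| average_sensory_quality | 0.54 | – | fixes S = 0.4368 on the base run |
| promo_tasters_fraction | 0.0036 | 1/yr | external influence |
| wom_strength | 0.151 | 1/yr | internal influence |
| availability_start_year | 2015 | yr | unit step enabling adoption |

The two influence constants were tuned (in the source model, not here) so
the base run reaches ≈20% familiarity in 2015 and so cumulative
word-of-mouth tasters are ≈10× cumulative promotional tasters; both are
verification targets of the battery, not free parameters of this package.
All five lookup tables ship with their published breakpoints and clamp to
their terminal values outside [0, 1] (the dominant system-dynamics
convention; on this model clamping is only a guard, since every input stays
inside the box).

## Numerics

Integration is fixed-step classical RK4 at dt = 0.125 yr on the 1998–2048
grid (401 points; every calendar year is on-grid). The source model was run
with an adaptive "RK4 Auto" scheme whose acceptance rule is not public;
fixed-step RK4 is a documented substitute chosen for bit-for-bit
reproducibility — the model is smooth and non-stiff, and halving dt changes
every stock by < 2·10⁻⁶ of the population, far inside the 0.1% convergence
band the engine's tests enforce. Euler is provided for cross-checks; its
truncation error against RK4 peaks at ≈0.55% of the population on the
potential-adopters stock near the adoption peak, which the tests bound at
the sub-percent level.

The availability step switches exactly at a grid point. Stage times within
each RK4 step are nudged 10⁻⁹·dt inside the open interval so the integrator
sees one-sided limits of the right-hand side and retains full order across
the discontinuity; recorded trajectory values use the inclusive-at-start
step convention (the step value holds *from* its start year). Stocks are
checked against negativity after every step (tolerance −10⁻⁹ of the
population) and the closed system conserves total population to round-off
(< 10⁻¹⁵ relative on the base run).

Degenerate inputs: an empty market (special_diet_fraction = 1 ⇒ m = 0) is
allowed at the model level — familiarity is defined as 0 there, since every
flow is zero anyway — while the standalone `average_familiarity` function
raises, because (m − PA)/m is genuinely undefined. A never-available product
is expressed as availability_start_year = ∞.

## Analytic oracles

Because F, b, f_p and s_w do not depend on the downstream stocks, PA obeys
exactly the mixed-influence Bass equation with p = b·f_p = 0.003348/yr and
q = b·s_w = 0.14043/yr. The closed form

    N(t) = m (1 − e^{−(p+q)t}) / (1 + (q/p) e^{−(p+q)t})

is compared against the simulated m − PA(t) at every grid point; the base
run deviates by at most ≈1.2·10⁻⁹ relative (pure integration error; the
test tolerance is 10⁻⁴).

The downstream stocks satisfy a reduced three-compartment system with
time-varying coefficients c(t) = a·S·L and d(t) = a·(1−S)(1−L). The package
integrates this reduction with its own stepper (independent of the engine
module) and matches the full model to ≈3·10⁻¹⁶ of the population. The
published reduction ends its tasters equation with a −d·R term; since the
stock-flow structure drains rejection from the tasters stock, the canonical
implementation uses d·T, and the literal d·R variant is selectable — with
R(0) = 0 it can never produce a rejecter, which is why it is read as a
typographical slip rather than an alternative model.

## Verification battery

* **Pattern behaviour** — familiarity must be non-decreasing, S-shaped
  (exactly one +→− sign change of the second difference of the yearly
  series after a 3-point moving average; the smoothing suppresses
  grid-scale noise), within ±3 percentage points of 20% in 2015, and above
  95% in 2048. The ±3-point band operationalises "approximately 20%"; the
  closed form puts the true value at 19.7%.
* **Influence ratio** — trapezoidal integrals of the word-of-mouth and
  promotional tasting flows over the full horizon; pass band [8, 12] for a
  target of "about ten".
* **Extreme conditions** — m = 0, disgust = 1 (tasting barrier 0), sensory
  quality = 0 (no adopter ever), and a never-available product (no adopter
  or rejecter ever), each also checked for conservation and non-negativity.
* **Dimensional audit** — structural rules (stocks share one unit, flows
  carry stock-units per year, violations are errors) plus declared-vs-usage
  checks. Two mismatches are inherited from the source tables and reported
  as warnings, not failures: word-of-mouth strength is declared
  dimensionless but used as a 1/yr rate, and the sensory adoption fraction
  is declared 1/yr but used inside (1 − fraction); both are treated as
  dimensionless per-year rate multipliers.
* **Sensitivity** — one-at-a-time sweeps with a central-difference
  elasticity at ±1% of the base value. The battery checks the qualitative
  ranking only (word-of-mouth ≫ promotion; sensory quality has exactly zero
  effect on familiarity, a structural fact): no quantitative external
  sensitivity reference is available.

No numeric pass thresholds exist in the source for these tests; the bands
above are this package's own choices, fixed before use and stated here.

## Scenarios

Overrides are applied to a copy of the base model and never mutate it.
The canonical s1.1/s1.2 follow the printed step formulas
(`0.151 + STEP(0.151·1.1, 2015)`, `0.0036 + STEP(0.0036·2, 2015)`), which
add 110% and 200% of the base values; the accompanying prose describes 10%
and 100% increases instead, and those readings are exposed as the
non-canonical `s1.1-prose`/`s1.2-prose`. s2.1 is a ramp of sensory quality
0.54→0.8 over 2017–2048, s2.2 a step to 0.8 at 2017, s3.1 replaces the
middle breakpoint of the likelihood lookup (0.55, 0.12)→(0.55, 0.19) — 1.6×
the base output at a barrier of 0.55 — and s3.2 combines s3.1 with s2.2.
Because quality and likelihood act strictly downstream of the tasting
decision, every s2.x/s3.x potential-adopters trajectory is bit-identical to
the base run, which the tests assert literally.

## Limitations

The model is descriptive, not predictive: it reproduces patterns of
behaviour under literature-derived averages, not sales. Aggregation assumes
a perfectly mixed population (no socio-demographic segments, no individual
heterogeneity); tasters decide exactly once (no re-trial, no permanent
indecision exit); word-of-mouth is only positive; and the market size is
frozen at its 2015 value for the whole half-century. Scenario outcomes
should be read as comparative curve shapes, not forecasts.
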