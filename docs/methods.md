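# Methods

This note documents the model, the choices behind it, and what the
synthetic scenarios do and do not show. Everything quantitative stated
here is computed by the test suite or the example scripts.

## Scope and scale

The package re-implements a published agent-based skylark system at desk
scale. The full system runs on digitised 10x10 km landscapes with ~35
landscape element types, ~70 vegetation types, ~50 crop management
plans and measured station weather; none of those inputs are deposited.
This implementation keeps the mechanisms — dynamic vegetation,
probabilistic weather-gated farm operations with feedbacks, habitat
scoring and territory blocks, energetics-limited breeding, degree-day
egg development, probabilistic predation and return mortality — on a
reduced inventory: ten element types, eight growth curves, four crop
plans, a seeded stochastic weather generator, and synthetic landscapes
of tens to hundreds of hectares. Consequently the published headline
fits (plot-density regression slope/R², the distribution fits, the
scrape-series fits) are not reproduction targets; the package's tests
are property-based (closed forms, oracle equivalence, Monte-Carlo
consistency, directional effects) plus the two in-text numeric values
that are self-contained (the 10.2-day uninterrupted incubation length
and the 13.75 mean of the four recorded scrape-field pair counts).

## The thirty fitted parameters

`SkylarkParams` carries the thirty named calibration parameters with
their published fitted values as defaults, each individually
overridable (the sensitivity harness depends on this). Three printed
conventions needed interpretation, resolved as config-visible scale
factors:

- `ADULTRETURNMORT` (35), `JUVRETURNMORT` (35.0) and `NESTLEAVECHANCE`
  (23) are percentages (`percent_scale` = 1e-2).
- `CLUTCH_MORT_PROB` (350) and `NEST_MORT_PROB` (23) are daily
  probabilities in units of 1e-4 (`predation_prob_scale`), giving
  0.035/day and 0.0023/day — clutch survival over an 11-day incubation
  is then ~0.68, in the plausible range of the reported fate
  distributions.
- The set of "small integer" parameters stepped by ±1/2/4/8 in the
  sensitivity protocol was read off the printed precision of the fitted
  values (35 vs 35.0, 4 vs 4.7, etc.).

Structural constants the publication does not print (baseline crop
score q0 = 40/m², adult food need 2.5 units/day, assimilation 0.7 g per
food unit, clutch sizes {3,4,5}, nest-height window 10–60 cm, territory
block 1 ha, split multiplier 2, daily time budget 840 min, and the
breeding calendar) are lower-case fields on the same dataclass, chosen
once for internal consistency: with these values a fresh barley field
scores 400 000 per territory (acceptable), a 10.5-minute trip in good
foraging conditions yields ~0.5 food units, an incubating female needs
~5 trips/day, and a brood of four needs ~26 units/day split between two
parents — all comfortably inside the daily budget when food is
accessible, and impossible when a closed, unsprayed crop drops
accessibility to zero. That knife edge is the intended mechanism: it is
what makes tramlines and scrapes matter.

## Landscape, vegetation and insects

The landscape is a raster of integer polygon ids (plain-text grid +
CSV attribute table; cell size configurable, 1 m nominal, 2–4 m in the
fixtures to keep memory and time small). Vegetation follows a logistic
in biomass, `db = r·b·(1−b/b_max)·max(0, T−T_base)/T_scale`, with
height and density linear in biomass up to crop-specific maxima; the
source publication does not print its growth equations, so this is the
package's own minimal model satisfying the stated contract (daily,
temperature-scaled, capped, reset by operations). Density maxima were
set so that density-driven inaccessibility begins at roughly the same
crop stage as height-driven inaccessibility (~40 cm in barley), which
is what gives mid-June fields their dependence on tramlines.

Insect food is a stand-in for an external submodel:
`food = envelope(doy) · element coefficient · b/(b+K) · food_max`, a
triangular seasonal envelope peaking at midsummer (day 180), K = 100,
food_max = 200 units/m², with insecticide knock-down multiplying food
by 0.3 and recovering linearly over 28 days. It is zero at zero
biomass, linear in the element coefficient and monotone in biomass
(tested properties).

## Farming

Each crop plan is an ordered list of operations with day-of-year
windows, daily attempt probabilities and a precipitation gate.
Operations become eligible in plan order, fire with their daily
probability, and are forced on the last gated-open window day so
rotations stay coherent; a window closed by weather is skipped for the
year. Published values for windows/probabilities do not exist, so the
defaults are illustrative and live in `default_crop_plans()`.
Nest-destruction probabilities are mechanism-faithful defaults: 1.0 for
soil-moving operations, 0.9 for mowing, 0.0 for spraying. Organic farm
types never spray (enforced in the scheduler, not just the plans).
Rotations are assigned by largest-remainder apportionment of rotation
slots to crops with per-field phase offsets; because every field cycles
through every slot, long-run mean crop areas match their targets to
within one field regardless of phases.

## Skylark behaviour

Males arrive mid-March to mid-April, search daily on a coarse candidate
lattice (stride of half a block side) and claim the best acceptable
non-overlapping 1 ha block; an occupied block scoring at least twice
the acceptance threshold may split along its longer axis if both halves
stay acceptable. Females accept the best available territory at or
above `MINFEMACCEPTSCORE`. A territory whose current score falls below
that threshold is given up once no nest is active — this, rather than
adult energetics, produces the mid-season territory abandonment on
maturing crops, and the tramline/scrape premiums delay it; pre-breeding
adults are assumed able to feed themselves off-territory. During
incubation the female is tied to the nest: her trips (10.5 min each,
up to 40/day) are set by requirement/intake, each trip cools the eggs
(closed-form exponential, instant rewarming), and three consecutive
days of energy shortfall abandon the nest ("other" mortality). Both
parents provision nestlings 50/50 from the territory's best cells;
growth is `min(PEMAX, 0.7 · share)` and three consecutive days below
a quarter of `PEMAX` kill the brood. Broods may leave from day 7
(daily probability 23 %) and must by day 11; the male tends
pre-fledglings (daily survival 0.985) to independence at 30 days
post-hatch while the female may renest after a 5-day delay, until
31 July. The season ends on day 273; return mortality (35 % adults and
first-years) is applied between years; the population is closed.

Incubation length is recorded as days from the first incubation day to
the hatch day, both included; the nestling period as days from hatching
to nest leaving. The event log carries every arrival, acquisition,
split, abandonment, pairing, nest event with fate and cause, operation,
and independence event; the observation protocols are pure functions of
it.

## Observation protocols and burn-in

The census protocol counts a pair for a plot on a visit date if the
mated territory's centre cell lies inside the plot (the
proportion-inside refinement used by field workers is deliberately not
applied to model output). Nest monitoring bins incubation lengths over
days 9–17 and nest-leaving days over 6–11, plus the predated/other
fates, normalised to proportions; durations outside the bin ranges are
clipped to the nearest bin. Long runs discard burn-in: statistics use
the last 20 years of a 60-year run by default.

## Fit statistics and sensitivity

`regression_origin` uses b = Σxy/Σx² and the general coefficient of
determination R² = 1 − SS_err/SS_tot about the observed mean (R² may be
negative). The published scaling sentence for the slope and R²
statistics is ambiguous; they are implemented as |1−b|/M_slope and
(M_R² − R²)/M_R², both clamped to [0, 1], with the M constants recorded
in the `FitReport`. Distribution fits are scaled by the analytic SSD
maximum of 2; per-date series fits by the score of an extinct
population. The overall statistic is the weighted mean of per-set means
with configurable weights, default (2, 2, 1).

The sensitivity harness perturbs each parameter at its eight protocol
values with the others fixed, classifies it insensitive when no
perturbation moves the overall statistic by more than 0.1, and
propagates runner failures with the offending parameter named. With no
field data available, reference patterns for the harness are
synthesised by a baseline run of the fitted parameter set on a
miniature two-field scenario (common random numbers across runs), so
the baseline scores zero by construction and deviations measure pure
parameter effect at desk scale — rankings are not expected to reproduce
the published ones. The guided-fitting loop is provided as a scripted
grid/random scan ranked by overall fit (`fit_scan`); the human
judgement in the published iteration is out of scope.

## Temperature-logger analysis

Traces are 2-minute series quantised to 0.1 °C; detection works on the
quantised deci-degree integers, so it is exact at logger resolution and
invariant to constant offsets. A trip event is a maximal run of at
least two consecutive steps each dropping by at least 0.2 °C
(single-step drops are excluded as egg turning; a run may not include a
sub-threshold step). Daily event rates per duration bin (4, 6, 8, ...
minutes) are pooled across loggers; control rates are subtracted and
clamped at zero, and the mean trip length is the arithmetic mean of the
net discrete distribution (flagged degenerate when all net rates are
zero). The synthetic trace generator mirrors the incubation thermal
model (exponential cooling toward a sinusoidal ambient, instant
rewarming, additive noise, 0.1 °C quantisation); on noise-free traces
the schedule is recovered exactly up to quantisation, and recovery of
the mean stays within 2 minutes at modest noise.

## Scenarios

Three seeded fixture generators emulate the study designs: a multi-plot
mixed-farmland census landscape (16 plots, four fields each, mean field
3.9 ha, pig/arable/mixed/hobby farms, eight visits per season), an
all-spring-barley landscape (default 25 ha) for nest monitoring over
the last 20 of 60 years, and the two-field scrape experiment (22 ha
with scrapes and tramlines kept open, 35 ha control, weekly visits). A
scenario directory (raster, polygon table, plots, farms, weather,
parameters, manifest) reproduces a run bit-for-bit given its seed.
Because the two scrape-experiment fields differ in area, their pair
counts are compared per hectare; the directional scrape benefit in the
tests is the 20-year mean of the per-season peak pair density.

The weather generator is a sinusoidal seasonal temperature (mean 8 °C,
amplitude 8.5 °C, peak day 200, Gaussian noise sd 3 °C) with a two-state
wet/dry Markov chain and gamma wet-day amounts — Danish-like climate
statistics; a measured series in the same CSV schema can be supplied
instead.

## Numerical choices and degenerate inputs

Degree-day integration is closed-form within each trip, including the
threshold crossing when ambient is below the development threshold;
rewarming is instantaneous (sub-minute thermal dynamics are below the
model's daily-with-minute-accounting resolution). A cooling rate ≤ 0 is
treated as no cooling. Zero rain is exactly zero hindrance (guarding
negative perturbed exponents). Foraging with no depletion uses the
best-rate cell, so "best cells first" reduces to a single maximum. Ties
in candidate scores resolve to the first candidate in row-major order;
within-day ordering of searching males is shuffled by the run's seeded
generator, which is the only source of randomness — identical seeds
give bit-identical event logs.

## What passing tests do and do not show

The synthetic scenarios demonstrate mechanism-level correctness
(closed forms, oracle equivalence, binomial consistency, invariants,
directional effects) and desk-scale emergent behaviour (hatch-day
support starting at day 11, mixed fate distributions, mid-season
abandonment on closing crops and its rescue by scrapes/tramlines).
They do not validate the model against real landscapes: synthetic
fields are rectangular and internally homogeneous, weather is
stationary, farm management is a four-plan caricature, detection is
perfect, and population sizes equilibrate at territory capacity rather
than at field densities. Known limitations beyond scale: no wintering
behaviour beyond return mortality, no individual parameter variation,
no predator agents, fixed-area square territories on a lattice, and no
soil-type covariate in operation scheduling.
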