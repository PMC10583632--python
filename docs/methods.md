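# Methods

## Scope and intent

`mauflow` models the occupancy of small inpatient units whose state
changes matter only at a daily resolution: admission and discharge
*dates* are known, times are not. A discrete-time (fixed 24-h
increment) simulation is therefore the natural formalism — there are no
intra-day events to order, and every stochastic draw happens at
midnight. The unit of analysis is the midnight census; the headline
statistic is the **absolute mean occupancy**, the census averaged over
a 365-day core window and over replications.

## The daily update

The engine holds a list of inpatients, each tagged with an origin unit
(relevant when several units are simulated against a pooled bed stock).
One day advances in five ordered steps:

1. **Discharges.** Each inpatient leaves with probability
   `logit⁻¹(γ₀ + γ_wd)`, where the weekday is that of the coming day —
   the decision taken at midnight concerns the next 24 hours. One
   uniform(0,1) draw per inpatient, in list order.
2. **Potential admissions.** Each unit draws
   `A_u ~ Poisson(max(0, β₀ᵘ + β_wdᵘ + β_monthᵘ))`; draws are pooled
   into one list tagged by origin.
3. **Available beds.** `(pooled capacity − census before discharges) +
   F`, with `F ~ Binomial(D, q)` over the day's D discharges and
   `q = 0.5` by default. This is the 50–50 rule: with only daily
   resolution, a bed vacated at an unknown time of day is usable for a
   same-day admission only with probability ½. The rule is applied
   per bed (a binomial), not as one coin for all freed beds. Because
   `F ≤ D`, the census can never exceed capacity.
4. **Admission or turn-away.** If the pooled potential list exceeds the
   available beds, a uniformly random subset (a shuffled prefix) is
   admitted — so potential patients from different origin units face
   the same turn-away probability. In unconstrained mode everyone is
   admitted and the turn-away count is identically zero.
5. **Bookkeeping.** Admitted patients join the list with their origin
   tag; the census is recorded *after* the update (occupancy entering
   the next day). With this convention a stay of L nights contributes
   exactly L census counts, so summed census = patient-nights and
   annual patient days = 365 × absolute mean occupancy, exactly.

Capacity is fixed: units do not open extra beds under pressure, and
staffing/financial constraints are out of scope.

### Replications and summaries

Each replication starts from an empty unit, runs `warmup (14) + core
(365) + cooldown (7)` days, and contributes the mean census over the
core window. Fourteen warm-up days suffice because the system's memory
is the length of stay (~3 days); the cool-down exists so that every
stay admitted in the core window can complete when stays are being
exported as records. Simulation day 0 is `start_date − warmup`, so the
core window aligns with the configured calendar year and weekday/month
effects line up with real dates. The default 2017 calendar starts on a
Sunday.

Each run gets its own `numpy` substream spawned from the master
`SeedSequence`, so runs are order-independent and the whole pipeline is
bit-reproducible for a fixed seed. The 95% interval over runs is the
normal approximation `mean ± 1.96·sd/√n_runs`; with the default 100
runs the normal and t intervals are indistinguishable.

## Calibrating the sub-models

**Admissions** (OLS, daily count ~ weekday + month, references Monday
and January) are fitted on *low-occupancy days only* — days whose
census is at or below the unit's median. On such days a bed was surely
available, so observed admissions equal potential admissions; this is
what lets a model of *unconstrained* demand be estimated from
capacity-censored data. The median rule retains at least half the days
by construction. Retained days with zero admissions enter as zeros:
omitting them would bias the intercept upward. Occupancy itself is
deliberately not a predictor — its coefficient would only be valid at
the historical capacity, and the experiments change capacity.

Two consequences worth knowing:

* A linear model can predict a (slightly) negative mean for quiet
  weekday/month combinations; the prediction is clamped at zero with a
  warning rather than rejected, since OLS can legitimately produce it.
* The midnight census includes same-day admissions, so on data that is
  *already unconstrained* the low-occupancy filter selects against
  high-admission days and biases the fit downward. The filter is a
  correction for capacity censoring; end-to-end tests on unconstrained
  synthetic data therefore calibrate on all days.

**Discharges** (logistic, next-day discharge ~ weekday, reference
Monday) are fitted on the inpatient-day expansion: one row per midnight
a patient is present, outcome 1 if they leave within the following 24 h,
predictor the weekday of that following day. A patient is first at risk
at the first midnight after admission, so same-day (LOS 0) stays
contribute nothing. No occupancy filtering applies. Complete separation
(e.g. every stay exactly one night) is reported as a warning and the
quasi-separated fit returned with its large standard errors, rather
than failing. Age, sex, residence, occupancy and length-of-stay to date
are intentionally not predictors: weekday alone reproduces the
occupancy distribution, which is the target quantity.

Both fits are delegated to `statsmodels` (OLS / Logit); the design
matrices use explicit treatment coding with the reference levels never
stored in coefficient files (they are implicitly zero).

## Erlang loss triangulation

For a unit with `n` beds and offered load `ρ` (the mean occupancy with
unlimited beds), the Erlang B formula gives the blocked fraction and
`ρ(1−B)` the realised occupancy. The forward computation uses the
recurrence `B₀ = 1, B_k = ρB_{k−1}/(k+ρB_{k−1})` — mandatory, because
`ρⁿ/n!` overflows naive arithmetic near n = 72 — while the direct
factorial form survives as a small-n test oracle (agreement ≤ 1e−12
for n ≤ 20, ρ ≤ 50). The inverse problem (observed occupancy → load)
is solved by bisection: the bracket `[occ, occ+1]` is grown
geometrically until it straddles the target (occupancy never exceeds
load and is strictly increasing in it, so the root exists and is
unique for occupancy < n), then halved until the *occupancy residual*
is ≤ 1e−8 beds — terminating on the residual, not the bracket width,
is what the round-trip guarantee needs. Non-integer capacities are
rejected; bed counts are integers. Reported values are conventionally
rounded to 2 decimals.

The Erlang model assumes a constant Poisson arrival rate. With weekday
and seasonal variation at the same annual average load, blocking is
higher than the constant-rate figure, so Erlang-based loss estimates
are a lower bound on the simulated ones — this direction is asserted in
the ordering tests, and is the reason the simulation, not the formula,
is the primary instrument.

## Experiments

* **Unconstrained demand**: the same unit simulated with and without
  its capacity constraint (independent substreams); the difference in
  absolute mean occupancy is the loss due to turn-aways, with a CI
  combining both standard errors.
* **Merger**: units simulated in parallel against the pooled bed stock;
  arrivals per origin unit, discharges by origin-unit coefficients,
  turn-away uniformly random over the pooled potential list. The gain
  CI is computed from per-run differences (merged run minus the sum of
  baseline runs at the same run index).
* **Bed reduction**: beds are removed from the pool one at a time,
  re-simulating each capacity under common random numbers (the same
  master seed, hence the same per-run substreams, at every capacity
  level) so the comparison against the target service level is not
  dominated by between-sweep noise. The target is met if merged
  occupancy ≥ target − ε with ε = one Monte-Carlo standard error;
  a point-estimate comparison alone would make the answer
  seed-dependent at the margin. Occupancy is monotone in capacity, so
  the first failing capacity ends the sweep. A target that fails even
  at full pooled capacity returns zero removable beds with a warning.
  Turn-aways during warm-up are never counted in annual totals.

## The synthetic generator

Real admission records for such units are not publishable, so the
generator produces record files with exactly the statistical structure
the model assumes — Poisson daily arrivals with weekday/month effects,
per-night logistic discharge draws — by running the engine itself in
stay-emitting mode. The emitted records and the returned census trace
are two views of the same trajectory, and `compute_daily_occupancy` on
the records reproduces the trace day for day.

Presets are scaled to the study-population ranges typical of these
units: capacities 6 (small), 14 (medium), 15 (mid_low) and 72 (large);
mean length of stay ≈ 3 nights except the small unit's ≈ 5; daily
arrival means ≈ 0.5–15 chosen so offered loads sit near, but mostly
below, capacity (only the medium archetype is meaningfully
capacity-constrained); weekend dips in both arrivals and discharges and
a summer-holiday dip in arrivals. The `four_unit` preset combines all
four and yields ≈ 7,400 admissions/year. The generation window starts
from an empty unit with no warm-up — like a newly opened unit — so the
record file and census are exactly consistent; the simulation is
extended past the window (admissions closed) until the last inpatient
leaves, so no discharge date is ever missing.

What the generator does **not** emulate: length-of-stay dispersion
(per-night discharge draws make LOS geometric-like, matching the mean
but not the empirical sd — occupancy, not the LOS distribution, is the
quantity of interest), case mix, referral behaviour, or any dependence
of arrivals on occupancy. Demographics (age ~ N(79, 12²) clipped to
[18, 105], two-thirds female, municipality = origin unit) are filled
from fixed marginals for schema completeness only and are never
predictors. Passing tests therefore demonstrate internal consistency
and correct statistical machinery, not fidelity to any particular real
unit.

## Numerical and testing choices

* Cleaning rules (missing/unparseable dates, discharge < admission,
  LOS > 21 days) are applied in a fixed order so exclusion logs are
  reproducible; LOS ≤ 21 is kept (21 is the last plausible short-stay
  value), and LOS-0 records are retained but contribute no occupancy.
* Statistical tests are seeded and sized so that nominal-coverage
  checks use per-coefficient 95% CIs over 20 replicates of 5 simulated
  years, steady-state checks use 100 runs × 365 days (±3 Monte-Carlo
  standard errors), and ordering checks allow 1–2 combined standard
  errors of slack; these problem sizes keep the full suite under a
  minute while leaving comfortable statistical margins.
* The one-day Markov chain with p = 1 (everyone leaves next day) has an
  exactly enumerable stationary distribution; it is used as an
  independent oracle for the capacity + 50–50 mechanics.

## Known limitations

* Additive linear arrival means can go negative (clamped) and are not a
  generative model at very low counts; a log-link Poisson regression
  would be the principled alternative but is not the specification
  being implemented.
* The 50–50 availability parameter is an assumption, not an estimate;
  it is configurable (`freed_bed_availability`) for sensitivity
  analysis.
* Common random numbers in the bed-reduction sweep share substreams,
  not event-level draws: trajectories diverge after the first blocked
  admission, so the variance reduction is partial.
* No inter-unit patient routing (a full unit does not redirect to a
  partner), no queueing, no staffing or cost modelling.
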