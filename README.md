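# mauflow

Discrete-time stochastic modelling of bed occupancy in small
admission-avoidance units — the municipal acute units (MAUs) that many
Norwegian municipalities run to divert low-acuity patients away from
acute hospitals, and units like them.

These units are small (6–72 beds), so their occupancy is dominated by
random variation in daily arrivals and discharges. `mauflow` is for
health-services researchers and capacity planners who want to answer
questions such as: *how many patients are being turned away that we
never observe? what would merging two units do to their combined
occupancy? how many beds could a merged unit give up without reducing
the care actually delivered?*

## The model

Time advances in 24-hour steps; all events are drawn at midnight. Each
day, for a unit (or pooled set of units) with capacity *n*:

1. every inpatient is discharged with probability
   `p(d) = logit⁻¹(γ₀ + γ_weekday(d))`, fitted by logistic regression of
   the next-day discharge indicator on the weekday (reference Monday);
2. potential admissions are drawn `A ~ Poisson(μ(d))` with
   `μ(d) = β₀ + β_weekday(d) + β_month(d)` (clamped at 0), an OLS fit of
   daily admission counts on weekday and month dummies (reference
   Monday/January) estimated **only on low-occupancy days** (census ≤
   the unit's median), so that μ reflects unconstrained demand;
3. available beds = (n − census) + F, where `F ~ Binomial(D, ½)` and D
   is the number of same-day discharges — a vacated bed is usable for a
   same-day admission only about half the time (the "50–50 rule");
4. if more potential patients than available beds, a uniformly random
   subset is admitted and the rest are turned away.

The key performance indicator is **absolute mean occupancy**: the mean
midnight census over 365 days (so annual patient days = 365 × absolute
mean occupancy). Removing the capacity constraint yields the unit's
*potential* occupancy; the difference is the occupancy lost to
turn-aways, a quantity rarely recorded anywhere.

The simulation estimate is triangulated against the Erlang loss
(M/M/n/n) model: the blocking probability

    B(n, ρ) = (ρⁿ/n!) / Σᵢ₌₀ⁿ ρⁱ/i!

computed by the stable recurrence `B_k = ρB_{k−1}/(k + ρB_{k−1})`, with
realised occupancy `ρ(1 − B)`. Because occupancy is strictly increasing
in the load ρ, a bisection recovers the load compatible with an
observed occupancy and capacity — e.g. a 14-bed unit observed at a mean
occupancy of 9.42 beds implies an offered load of 9.98 beds:

```console
$ mauflow erlang --beds 14 --occupancy 9.42
n=14 load=9.98 loss=0.0564 occupancy=9.42
```

## Worked example

Generate a synthetic year for four units with known ground truth (a
constrained world: units turn patients away when full), calibrate one
unit from the records, and run the experiments:

```console
$ mauflow synth --preset four_unit --years 1 --seed 7 --out records.csv --truth truth.json
mauflow synth: preset=four_unit records=7414 seed=7
$ mauflow calibrate --records records.csv --unit medium --year 2017 --out medium.json
mauflow calibrate: unit=medium ... retained_days=196/365 (excluded 46.3%)
$ mauflow experiment1 --coeffs medium.json --beds 14 --runs 100 --seed 11 --out e1.csv
```

`e1.csv` (abridged): the 14-bed unit would run at a potential occupancy
of 9.11 beds (95% CI 9.03–9.19) with unlimited beds, but at 8.64
constrained — a loss of 0.47 beds of daily occupancy, about 49 patients
turned away per year that the unit's own records would never show.

Merging it with a lower-occupancy 15-bed unit:

```console
$ mauflow merge --coeffs medium.json --beds 14 --coeffs mid_low.json --beds 15 \
    --runs 100 --seed 11 --out merge.csv
$ mauflow reduce-beds --coeffs medium.json --beds 14 --coeffs mid_low.json --beds 15 \
    --runs 50 --seed 11 --out reduce.csv
```

gives a merged occupancy of 14.14 beds against a baseline sum of 13.62
— a gain of 0.51 beds (95% CI 0.39–0.63), the spare capacity of one
unit absorbing the other's turn-aways — and `reduce.csv` reports that 8
of the 29 pooled beds (28%) could be repurposed while keeping the
combined occupancy at the baseline service level (13.60 vs target
13.64, within one Monte-Carlo standard error).

The same workflow runs from Python via `mauflow.make_scenario`,
`mauflow.generate_records`, `mauflow.fit_admission_model`,
`mauflow.run_replications`, `mauflow.experiment_merge`, etc.; see
`docs/methods.md` for the modelling details and design choices.

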