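# Methods

## The estimation target

The quantity of interest is the set of one-year transition probabilities
between coarse long-term-care states among adults aged 65–94, stratified
by sex and single year of age:

* 4-state chain: no-disability, light (certified levels SL1–CL2), heavy
  (CL3–CL5), death;
* 5-state chain (insured persons only): light/heavy crossed with
  cognitive (any dementia-related service use) vs physical service type,
  plus death.

Transitions are modelled as a first-order Markov chain within each
(sex, age) stratum: the next January's state depends only on the current
state. Probabilities are maximum-likelihood empirical frequencies
n_ij / n_i per (year, sex, age), then combined across observation years by
population-weighted averaging. Death is absorbing: its row is fixed at the
unit vector, so a K-state chain has K(K−1) free patterns (12 and 20).

Origin ages run 65–93: an age-94 observation has no in-scope successor
(95+ is excluded), so matrices cover origins 65–93 while prevalence
profiles cover 65–94 and mortality profiles 65–93.

## Panel construction and its conventions

Claims are reduced to January snapshots; a pair of consecutive Januaries
yields one transition. Conventions the source data do not pin down, fixed
here as package policy:

* **Age** is completed years at the January snapshot date.
* **Death linkage** requires equality of disqualification and death dates
  by default; a configurable lag (`lag_days`) admits municipalities that
  disqualify some days after the death notice. Records disqualified for
  *relocation* are never linkage candidates. If a linkage key
  (municipality, sex, birth date, death date window) matches more than one
  certificate, the record is left unlinked and counted — a deterministic
  rule cannot resolve twins, and guessing would contaminate the death
  timing.
* **Tracing**: a person must appear in two consecutive January snapshots,
  with a linked death counting as the second-year outcome. Claims begin
  one year before the first panel January (the lead-in year) so that
  recipients already enrolled when the panel opens are traceable; lead-in
  records are used for tracing only, never as panel observations. Without
  the lead-in, every first-panel-year observation of the oldest age would
  be spuriously dropped.
* **Censoring**: persons disqualified by relocation re-enter under a new
  person id in another municipality and are untraceable; their transitions
  are counted only up to the last observed January.
* **Dementia-service flag** is evaluated from the snapshot year's claims
  records.
* **Final-year origins are excluded from counting.** In the last observed
  year the only visible outcome is death (survivors have no successor
  snapshot), so including those origins would condition the risk set on
  dying — empirically it drives the apparent death probability toward 1.

## The residual no-disability row

Claims never show the uninsured. For each (year, sex, origin age a):

* non-disabled population N_nd = resident population − insured count;
* P(→light), P(→heavy) = new entrants at age a+1 (person ids absent the
  year before) with that severity, over N_nd;
* P(→death) = (death rate × population − deaths among the insured) / N_nd,
  floored at zero and logged when the residual is negative;
* P(→no-disability) is the complement.

Per-year rows are averaged with weights proportional to N_nd. Origin years
are capped at two before the final panel year: an entrant first seen in
the last January who survives past the window appears exactly once and is
removed by the tracing rule, which would systematically undercount onset.

Known boundary limitation: onset at origin age 93 (entrants aged 94) is
only observable through deaths, because an entrant at 94 who survives
leaves the age scope before a second snapshot. The estimated
no-disability→light cell at 93 is therefore biased low. The same censoring
applies identically to the observed and the simulated prevalence at 94, so
the validation comparison remains internally consistent.

## Stability flags and weighting

Rows with fewer than `min_cell` at-risk persons are flagged unstable and
excluded from the weighted average (weights renormalized over the
remaining years); if every contributing year is unstable the output row is
flagged, never silently zero-filled. The library default is
`min_cell = 50`, sized for full-scale administrative data. Desk-scale runs
(n = 100,000 synthetic persons) use `min_cell = 10`, because per-year
strata there hold roughly 10–150 at-risk persons; this was fixed from that
stratum-size arithmetic, not tuned to any test outcome.

Downstream simulation refuses flagged rows unless `allow_flagged` is set,
in which case a flagged row carries its state (identity row). In practice
the only flagged rows in desk-scale runs are near-empty young-age strata
(for example, heavy at 66, occupancy ~10⁻³), where the substitution is
numerically irrelevant; the Monte Carlo and the analytic oracle apply the
same substitution, so their comparison is exact regardless.

Weighting note: the population-weighted average of per-year frequencies
equals the pooled-count estimator exactly when weights are proportional to
the per-year risk sets; with uniform weights the identity holds under
equal stratum sizes (tested in that form). Since stratum sizes at fixed
(sex, age) are nearly constant across years, the two estimators coincide
to first order here.

## Microsimulation and validation

Trajectories start at age 65 from the observed cross-sectional
distribution (insured shares from the panel, non-disabled complement from
the population table) and draw successive states from the (sex, age)
matrices; trials are independent individuals, municipality structure
having been absorbed by the weighting. The exact oracle is the
Chapman–Kolmogorov product π(a+1) = π(a) P(a); eligibility prevalence is
(light + heavy) among survivors, one-year mortality is the increment of
the death mass over the surviving mass. The validation statistic is the
maximum over (sex, age) of |simulated − observed| × 100 (percentage
points), computed separately for prevalence and mortality.

## The synthetic world

The generator encodes, as one-year probabilities evaluated at January:

| parameter | default | meaning |
| --- | --- | --- |
| incidence_base | 0.004 | P(onset) at 65, per year |
| incidence_slope | 0.155 | log-odds increment per year of age |
| progression_light_to_heavy | 0.10 | per year, conditional on survival |
| mortality_gompertz_a, b | 0.010, 0.095 | one-year death prob. a·e^{b(age−65)} |
| mortality multipliers | 1.0 / 1.5 / 2.8 | no-disability / light / heavy |
| sex_incidence (F) | 1.25 | female excess late-life disability |
| sex_mortality (F) | 0.65 | male excess mortality |
| cognitive_fraction | 0.12 | entrants using dementia-related services |
| cognitive_progression_boost | 2.0 | progression multiplier if cognitive |

All probabilities are capped at 0.97 so rows remain proper. Defaults were
chosen once so the implied profiles reproduce the qualitative shape of the
emulated system — eligibility below ~10% until the mid-70s rising steeply
to ~74% (men) / ~87% (women) at 94, persistence of 55–99% across states —
and were not revisited afterwards. Incidence splits entrants
light-physical vs light-cognitive; the service type is assigned at first
eligibility and persists; there is no recovery to lighter states, so
recovery cells are exactly zero in the generating kernel. Severity within
light (SL1/SL2/CL1/CL2) and heavy (CL3/CL4/CL5) is drawn once per spell
from fixed mixtures; it carries no dynamics of its own.

Because the cognitive and physical light states progress at different
rates, the marginal 4-state process is a mixture and not exactly Markov;
the generator therefore exposes the *implied* 4-state kernel — light rows
mixed by the analytic cognitive/physical occupancy at each age — which is
exactly the expected transition frequency a panel of this cohort exhibits,
and is what parameter-recovery tests compare against.

Cohorts are drawn uniformly from the configured birth years; everyone
starts non-disabled at 65 (pre-65 mortality and pre-65 onset are not
modelled). Relocation (default 2%/year among the insured) creates a new
person id in a different municipality; `coverage_fraction` drops whole
municipalities from claims but not from the population table.

**What a green test establishes — and what it does not.** The synthetic
world is first-order Markov by construction, time-homogeneous, with exact
administrative recording (no key noise, no date lag unless configured, no
care-level manipulation). Recovery and end-to-end tests therefore verify
that the pipeline's bookkeeping and estimators are correct, not that real
claims data satisfy the first-order assumption. Validation runs use
`relocation_rate = 0` and full coverage: relocation re-identification
makes movers reappear as spurious no-disability entrants — an
identification limit of re-keyed administrative data itself, present in
the realistic default world and documented here, not an estimator defect.

## Numerical choices

* Row sums are renormalized after weighting to absorb floating-point
  drift; assembled sets are validated to 1e-9.
* Monte Carlo sampling inverts the per-row CDF with the top bucket clamped
  to 1, so a uniform draw can never fall off the end of a row.
* All randomness flows from a single root seed: stage seeds are derived
  through `numpy.random.SeedSequence` and kept below 2³¹.
* Undefined rates (no survivors, zero at-risk) are NaN and propagate to an
  explicit error in the validation statistic rather than a silent zero.

## Known limitations

* No smoothing or shrinkage across ages; no confidence intervals beyond
  the binomial-SE stability flags.
* Persons whose eligibility lapses between Januaries are unobservable in
  claims-only data; like the emulated system, the pipeline cannot separate
  sustained recovery from unrecorded death among the disenrolled.
* The 5-state chain conditions on insurance: it has no entry row, so
  5-state simulations describe the insured cohort from 65, not the full
  population.
* Life-expectancy summaries, cost projections and covariate-adjusted
  transition models are out of scope.
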