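# ltcmarkov

Disability and mortality trajectory estimation for older adults from
long-term-care insurance (LTCI) claims panels.

Japan's public LTCI certifies every resident aged 65+ who needs care into
one of eight levels — independent, support-required SL1–SL2, care-required
CL1–CL5 — from the estimated minutes of total care demanded. Claims records
carry the level, but not the date of death: the register only records a
*disqualification* when the municipality is notified of a death, a
relocation, or recovered independence. This package implements the full
analysis pipeline such data supports:

1. **Linkage** — deterministic matching of disqualified claims records to
   death certificates on (municipality, sex, birth date, disqualification =
   death date), plus the record-inclusion flowchart (ages 65–94, fixed
   birth cohorts, persons traceable across two consecutive Januaries).
2. **Panel construction** — one observation per person per January, with
   coarse LTC-status (`no_disability`, `light` = SL1..CL2, `heavy` =
   CL3..CL5, `death`) and a five-state refinement splitting recipients into
   cognitive (any dementia-related service) vs physical service users.
3. **Markov estimation** — first-order, age- and sex-stratified one-year
   transition matrices: within stratum the probability of moving from
   origin i to destination j is the empirical frequency n_ij / n_i; the
   death row is the absorbing unit vector, leaving K(K−1) free patterns
   (12 for the 4-state chain, 20 for the 5-state chain). Per-year matrices
   are combined by population-weighted averaging, and the no-disability
   row — invisible in claims — is completed residually from aggregated
   population and mortality tables (entrants / non-disabled population;
   total deaths − insured deaths over the same denominator).
4. **Microsimulation** — Monte Carlo lifetime trajectories from age 65
   (500,000 trials by default) validated against the exact
   Chapman–Kolmogorov forward propagation π(a+1) = π(a) P(a), and against
   the observed raw profiles via the maximum absolute difference in
   percentage points (ppt).

The real administrative sources are restricted, so a first-class
**synthetic-data module** generates claims, death-certificate and
population/mortality tables from a known parametric transition model
(logistic incidence in age, near-irreversible progression, Gompertz
mortality ordered no-disability < light < heavy, male-excess mortality,
female-excess late-life disability, persistent cognitive service status).
Every downstream stage is tested by parameter recovery against that model.

## Worked example

```python
import ltcmarkov as ltc

config = ltc.PipelineConfig(
    seed=7,
    synthetic=ltc.SimConfig(n_individuals=20_000, seed=7, relocation_rate=0.0),
    min_cell=10,          # desk-scale strata; use 50 at full scale
    trials=100_000,
)
report = ltc.run_pipeline(config)
```

prints nothing but returns a report whose key numbers are:

```
panel records:   22809
unique persons:  4615
status shares:   {'light': 0.676, 'heavy': 0.324}
validation:      {"eligibility": 1.66, "mortality": 2.23}   # max |sim − obs|, ppt
```

22,809 January observations on 4,615 insured persons; two thirds hold a
light level. The validation entries say the Monte Carlo profiles simulated
from the estimated matrices track the raw eligibility-prevalence and
mortality profiles to within ~2 ppt at every age and sex — at this small
cohort size that residual is sampling noise, and it shrinks at n = 100,000
(about 1 ppt and 0.5 ppt).

The estimated 4-state matrix at (female, 80), rows ordered
(no_disability, light, heavy, death):

```
[[0.942 0.040 0.000 0.017]
 [0.000 0.870 0.092 0.038]
 [0.000 0.000 0.928 0.072]
 [0.000 0.000 0.000 1.000]]
```

Staying in the current state dominates every live row, recovery to a
lighter state is exactly zero, and mortality rises with severity — the
persistence-and-irreversibility structure the estimator is built to
measure.

A CLI mirrors the stages:

```sh
ltcmarkov generate --n 20000 --seed 7 --outdir tables/
ltcmarkov link --claims tables/claims.csv --deaths tables/deaths.csv \
    --report flow.json --out appended.csv
ltcmarkov panel --appended appended.csv --out panel.csv
ltcmarkov estimate --panel panel.csv --population tables/population.csv \
    --mortality tables/mortality.csv --scheme 4 --out m4.json
ltcmarkov simulate --matrices m4.json --trials 500000 --seed 7 \
    --allow-flagged --out profiles.csv
ltcmarkov run -c config.yaml          # everything from one YAML
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch at n = 100,000 — synthetic world,
linkage, panel, 4- and 5-state estimation, 500,000-trial Monte Carlo — and
prints a run summary (panel sizes, free-pattern counts, simulated-vs-raw
and Monte-Carlo-vs-analytic maximum differences) to stderr before writing
the results JSON to `--out`. See `docs/methods.md` for the model, its
assumptions, and what the synthetic world does and does not establish.
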