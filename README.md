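# flushrisk

Nest-defence risk modelling and statistics for ground-nesting shorebirds.

Small shorebirds with single-parent incubation (sandpipers, phalaropes)
cannot defend their nests aggressively.  When a predator approaches, the
incubating bird must decide when to leave: flush at close range and attempt
*active deception* (broken-wing or rodent-run displays, distraction calls),
or flush far away and slip off unnoticed (*passive deception*).  The
departure itself is a visual cue that can betray the nest, and `flushrisk`
is built around a simple model of that cue, for behavioural ecologists who
want to analyse flush-distance and nest-fate data or probe the model's
predictions by simulation.

## The model

A bird flushes when a predator enters the circle of its threshold distance
*r*.  Conditional on a predator somewhere within a reference radius
*R* = 125 m of the nest:

* probability of flushing: `P_flush(r) = min((r/R)^2, 1)` — the area ratio
  for a uniformly placed predator;
* probability the flush reveals the nest: `P_detect(d) = 1` for
  `d <= F_close` (5 m), `0` for `d >= F_long` (100 m), declining linearly
  (by default) in between;
* flush-attributable predation risk: `risk(d) = P_detect(d) * P_flush(d)`.

The risk vanishes at both tails and peaks at intermediate distances — for
the linear decline at `d* = 2 F_long / 3 ≈ 66.7 m`, with at least half the
maximum risk carried between roughly 33 and 91 m.  Intermediate flush
distances are the dangerous strategy; the two tails are the sensible ones.

Around this core the package provides a Monte Carlo predator-encounter
simulator (the model's brute-force oracle, plus a transect geometry
mimicking a walking searcher and an observer-discovery bias filter), a
synthetic nest-record generator, and the statistical pipeline used on such
data: Hartigan's dip test of unimodality (implemented in-package, with
Monte Carlo calibration), proportional-odds regression of defence category
on species and flush distance, quadratic logistic regression of nest fate,
pooled t-test, OLS R², and descriptive summaries.  See `docs/methods.md`
for the full model account and design choices.

## Worked example

Tabulate the analytic curves and locate the risk peak:

```sh
$ flushrisk riskcurve --grid-step 25
# flushrisk riskcurve: RiskModelParams(f_close=5.0, f_long=100.0, r_ref=125.0, detection_shape='linear')
# argmax_risk=66.667 m, half-max band=(33.333, 91.068) m
distance_m,p_detect,p_flush,risk
0.0,1.0,0.0,0.0
25.0,0.7894736842105263,0.04000000000000001,0.03157894736842106
50.0,0.5263157894736843,0.16000000000000003,0.0842105263157895
75.0,0.26315789473684215,0.36,0.09473684210526317
100.0,0.0,0.6400000000000001,0.0
125.0,0.0,1.0,0.0
```

The header lines say it all: under the default constants the flush that
maximises predation risk is at 66.7 m, and everything between 33 and 91 m
carries at least half that maximum — the "intermediate distances are risky"
band.

Generate a study-sized synthetic dataset (62 sandpipers, 38 phalaropes)
and run the full pipeline on it:

```sh
$ flushrisk generate --preset paper_like --seed 7 --out nests.csv
wrote 100 records to nests.csv
$ flushrisk analyze nests.csv --seed 7 --n-null 1999 --out results
$ flushrisk report results
summary: per_species_n.phalarope=38, per_species_n.sandpiper=62, per_species_mean.phalarope=13.3904, per_species_mean.sandpiper=12.1961, ...
dip: statistic=0.0213, p_value=0.996, n=100, n_null_samples=1999, seed=7
ttest: t_statistic=-0.399, degrees_of_freedom=98.0, p_value=0.6907, variant=pooled, ...
ordinal: coefficients.species_sandpiper=2.7181, coefficients.flush_distance_m=-0.0672, ...
fate_logistic: intercept=-0.9042, beta_flush=-0.0769, beta_flush_sq=0.001, ..., n=95
fate_curve: peak_predation_m=37.6655
```

Reading the report: the dip statistic 0.021 with p = 0.996 finds no
departure from unimodality in the flush distances (as expected — this
preset draws from a single lognormal); the pooled t on 98 df shows no
species difference in flush distance; the ordinal fit's positive sandpiper
coefficient (2.72) says sandpipers escalate to active deception more than
phalaropes, and the negative flush coefficient (−0.067) says closer
flushers escalate more; the fate regression's negative linear and positive
quadratic terms bend hatching odds down then up, putting the maximum
predicted predation at 37.7 m — an intermediate flush distance, as the
analytic model predicts.  Every run writes its resolved configuration and
seed (`results/config.json`) next to full-precision JSON results, so it can
be reproduced byte-for-byte.

The same pipeline runs on real field tables: a CSV with columns `nest_id,
species, flush_distance_m, defence_category, fate` (case-insensitive
vocabularies, column remapping and an explicit XLSX→CSV converter in
`flushrisk.io`).

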