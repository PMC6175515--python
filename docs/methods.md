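# Methods

`flushrisk` models one component of nest-predation risk for small
ground-nesting shorebirds with single-parent incubation (e.g. White-rumped
Sandpiper, Red Phalarope): the risk created by the incubating bird's own
departure ("flush") from the nest as a predator approaches.  The package
has four parts — a closed-form risk model, a Monte Carlo encounter
simulator that serves as its independent oracle, a synthetic nest-record
generator, and the statistical pipeline applied to nest-record tables.

## The flush-risk model

A bird's strategy is its *flush threshold* r: it leaves the nest the moment
a predator comes within r metres.  Two opposing probabilities govern the
risk of the flush revealing the nest, conditional on a predator being
somewhere within a reference radius `r_ref` of the nest:

* **Flush probability.**  With the predator's position area-uniform in the
  disk of radius `r_ref`, the chance it falls inside the bird's threshold
  circle is the area ratio `(r / r_ref)^2`, capped at 1.  Long-threshold
  birds flush often; tight sitters almost never do.
* **Detection probability.**  A flush at or below `f_close` metres is
  assumed to always reveal the nest; a flush at or beyond `f_long` metres
  never does; between the two the probability declines continuously and
  strictly.  Defaults: `f_close = 5` m, `f_long = 100` m, `r_ref = 125` m.

The risk attributable to flushing is the product.  It vanishes at both
tails and peaks in between: for the linear detection decline the maximum of
`((f_long - d) / (f_long - f_close)) * (d / r_ref)^2` on
`[f_close, f_long]` is at `d* = 2 f_long / 3` whenever
`f_close <= 2 f_long / 3` — 66.7 m under the defaults, inside the 30–80 m
band where at least half the maximum risk is carried
(`high_risk_band(params, 0.5)` → 33.3–91.1 m).  This is the model's core
prediction: intermediate flush distances are the dangerous ones, which is
why short-flushing birds pair the flush with active distraction displays
and long-flushing birds can simply slip away.

**Detection-curve family.**  Only the endpoints of the detection decline
are identifiable from first principles; the curvature between them is not.
The decline is therefore a parameter (`detection_shape`): `linear` is the
default (minimal assumption, reproduces the 30–80 m band), with
`smoothstep` and a rescaled `logistic` available so conclusions can be
checked for sensitivity to this choice.  The shape in force is echoed in
all CLI output headers.

**Numerics.**  `argmax_risk` is a deterministic fine-grid scan (step =
tolerance, default 0.01 m) with bounded scalar refinement — no randomness,
so the band checks are exactly reproducible.  `high_risk_band` brackets the
level crossing with `brentq` on each side of the peak; for the linear shape
the restricted risk is unimodal, so the level set is a single interval.

## Encounter simulator

Each Monte Carlo trial realises the two probabilities as events.  Two
predator geometries:

* `stationary_uniform` (default oracle): the predator is a point placed
  area-uniformly (radius `R * sqrt(u)`).  This is exactly the conditioning
  of the analytic model, so flush/detection frequencies must converge on
  the square law and the risk product — the simulator-vs-closed-form
  agreement is asserted within 3 binomial standard errors at 1e5 trials per
  threshold.
* `transect`: the predator walks a straight chord of the arena, mimicking a
  searcher at walking speed.  Chords are generated by a uniform bearing
  plus a uniform perpendicular offset in (−R, R); under this convention the
  closest approach is |offset| and the flush frequency is `r / R`, strictly
  above the stationary square law for r < R.  Chord conventions change the
  answer, so this one is stated here and in output metadata.

Detection is evaluated exactly at the threshold distance (the bird flushes
the instant its circle is crossed), for both geometries.  Population
simulation (`simulate_population`) draws a threshold per bird and marks a
nest depredated if any of its encounters ends in detection; one encounter
per nest is the default because the analytic model is a per-encounter
statement, and no per-season encounter rate is assumed — multi-encounter
exposure is an explicit flag.

`observer_discovery_filter` emulates the sampling bias of finding nests by
walking and flushing birds: each nest is retained with probability
proportional to the same detection-times-flush product, renormalised to a
maximum of 1.  It exists to demonstrate that searcher-collected samples
over-represent intermediate flush distances, which weakens bimodality tests
on field data.

## Synthetic nest records

`generate_dataset` emulates a nest-monitoring table: one row per nest with
species, flush distance, ordinal defence category (1 pure flush → 4
attention flights) and fate (hatched / depredated / unknown).

* **Flush distances**: lognormal by default — right-skewed with positive
  support, matched to the field moments (sandpiper 15.3 ± 18.8 m,
  phalarope 13.8 ± 19.0 m) via the arithmetic-moment parameterisation.  The
  family is a choice (nothing identifies it beyond skew and support); gamma
  and two-component mixtures are available.
* **Defence category**: proportional odds, `P(Y <= k) = logistic(c_k − η)`
  with `η = β_sp·1[sandpiper] + β_fl·d`, phalarope as reference.  Defaults
  `c = (1.126, 2.349, 4.325)`, `β_sp = 2.7`, `β_fl = −0.04` were calibrated
  once (least squares against the field category table: phalaropes 0.84 /
  0.08 / 0.08 / 0.00, sandpipers 0.26 / 0.28 / 0.34 / 0.11) and frozen.
  The negative flush coefficient makes close flushers escalate to active
  deception.
* **Fate**: `logit P(hatched) = β0 − 0.141 d + 0.002 d²`, the field study's
  quadratic coefficients; `β0 = −0.639` was solved once so the marginal
  hatch probability is ≈ 0.17 (apparent hatch success ≈ 0.15 after the
  unknown-fate mask), matching the heavily depredated study system.  The
  positive quadratic term places peak predation at intermediate distances
  (vertex 35.25 m for the printed coefficients).
* **Unknown fates**: masked independently of covariates at rate 0.08
  (the study reported 7–9% without a mechanism; independence is the
  neutral assumption).

Presets: `paper_like` (62 + 38 nests as above), `unimodal_null` (single
lognormal component — the unimodality null), `bimodal_alternative` (a
0.55/0.45 lognormal mixture with modes near 3 m and 90 m — the
avoidance-of-intermediates alternative).

What the generator does *not* emulate: the searcher discovery bias above
(unless the filter is applied), co-occurrence of display categories
(category 4 often accompanies 2–3 in the field; generation is
single-valued ordinal), species/year heterogeneity in fate, overdispersion,
and measurement error in paced distances.  Passing parameter-recovery tests
therefore show the pipeline is correct for its assumed models, not that
those models exhaust real field data.  Notably the `paper_like` lognormal
reproduces the field moments but not the field's exact short-distance bin
mass (≈25% below 5 m versus 41% observed), a reminder that two moments do
not pin down the distribution.

## The dip statistic and test

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex up to a mode, concave after).  It is
computed by the classical modal-interval iteration: fit the greatest convex
minorant (GCM) and least concave majorant (LCM) of the ECDF on a candidate
modal interval, find the largest separation between the fits, shrink the
interval to the separation's touch points, accumulate the one-sided ECDF
deviations outside it, and stop when the remaining separation no longer
exceeds the accumulated deviation.  Bookkeeping is in count units with the
upper/lower ECDF step values handled explicitly (so ties are exact), and
the result is halved because an optimal unimodal fit splits each one-sided
deviation evenly.  Closed forms used as anchors: two distinct values give
1/4; n equally spaced values give 1/(2n); a constant sample gives 0.

Correctness is established in the test suite against an independent exact
oracle: the dip as the minimum over mode placements of a small linear
program over piecewise-linear unimodal CDFs (convexity/concavity and
monotonicity as linear constraints, an atom allowed at the mode).  The two
agree to 1e-8 on hundreds of random samples with and without ties.

`dip_test` calibrates by Monte Carlo against uniform(0,1) samples of the
same size — the asymptotically least favourable unimodal null — with
10,000 null draws by default and the add-one p-value
`(1 + #{null >= obs}) / (1 + B)`.  Calibration tables can be precomputed
and shared across datasets of the same size (`dip_null_table`); the
replicated calibration checks in the test suite do this, using null tables
several times larger than the replicate count so that sharing adds
negligible correlation.  Against non-uniform unimodal data the test is
conservative by construction.

## Regression and summary choices

* **Ordinal fit**: maximum-likelihood proportional odds (statsmodels
  `OrderedModel`, logit link), species indicator (phalarope reference) plus
  flush distance.  Per-term χ² are drop-one likelihood-ratio statistics
  (refit without the term, 1 df) — the conventional reading of per-term χ²
  for this model; Wald is available by flag.  Divergence and perfect
  separation raise `SeparationError` rather than returning silently.
* **Fate regression**: ML logistic of hatched (=1) vs depredated on flush
  and flush²; unknown fates are excluded.  Wald standard errors from the
  observed information.  Predation probability is 1 − predicted hatching;
  its maximum over a stated range is the quadratic's vertex when interior,
  else the better endpoint.
* **t-test**: pooled-variance Student by default (df = n1 + n2 − 2, so a
  62 + 38 comparison reports 98 df); Welch by flag; two-sided p; sign is
  sandpiper minus phalarope.
* **Distance bins**: "<5 m, 5–20 m, >20 m" is ambiguous at the boundaries;
  the package uses [0, 5), [5, 20], (20, ∞), recorded in output metadata
  and configurable.
* **Apparent hatch success**: hatched / all nests found, unknown fates in
  the denominator — the field convention for nests-found summaries,
  uncorrected for exposure.
* **Convergence**: relative log-likelihood tolerance 1e-9, 200 iterations
  maximum; these GLMs at study sizes converge in far fewer.

## Problem sizes in the shipped checks

The test suite sizes its simulations to be decisive yet quick: 1e5 trials
per threshold for simulator-vs-analytic agreement (3 SE); 500 replicates
for dip-test size (n = 200 against a 4,999-draw null table) and for the
conservative-null (n = 10,000, 1,999-draw table) and power (n = 1,000,
999-draw table) checks; 1e5 synthetic records for coefficient recovery
within 2 SE.  `scripts/acceptance.py` recomputes the deterministic
headline quantities (risk-peak location, detection percentage at
`f_close`, printed-coefficient predation peak) and attaches a seeded Monte
Carlo cross-check of the peak in its metadata.

## Known limitations

* Only the visual flush cue is modelled: no olfactory search, nest
  concealment, egg visibility, incubation-recess exposure, energetic costs,
  predator learning, or multi-season dynamics.
* Depredation frequencies from the population simulator are per-encounter
  quantities unless the caller supplies an exposure count.
* The transect geometry fixes one chord convention; others (e.g. random
  endpoints on the boundary) yield different flush frequencies.
* The dip test's Monte Carlo calibration is exact only against its uniform
  null; for other unimodal data it errs on the conservative side.
* Reproducing a specific field study's printed statistics requires that
  study's own records; the synthetic generator reproduces their structure
  and moments, not their realised sample.
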