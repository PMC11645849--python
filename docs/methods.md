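# Methods

This note documents the accounting conventions, model structure, numerical
choices and limitations of `qalyval`. It is the reference for *why* the
package computes what it computes; the README shows *how* to run it.

## QALY accounting on the annual-cycle grid

Time is divided into annual cycles `t = 1, 2, …`. The conventions, shared
between trial-side and model-side accounting:

* **Events at the start of the year.** A clinical event in cycle `t`
  decrements utility in cycle `t` (its event-year decrement) and, for
  permanent decrements, in every later cycle (its subsequent-years
  decrement).
* **Deaths halfway through the year.** A death at fractional time `d`
  falls in cycle `⌈d⌉`, and that cycle accrues weight 0.5 wherever in the
  year the death occurred — a half-cycle correction, not exact-day
  accrual. Events recorded in the death cycle still apply before the
  half-year weight (start-of-year events precede a mid-year death).
* **Censoring pro rata.** The cycle in which a participant is censored at
  time `c` accrues weight `frac(c)`; integer censor times produce no
  partial cycle.
* **Additive utilities, no floor.** Annual utility is the baseline utility
  minus the sum of active counted decrements. With several concurrent
  permanent decrements the value can go negative; this is deliberate — the
  framework validates an additive utility model and imposing a floor would
  change the model being validated.
* **Discounting** (optional, default 0) multiplies cycle `t` by
  `1/(1+r)^(t−1)`: the first year is undiscounted, consistent with accrual
  beginning at randomization and events at the start of each year. A
  consequence worth knowing: discounting strictly reduces QALYs only for
  participants accruing beyond the first cycle.

### Occurrence counting

Decrements attach to *counted* occurrences. Under the default rule an
occurrence counts if its cumulative number — baseline history plus in-trial
occurrence index — does not exceed the per-event cap: 2 for MI, stroke and
amputation (a second event has the same impact as the first), 1 for all
other events. A third MI/stroke/amputation or a second ulcer therefore
changes nothing, and a participant with a prior ulcer at baseline gets no
decrement from an in-trial ulcer (it is their second).

Three alternative rules support sensitivity analyses:
`count_all_since_randomization` ignores baseline history and counts up to
two occurrences of MI, stroke, amputation, blindness and ulcer;
`exclude_second_events` caps every event at one cumulative occurrence;
`exclude_second_events_and_ulcer` additionally removes the ulcer decrement
entirely.

### Utility tables

The default table starts everyone at utility 0.807 regardless of baseline
history (history affects risk and occurrence counting, not starting
utility). MI decrements 0.065 for the event year only; stroke (0.165) and
renal failure (0.330) decrement permanently; IHD and blindness carry no
decrement in the base case. The CHF (0.108), amputation (0.280) and ulcer
(0.170) defaults are labeled placeholders borrowed from the alternative
set below, because no primary-source default is available for them; users
with authoritative values should supply their own YAML table. The packaged
**alternative table** (sensitivity analysis SA4) is fully specified:
initial utility 0.785 and event-year-equals-subsequent decrements of
IHD 0.090, MI 0.055, stroke 0.164, CHF 0.108, blindness 0.074, ulcer
0.170, amputation 0.280, renal failure 0.204.

### Trial vs model QALYs

Trial QALYs accrue until the participant dies or is censored. Model QALYs
are computed per Monte Carlo loop over the full simulation horizon
(7 years by default) and then truncated at the participant's censor time —
for participants who died in the trial, at their *administrative end time*
(the follow-up they would have had absent death), so the model is judged
on the whole window it was asked to predict. The censor-year term is
adjusted per loop for deaths occurring in that year: loops in which the
simulated patient dies in or before the censor cycle contribute the
half-cycle death-year weight; surviving loops contribute the
fraction-of-year censor weight. This per-loop rule is our interpretation
of the requirement to allow for deaths in the censor year; no closed-form
specification of that adjustment exists to copy.

## Performance metrics

`bias`, `MSE`, `MAE`, `R²` and `Q²` are defined in the README. Numerical
choices:

* Q² uses the **N denominator for MSE and the N−1 denominator for SD²**,
  exactly as the metric is defined. The resulting (N−1)/N factor is part
  of the definition; "harmonizing" it would change published values.
* `r_squared` is the closed-form univariate OLS of trial on model
  outcomes; it equals the squared Pearson correlation and is invariant to
  affine transforms of the predictions. A constant predictor has an
  undefined slope; we return R² = 0 with a warning (a constant explains
  nothing).
* Constant observed outcomes make both R² and Q² undefined → input error.
* Metrics are computed and stored at full precision; only the display
  layer (`pipeline.report`) rounds, to 3 decimal places. Subgroup metrics
  are computed on full-precision subgroup members, never by aggregating
  rounded numbers.

## The microsimulation engine

The engine is a generic coefficient-driven annual-cycle individual
simulator. Equations are supplied as YAML: per event a link (`logistic` or
`cloglog`), a coefficient vector over covariates (`intercept`, `age` —
current age, advancing one year per cycle — `age_base`, `female`,
`diabetes_duration`), history terms (`hist_<EVENT>`, `count_<EVENT>`), and
a `second_event` flag (permitted only for MI, stroke, amputation); plus a
death equation that may additionally reference same-year event indicators
(`new_<EVENT>`) to capture acute fatality. No published model coefficients
are embedded; the engine runs whatever the user supplies.

**Within-year policy** (declared, since published models do not specify
their internal ordering): all eligible events are drawn simultaneously and
independently from start-of-year state; death is drawn last, seeing the
same-year event indicators; history updates at year end. An event is
eligible while its cumulative occurrence count (baseline history plus
simulated) is below its cap (2 with `second_event`, else 1).

**Randomness.** Each patient owns an independent substream
(`SeedSequence([master_seed, patient_key])`), within which uniforms are
drawn on a fixed `(loop, cycle, channel)` grid — one channel per event
type plus one for death, drawn whether or not the channel is used that
cycle. This buys three properties: the scalar reference implementation
(`simulate_loop`) and the vectorized production path (`run_patient`)
consume identical draws and agree bit-exactly; the running mean over the
first `k` loops equals a run with `n_loops = k`, which makes the
convergence diagnostic a single simulation; and changing one patient's
loop count never perturbs another patient's draws.

**Loop count.** The default is 50,000 loops per patient, the point at
which the convergence diagnostic's running mean is stable well within 0.01
QALYs on constant-hazard fixtures. Full-cohort validation runs in this
repository use 400 loops per patient: the Monte Carlo standard error of a
patient's mean QALYs is then ≈ `SD_loop/√400` ≈ 0.06, which adds ≈ 0.004
to MSE — negligible against observed-outcome variances near 1 — while
keeping a 2,000-patient two-model study around ten seconds.

## Cumulative incidence with competing risks

Observed curves use the Aalen–Johansen estimator,
`CIF(t) = Σ_{τ≤t} Ŝ(τ⁻)·d₁/n`, with `Ŝ` the all-cause Kaplan–Meier in the
analysis subset. The pointwise variance is the Aalen-type estimator
(the Marubini–Valsecchi form used by standard competing-risks software)
and 95% limits are computed on the log(−log) scale. The implementation is
in-package to control tie handling exactly; `lifelines` serves as an
independent cross-check in the tests.

Conventions: an event in cycle `y` is placed at time `y − 0.5`, matching
the half-cycle placement of deaths, so `CIF(0) = 0` holds and event/death
ties are processed jointly at the same time with the event of interest
never pre-empted by a same-time death. Subset rules mirror the validation
design: first-event curves use only patients with no baseline history of
that event; second-event curves only patients with history (their first
in-trial occurrence is their second overall); death and the any-event
composite (first event of any type, death included) use everyone.

Predicted curves are the simulator's cumulative expected events divided by
the number of individuals at the start of simulation, stepping at cycle
boundaries; comparison interpolates the observed step function onto those
boundaries and reports the fraction of grid times at which the prediction
lies inside the observed CI.

## The synthetic trial generator

The generator emulates the *structure* of a large contemporary
cardiovascular-outcome trial in type 2 diabetes: ~73% with prior
cardiovascular events (MI/IHD/stroke, at least one component guaranteed
for prior-CVD patients), diabetes duration log-normal with median 12
years, age ≈ N(62, 8²) truncated to 40–88, 38% female, modest baseline
prevalences of heart failure, amputation, blindness, renal failure and
ulcer history. Follow-up combines administrative censoring uniform on
2.5–4.5 years (staggered entry against a fixed study end, capped at the
7-year maximum) with 5%/year withdrawals; under the default truth
equations this yields a median observed follow-up of ≈ 3.2 years (checked
once at n = 5,000).

The truth process is **one microsimulation loop per patient** under a
known equation set, run through the same engine as the validated models —
so the model class can in principle attain the stochastic ceiling, and
validating the truth equations against their own trial must outrank any
perturbed candidate on Q² and MSE (the package's analogue of ranking two
published model versions). Truth-equation intercepts correspond to annual
probabilities of roughly 0.3–2% per event and 1.2% for death at age 62
without history, with positive age, duration, and history effects and
acute-fatality terms for same-year MI/stroke — plausible magnitudes for a
contemporary trial population, chosen once and not tuned.

What the synthetic data do **not** emulate: correlated risk-factor
trajectories (covariates other than age are fixed at baseline), multiple
imputation of missing risk factors, treatment-arm structure (arms pooled),
event-definition mismatches between trial and model, and any real
covariate joint distribution. Passing the self-validation tests therefore
demonstrates internal consistency of the accounting/metric/simulation
machinery, not external validity of any particular risk-equation set.

## Degenerate inputs and tie-breaks

* Censor time 0 → empty trace, 0 QALYs. Death times must be > 0.
* Death and censor in the same cycle of a simulated loop: the death-year
  half-weight wins (the loop's patient died).
* `exclude_censor_year` drops only the *partial* censor-year term;
  integer censor times have no partial year to drop.
* Events recorded after follow-up ends are rejected by the generator and
  ignored by the trace builder (they cannot arise from the packaged I/O).
* Empty subgroups are omitted from evaluation with a warning; an empty
  analysis subset skips the analysis with a warning.

## Known limitations

* The annual grid cannot represent sub-year event ordering; two events in
  the same cycle are order-free by construction.
* The Aalen-type CIF variance is computed by a quadratic-time loop over
  failure times — fine for trial-scale data, not for millions of subjects.
* Model QALYs ignore parameter (second-order) uncertainty; only
  first-order Monte Carlo noise is averaged out, by design.
* The censor-year death adjustment for model QALYs is an interpretation
  (documented above); alternative conventions would shift model QALYs by
  a fraction of the censor-year utility for loops dying in that year.
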