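# qalyval

External validation of patient-level health simulation models using
quality-adjusted life-years (QALYs) as the outcome and **Q², the
proportional reduction in error**, as the headline accuracy metric.

## The problem

Decision-analytic microsimulation models (diabetes outcome models are the
motivating case) predict mortality and many clinical events — myocardial
infarction, stroke, heart failure, blindness, amputation, renal failure,
foot ulcer — for individual patients. Validating each event separately does
not answer the question a health-technology-assessment user actually has:
*how accurately does the model predict the QALYs this patient would
experience?* QALYs weight every event by its utility decrement and every
death by the life-years lost, collapsing the whole event profile into the
single outcome on which reimbursement decisions turn.

`qalyval` operationalises that validation. For each trial participant it
computes:

* **trial QALYs** `Tᵢ` — the model's own utility assumptions applied to the
  participant's *observed* events and survival, on an annual-cycle grid
  (events at the start of each year; deaths halfway through the year, so
  the death year accrues half a cycle; censored years accrue the fraction
  of the year on study);
* **model QALYs** `Mᵢ` — the same accounting applied to each Monte Carlo
  loop of a coefficient-driven annual-cycle microsimulator, averaged over
  loops and truncated at the participant's follow-up (for decedents, the
  follow-up they would have had).

Five metrics compare the pairs `(Mᵢ, Tᵢ)` over the `N` participants:

```
bias = Σ(Mᵢ − Tᵢ)/N                 MSE = Σ(Mᵢ − Tᵢ)²/N
MAE  = Σ|Mᵢ − Tᵢ|/N                 R²  = 1 − Σ(aMᵢ + b − Tᵢ)²/Σ(Tᵢ − T̄)²
Q²   = 1 − MSE/SD²,   SD² = Σ(Tᵢ − T̄)²/(N − 1)
```

R² recalibrates slope and intercept by OLS, so it measures discrimination
only; Q² is penalised by bias as well, can be negative for very poor
models, and — unlike MSE/MAE — is comparable across samples, subgroups and
outcomes. A systematically shifted predictor keeps its R² but loses Q².

Because real trial data of this kind are proprietary, the package includes
a synthetic trial generator (cohort with realistic prior-event history,
a known "truth" risk-equation set, staggered administrative censoring and
withdrawals) so the complete workflow — QALY accounting, metrics with
subgroup breakdowns, sensitivity analyses, and observed-vs-predicted
cumulative incidence with death as a competing risk (Aalen–Johansen) — is
exercisable end to end with no external data.

## Worked example

Validate the truth equations and a deliberately miscalibrated candidate
(every intercept shifted by +0.5 on the logit scale) against a synthetic
trial of 1,000 participants:

```python
from qalyval.synth import generate_trial, perturbed_equations
from qalyval.pipeline import ValidationConfig, run_validation, report

records, truth = generate_trial(1000, seed=7)
config = ValidationConfig(
    models={"truth": truth, "biased": perturbed_equations(truth)},
    n_loops=400, seed=7, analyses=("base_case",), curves=(),
)
res = run_validation(records, config)
view = report(res.metrics)
print(view[view.subgroup == "overall"].to_string(index=False))
```

```
 analysis  model subgroup    n trial_mean_sd model_mean_sd    q2    r2   mae   mse   bias
base_case  truth  overall 1000 2.464 (0.797) 2.476 (0.645) 0.613 0.614 0.255 0.246  0.012
base_case biased  overall 1000 2.464 (0.797) 2.373 (0.618) 0.596 0.609 0.321 0.257 -0.091
```

Reading the rows: over a median ≈3.2 years of follow-up participants
accrued on average 2.464 trial QALYs (SD 0.797). The truth model predicts
2.476 on average — essentially unbiased (bias 0.012) — and reduces squared
prediction error by 61.3% relative to predicting the mean (Q² 0.613; the
gap from 1 is the irreducible single-realization noise of a trial). The
miscalibrated candidate underestimates QALYs by 0.091 on average and is
correctly ranked worse on Q² and MSE, while its R² (0.609 vs 0.614) barely
moves — the bias-blindness of R² that motivates Q². Note the model-QALY SD
(0.645) is smaller than the trial SD: loop-averaging removes first-order
noise.

The full analysis catalogue adds life-year comparisons, two extreme-bias
cross-comparisons, and eight sensitivity analyses (second-event counting
rules, an alternative utility set, censor-year exclusion, 3.5% discounting,
1- and 3-year horizons), plus observed-vs-predicted cumulative incidence
curves per event. A 50-patient fixture for quick experiments ships in
`examples/fixture_n50/`; the same artifacts are produced by the CLI:

```sh
qalyval synth --n 1000 --seed 7 --out trial/
qalyval validate --config config.yaml --out results/
```

## Layout

| module | contents |
| --- | --- |
| `qalyval.qaly` | event types, utility tables, patient records, utility traces, trial/model QALY accounting |
| `qalyval.metrics` | bias, MSE, MAE, R², Q², subgroup evaluation |
| `qalyval.microsim` | coefficient-driven annual-cycle simulator, convergence diagnostics |
| `qalyval.incidence` | Aalen–Johansen observed CIF, predicted CIF, curve comparison |
| `qalyval.synth` | synthetic cohort, truth process, fixture writer |
| `qalyval.pipeline` / `qalyval.cli` | validation orchestration, reporting, `qalyval` CLI |

See `docs/methods.md` for the accounting conventions, simulator design,
what the synthetic data do and do not emulate, and known limitations.
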