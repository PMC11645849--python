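"""Synthetic trial generator.

Emulates the structure of a large contemporary cardiovascular-outcome trial
in type 2 diabetes: ~73% of participants with prior cardiovascular events,
diabetes diagnosed a median of 12 years before randomization, median
follow-up around 3.2 years with a 7-year maximum, administrative censoring
from staggered study entry plus annual withdrawals, eight non-fatal event
types plus death with second occurrences of MI, stroke, and amputation.

The "truth" process is one microsimulation loop per patient under a known
risk-equation set — the same code path the validated models run — so the
model class can in principle achieve the stochastic ceiling, and validating
the truth equations against their own synthetic trial must outperform any
perturbed candidate. Censoring is non-informative given covariates.

Covariate joint distributions are plausible placeholders (the source trial's
patient-level data are proprietary); see docs/methods.md for what these
synthetic data do and do not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    write_equations,
    write_patients,
    write_utility_table,
    read_equations,
    read_patients,
    read_utility_table,
)
from .microsim import RiskEquation, RiskEquationSet, SimConfig, simulate_loop
from .qaly import (
    EventOccurrence,
    EventType,
    InputError,
    PatientRecord,
    UtilityTable,
)

__all__ = [
    "CohortSpec",
    "FollowUpSpec",
    "generate_cohort",
    "default_truth_equations",
    "perturbed_equations",
    "generate_truth_histories",
    "generate_trial",
    "write_fixture",
]


@dataclass(frozen=True)
class CohortSpec:
    """Baseline cohort distribution parameters."""

    n_patients: int = 1000
    age_mean: float = 62.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (40.0, 88.0)
    female_frac: float = 0.38
    prior_cvd_frac: float = 0.73
    diabetes_duration_median: float = 12.0
    diabetes_duration_log_sd: float = 0.6
    #: conditional probabilities of each CVD component given prior CVD
    cvd_pattern: dict = field(
        default_factory=lambda: {"MI": 0.45, "IHD": 0.60, "STROKE": 0.17}
    )
    #: marginal baseline prevalences of non-CVD event history
    history_prevalence: dict = field(
        default_factory=lambda: {
            "CHF": 0.16,
            "AMPUTATION": 0.02,
            "BLINDNESS": 0.03,
            "RENAL_FAILURE": 0.02,
            "ULCER": 0.04,
        }
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InputError("n_patients must be >= 1")
        fracs = [self.female_frac, self.prior_cvd_frac, *self.cvd_pattern.values(),
                 *self.history_prevalence.values()]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise InputError("all fractions must lie in [0, 1]")


@dataclass(frozen=True)
class FollowUpSpec:
    """Censoring process: staggered entry plus annual withdrawals.

    Administrative censor times are uniform on ``admin_window`` (years of
    potential follow-up implied by staggered entry against a fixed study
    end), capped at ``max_years``; withdrawals occur with a constant annual
    probability. Defaults target a median observed follow-up of ~3.2 years
    under the default truth equations.
    """

    max_years: float = 7.0
    admin_window: tuple[float, float] = (2.5, 4.5)
    annual_withdrawal_prob: float = 0.05
    target_median: float = 3.2

    def __post_init__(self) -> None:
        lo, hi = self.admin_window
        if not 0 < lo <= hi <= self.max_years:
            raise InputError("admin_window must satisfy 0 < lo <= hi <= max_years")
        if not 0 <= self.annual_withdrawal_prob < 1:
            raise InputError("annual_withdrawal_prob must lie in [0, 1)")
        if not 0 < self.target_median <= self.max_years:
            raise InputError("target_median must lie in (0, max_years]")


def generate_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Baseline patient table, reproducible by seed.

    Prior cardiovascular disease (any of MI/IHD/stroke history) is drawn
    first at the specified marginal fraction, then the component pattern
    conditional on it (at least one component guaranteed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    n = spec.n_patients
    age = np.clip(
        rng.normal(spec.age_mean, spec.age_sd, n), *spec.age_range
    ).round(1)
    female = rng.random(n) < spec.female_frac
    dur = np.exp(
        rng.normal(np.log(spec.diabetes_duration_median),
                   spec.diabetes_duration_log_sd, n)
    ).round(1)
    cvd = rng.random(n) < spec.prior_cvd_frac
    rows = {"patient_id": np.arange(1, n + 1).astype(str),
            "age": age, "female": female.astype(int),
            "diabetes_duration": dur}
    comp_names = list(spec.cvd_pattern)
    comp = {c: (rng.random(n) < spec.cvd_pattern[c]) & cvd for c in comp_names}
    none = cvd.copy()
    for c in comp_names:
        none &= ~comp[c]
    if np.any(none):
        # guarantee at least one component for prior-CVD patients
        probs = np.array([spec.cvd_pattern[c] for c in comp_names], dtype=float)
        probs /= probs.sum()
        pick = rng.choice(len(comp_names), size=int(none.sum()), p=probs)
        idx = np.flatnonzero(none)
        for k, c in enumerate(comp_names):
            comp[c][idx[pick == k]] = True
    for ev in EventType:
        if ev.value in comp:
            rows[f"hist_{ev.value}"] = comp[ev.value].astype(int)
        elif ev.value in spec.history_prevalence:
            rows[f"hist_{ev.value}"] = (
                rng.random(n) < spec.history_prevalence[ev.value]
            ).astype(int)
        else:
            rows[f"hist_{ev.value}"] = 0
    return pd.DataFrame(rows)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _eq(base_p: float, *, age: float = 0.0, ref_age: float = 62.0,
        second: bool = False, **terms: float) -> RiskEquation:
    """Logistic equation with annual probability ``base_p`` at the reference
    age for a male patient with no history."""
    coef = {"intercept": _logit(base_p) - age * ref_age}
    if age:
        coef["age"] = age
    coef.update(terms)
    return RiskEquation("logistic", coef, second_event=second)


def default_truth_equations() -> RiskEquationSet:
    """Plausible annual-risk equations for a contemporary T2D trial cohort.

    Intercepts correspond to annual event probabilities of roughly 0.3–2%
    at age 62 with no history; history terms raise subsequent risks and the
    death equation sees same-year MI/stroke indicators (acute fatality).
    """
    events = {
        EventType.MI: _eq(0.014, age=0.04, second=True,
                          hist_MI=0.6, hist_IHD=0.5, hist_STROKE=0.3, female=-0.3),
        EventType.STROKE: _eq(0.008, age=0.05, second=True,
                              hist_STROKE=0.7, hist_MI=0.3),
        EventType.IHD: _eq(0.010, age=0.03, hist_MI=0.4),
        EventType.CHF: _eq(0.010, age=0.06, hist_MI=0.6, hist_IHD=0.3),
        EventType.BLINDNESS: _eq(0.003, diabetes_duration=0.02),
        EventType.AMPUTATION: _eq(0.0025, second=True,
                                  hist_ULCER=1.0, diabetes_duration=0.02),
        EventType.RENAL_FAILURE: _eq(0.003, diabetes_duration=0.02),
        EventType.ULCER: _eq(0.006, diabetes_duration=0.02),
    }
    death = _eq(0.012, age=0.08,
                hist_MI=0.5, hist_STROKE=0.5, hist_CHF=0.6,
                hist_RENAL_FAILURE=0.9, hist_AMPUTATION=0.6,
                new_MI=1.2, new_STROKE=1.2)
    return RiskEquationSet(events, death)


def perturbed_equations(
    eqs: RiskEquationSet, intercept_shift: float = 0.5
) -> RiskEquationSet:
    """A miscalibrated candidate: every intercept shifted by a constant.

    Raising all intercepts inflates event and death rates, biasing predicted
    QALYs downward — the stand-in for a poorly calibrated competitor model.
    """
    def shift(eq: RiskEquation) -> RiskEquation:
        coef = dict(eq.coefficients)
        coef["intercept"] = coef.get("intercept", 0.0) + intercept_shift
        return RiskEquation(eq.form, coef, eq.second_event)

    return RiskEquationSet(
        {ev: shift(eq) for ev, eq in eqs.events.items()}, shift(eqs.death)
    )


def generate_truth_histories(
    patients: pd.DataFrame,
    truth_eqs: RiskEquationSet,
    followup: FollowUpSpec = FollowUpSpec(),
    seed: int = 0,
    table: UtilityTable | None = None,
) -> list[PatientRecord]:
    """One realized trajectory per patient, then censoring.

    Each patient's history is a single microsimulation loop under the truth
    equations over the maximum horizon. Deaths fall mid-cycle (cycle − 0.5).
    The censor time is the minimum of the administrative end and the
    withdrawal time; deaths after it are unobserved, events are truncated at
    exit. The administrative end time is recorded for everyone, including
    decedents.
    """
    table = table or UtilityTable.default()
    horizon = int(np.ceil(followup.max_years))
    config = SimConfig(n_loops=1, seed=seed, horizon_years=horizon)
    rng_cens = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    n = len(patients)
    admin = rng_cens.uniform(*followup.admin_window, size=n)
    admin = np.minimum(admin, followup.max_years)
    w = followup.annual_withdrawal_prob
    if w > 0:
        withdraw = rng_cens.exponential(1.0 / -np.log1p(-w), size=n)
    else:
        withdraw = np.full(n, np.inf)

    records: list[PatientRecord] = []
    for i, row in enumerate(patients.itertuples(index=False)):
        prior = {
            ev: int(getattr(row, f"hist_{ev.value}", 0)) for ev in EventType
        }
        base = PatientRecord(
            patient_id=str(row.patient_id),
            age=float(row.age),
            female=bool(row.female),
            diabetes_duration=float(row.diabetes_duration),
            prior_events={ev: c for ev, c in prior.items() if c},
            censor_time=followup.max_years,
        )
        loop = simulate_loop(base, truth_eqs, table, config)
        censor = float(min(admin[i], withdraw[i], followup.max_years))
        death_time = None
        if loop.death_cycle is not None:
            d = loop.death_cycle - 0.5
            if d <= censor:
                death_time = d
        end = death_time if death_time is not None else censor
        events = [
            EventOccurrence(o.event_type, o.occurrence_index, o.year_index)
            for o in loop.events
            if o.year_index - 1 < end
        ]
        records.append(
            PatientRecord(
                patient_id=base.patient_id,
                age=base.age,
                female=base.female,
                diabetes_duration=base.diabetes_duration,
                prior_events=base.prior_events,
                events=events,
                death_time=death_time,
                censor_time=censor,
                administrative_end_time=float(admin[i]),
            )
        )
    return records


def generate_trial(
    n_patients: int = 1000,
    seed: int = 0,
    cohort_spec: CohortSpec | None = None,
    followup: FollowUpSpec = FollowUpSpec(),
    truth_eqs: RiskEquationSet | None = None,
) -> tuple[list[PatientRecord], RiskEquationSet]:
    """Convenience wrapper: cohort + truth histories in one call."""
    spec = cohort_spec or CohortSpec(n_patients=n_patients)
    if spec.n_patients != n_patients and cohort_spec is None:
        spec = CohortSpec(n_patients=n_patients)
    eqs = truth_eqs or default_truth_equations()
    patients = generate_cohort(spec, seed=seed)
    records = generate_truth_histories(patients, eqs, followup, seed=seed)
    return records, eqs


def write_fixture(
    out_dir,
    n_patients: int = 50,
    seed: int = 0,
    cohort_spec: CohortSpec | None = None,
    followup: FollowUpSpec = FollowUpSpec(),
    truth_eqs: RiskEquationSet | None = None,
    table: UtilityTable | None = None,
) -> dict:
    """Write a complete synthetic fixture to ``out_dir``.

    Produces patients.csv, events.csv, truth_eqs.yaml, utilities.yaml, and
    manifest.json (seed and sizes); regeneration with the manifest's seed
    reproduces the files byte-identically, and the CSVs round-trip through
    the package readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = table or UtilityTable.default()
    records, eqs = generate_trial(
        n_patients, seed, cohort_spec, followup, truth_eqs
    )
    write_patients(records, out / "patients.csv", out / "events.csv")
    write_equations(eqs, out / "truth_eqs.yaml")
    write_utility_table(table, out / "utilities.yaml")
    manifest = {
        "seed": seed,
        "n_patients": n_patients,
        "max_follow_up_years": followup.max_years,
        "files": ["patients.csv", "events.csv", "truth_eqs.yaml", "utilities.yaml"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_fixture(fixture_dir):
    """(records, truth equations, utility table) from a fixture directory."""
    d = Path(fixture_dir)
    records = read_patients(d / "patients.csv", d / "events.csv")
    eqs = read_equations(d / "truth_eqs.yaml")
    table = read_utility_table(d / "utilities.yaml")
    return records, eqs, table
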