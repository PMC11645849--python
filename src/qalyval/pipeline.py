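"""End-to-end validation study orchestration.

``run_validation`` loads (or receives) trial records, runs each candidate
risk-equation set through the microsimulator for every patient, computes
trial and model QALYs under the base case and the sensitivity-analysis
catalogue, evaluates the five performance metrics overall and by subgroup,
compares observed against predicted cumulative incidence per event, and
writes tidy CSV reports plus a run manifest.

The sensitivity-analysis catalogue:

==== ==========================================================
SA1  second MI/stroke/amputation/blindness/ulcer since
     randomization counted in trial QALYs regardless of history
SA2  no disutility from second MI/stroke/amputation
     (subset with no prior MI/stroke/amputation)
SA3  SA2 plus no ulcer disutility (same subset)
SA4  alternative utility table
SA5  censor-year QALYs excluded
SA6  discounting at 3.5% per annum
SA7  1-year horizon
SA8  3-year horizon
==== ==========================================================

plus the life-year analyses (model life-years v. trial life-years) and the
two extreme-bias cross comparisons (model life-years v. trial QALYs, model
QALYs v. trial life-years) that stress-test the metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import incidence
from .metrics import MetricReport, PairedPrediction, evaluate, reports_to_frame
from .microsim import PatientSimResult, RiskEquationSet, SimConfig, run_patient
from .qaly import (
    ConfigurationError,
    EventType,
    InputError,
    PatientRecord,
    QalyOptions,
    SECOND_EVENT_TYPES,
    SecondEventRule,
    UtilityTable,
    trial_qalys,
)

logger = logging.getLogger("qalyval")

__all__ = ["Analysis", "ANALYSIS_CATALOGUE", "ValidationConfig",
           "ValidationResult", "run_validation", "report"]


@dataclass(frozen=True)
class Analysis:
    """One row of the analysis catalogue.

    ``model_outcome`` / ``trial_outcome`` select QALYs or life-years for
    each side; ``subset`` optionally restricts the cohort.
    """

    name: str
    model_options: QalyOptions = QalyOptions()
    trial_options: QalyOptions = QalyOptions()
    model_outcome: str = "qalys"
    trial_outcome: str = "qalys"
    table_name: str = "default"
    subset: str | None = None  # None or "no_prior_second_event_types"


def _ly(opts: QalyOptions) -> QalyOptions:
    return QalyOptions(
        discount_rate=opts.discount_rate,
        horizon_years=opts.horizon_years,
        exclude_censor_year=opts.exclude_censor_year,
        life_years_mode=True,
        second_event_rule=opts.second_event_rule,
    )


ANALYSIS_CATALOGUE: dict[str, Analysis] = {
    "base_case": Analysis("base_case"),
    "life_years": Analysis(
        "life_years",
        model_options=_ly(QalyOptions()),
        trial_options=_ly(QalyOptions()),
        model_outcome="life_years",
        trial_outcome="life_years",
    ),
    "model_ly_vs_trial_qalys": Analysis(
        "model_ly_vs_trial_qalys",
        model_options=_ly(QalyOptions()),
        model_outcome="life_years",
    ),
    "model_qalys_vs_trial_ly": Analysis(
        "model_qalys_vs_trial_ly",
        trial_options=_ly(QalyOptions()),
        trial_outcome="life_years",
    ),
    "sa1_count_all_since_randomization": Analysis(
        "sa1_count_all_since_randomization",
        trial_options=QalyOptions(
            second_event_rule=SecondEventRule.COUNT_ALL_SINCE_RANDOMIZATION
        ),
    ),
    "sa2_exclude_second_events": Analysis(
        "sa2_exclude_second_events",
        model_options=QalyOptions(
            second_event_rule=SecondEventRule.EXCLUDE_SECOND_EVENTS
        ),
        trial_options=QalyOptions(
            second_event_rule=SecondEventRule.EXCLUDE_SECOND_EVENTS
        ),
        subset="no_prior_second_event_types",
    ),
    "sa3_exclude_second_events_and_ulcer": Analysis(
        "sa3_exclude_second_events_and_ulcer",
        model_options=QalyOptions(
            second_event_rule=SecondEventRule.EXCLUDE_SECOND_EVENTS_AND_ULCER
        ),
        trial_options=QalyOptions(
            second_event_rule=SecondEventRule.EXCLUDE_SECOND_EVENTS_AND_ULCER
        ),
        subset="no_prior_second_event_types",
    ),
    "sa4_alternative_utilities": Analysis(
        "sa4_alternative_utilities", table_name="alternative"
    ),
    "sa5_exclude_censor_year": Analysis(
        "sa5_exclude_censor_year",
        model_options=QalyOptions(exclude_censor_year=True),
        trial_options=QalyOptions(exclude_censor_year=True),
    ),
    "sa6_discount_3_5pct": Analysis(
        "sa6_discount_3_5pct",
        model_options=QalyOptions(discount_rate=0.035),
        trial_options=QalyOptions(discount_rate=0.035),
    ),
    "sa7_horizon_1y": Analysis(
        "sa7_horizon_1y",
        model_options=QalyOptions(horizon_years=1),
        trial_options=QalyOptions(horizon_years=1),
    ),
    "sa8_horizon_3y": Analysis(
        "sa8_horizon_3y",
        model_options=QalyOptions(horizon_years=3),
        trial_options=QalyOptions(horizon_years=3),
    ),
}

#: Subgroup definitions applied to the base-case analysis.
DEFAULT_SUBGROUPS = ("age_band", "prior_cvd", "duration_band")

#: Incidence curves compared between observed and predicted data.
DEFAULT_CURVES: tuple[tuple[str, str, int], ...] = tuple(
    [(ev.value, "no_history", 1) for ev in EventType]
    + [(name, "with_history", 1) for name in sorted(
        e.value for e in SECOND_EVENT_TYPES)]
    + [("DEATH", "all", 1), ("ANY_EVENT", "all", 1)]
)


@dataclass
class ValidationConfig:
    """Configuration of a full validation run."""

    models: Mapping[str, RiskEquationSet]
    utility_tables: Mapping[str, UtilityTable] = field(default_factory=dict)
    n_loops: int = 400
    seed: int = 0
    horizon_years: int = 7
    analyses: Sequence[str] = tuple(ANALYSIS_CATALOGUE)
    subgroups: Sequence[str] = DEFAULT_SUBGROUPS
    curves: Sequence[tuple[str, str, int]] = DEFAULT_CURVES

    def __post_init__(self) -> None:
        unknown = [a for a in self.analyses if a not in ANALYSIS_CATALOGUE]
        if unknown:
            raise ConfigurationError(f"unknown analyses: {unknown}")
        tables = dict(self.utility_tables)
        tables.setdefault("default", UtilityTable.default())
        tables.setdefault("alternative", UtilityTable.alternative())
        self.utility_tables = tables
        for name, eqs in self.models.items():
            missing = [
                ev.value for ev in eqs.events
                if ev not in tables["default"].decrements
            ]
            if missing:
                raise ConfigurationError(
                    f"model {name!r} simulates events with no utility decrement "
                    f"entry: {missing}"
                )


@dataclass
class ValidationResult:
    metrics: pd.DataFrame
    curves: pd.DataFrame
    curve_comparison: pd.DataFrame
    paired: dict[tuple[str, str], PairedPrediction]
    manifest: dict


def subgroup_labels(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Standard subgroup labels at randomization."""
    cvd_types = (EventType.MI, EventType.IHD, EventType.STROKE)
    return pd.DataFrame(
        {
            "age_band": ["<65" if r.age < 65 else ">=65" for r in records],
            "prior_cvd": [
                "prior_mi_ihd_stroke"
                if any(r.prior_count(ev) for ev in cvd_types)
                else "no_prior_mi_ihd_stroke"
                for r in records
            ],
            "duration_band": [
                "<5y" if r.diabetes_duration < 5 else ">=5y" for r in records
            ],
        }
    )


def _subset_mask(records: Sequence[PatientRecord], rule: str | None) -> np.ndarray:
    if rule is None:
        return np.ones(len(records), dtype=bool)
    if rule == "no_prior_second_event_types":
        return np.array(
            [
                not any(r.prior_count(ev) for ev in SECOND_EVENT_TYPES)
                for r in records
            ]
        )
    raise ConfigurationError(f"unknown subset rule {rule!r}")


def run_validation(
    records: Sequence[PatientRecord],
    config: ValidationConfig,
    out_dir=None,
) -> ValidationResult:
    """Run the full validation study for every candidate model.

    Each patient is simulated once per model; every analysis then derives
    its paired (model, trial) outcomes from the stored loop arrays without
    resimulating. Deterministic under a fixed seed.
    """
    records = list(records)
    if not records:
        raise InputError("no patient records supplied")
    logger.info("validation: %d patients, %d model(s), %d loops",
                len(records), len(config.models), config.n_loops)
    labels = subgroup_labels(records)
    sim_config = SimConfig(
        n_loops=config.n_loops, seed=config.seed,
        horizon_years=config.horizon_years,
    )
    default_table = config.utility_tables["default"]

    sims: dict[str, list[PatientSimResult]] = {}
    for model_name, eqs in config.models.items():
        sims[model_name] = [
            run_patient(rec, eqs, default_table, sim_config) for rec in records
        ]
        logger.info("simulated %d patients under model %s",
                    len(records), model_name)

    all_reports: list[MetricReport] = []
    paired_out: dict[tuple[str, str], PairedPrediction] = {}
    for analysis_name in config.analyses:
        spec = ANALYSIS_CATALOGUE[analysis_name]
        table = config.utility_tables[spec.table_name]
        mask = _subset_mask(records, spec.subset)
        subset_records = [r for r, keep in zip(records, mask) if keep]
        if not subset_records:
            logger.warning("analysis %s: empty subset, skipped", analysis_name)
            continue
        t_vals = np.array(
            [trial_qalys(r, table, spec.trial_options) for r in subset_records]
        )
        for model_name in config.models:
            subset_sims = [s for s, keep in zip(sims[model_name], mask) if keep]
            m_vals = np.array(
                [_model_outcome(s, table, spec.model_options)
                 for s in subset_sims]
            )
            paired = PairedPrediction(m_vals, t_vals, labels[mask].reset_index(drop=True))
            cols = config.subgroups if analysis_name == "base_case" else None
            all_reports.extend(
                evaluate(paired, cols, analysis=analysis_name,
                         model_name=model_name)
            )
            paired_out[(analysis_name, model_name)] = paired
        logger.info("analysis %s: n=%d", analysis_name, len(subset_records))

    metrics_df = reports_to_frame(all_reports)

    curve_frames, cmp_frames = [], []
    for event, subset_rule, order in config.curves:
        try:
            obs = incidence.observed_cif(records, event, subset_rule)
        except InputError:
            logger.warning("no observed curve for %s (%s)", event, subset_rule)
            continue
        curve_frames.append(obs.to_frame())
        for model_name in config.models:
            eff_order = order
            if subset_rule == "with_history":
                # patients with baseline history: their first simulated
                # occurrence is the second event overall
                eff_order = 1
            pred = incidence.predicted_cif(
                sims[model_name], event, order=eff_order, subset_rule=subset_rule
            )
            pred_frame = pred.to_frame()
            pred_frame["source"] = f"predicted:{model_name}"
            curve_frames.append(pred_frame)
            cmp = incidence.compare_curves(obs, pred)
            cmp["model"] = model_name
            cmp["subset"] = subset_rule
            cmp_frames.append(cmp)
    curves_df = pd.concat(curve_frames, ignore_index=True) if curve_frames else pd.DataFrame()
    cmp_df = pd.concat(cmp_frames, ignore_index=True) if cmp_frames else pd.DataFrame()

    manifest = {
        "n_patients": len(records),
        "models": sorted(config.models),
        "n_loops": config.n_loops,
        "seed": config.seed,
        "horizon_years": config.horizon_years,
        "analyses": list(config.analyses),
        "config_hash": _config_hash(config),
    }
    result = ValidationResult(metrics_df, curves_df, cmp_df, paired_out, manifest)
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _model_outcome(
    sim: PatientSimResult, table: UtilityTable, options: QalyOptions
) -> float:
    rec = sim.record
    censor = (
        rec.administrative_end_time if rec.death_time is not None
        else rec.censor_time
    )
    from .qaly import model_qalys_from_loops

    per_loop = model_qalys_from_loops(
        sim.loop_utilities(table, options.second_event_rule),
        sim.death_cycles,
        float(censor),
        options,
    )
    return float(per_loop.mean())


def _config_hash(config: ValidationConfig) -> str:
    payload = {
        "models": {k: v.to_dict() for k, v in sorted(config.models.items())},
        "tables": {k: t.to_dict() for k, t in sorted(config.utility_tables.items())},
        "n_loops": config.n_loops,
        "seed": config.seed,
        "horizon_years": config.horizon_years,
        "analyses": list(config.analyses),
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _write_outputs(result: ValidationResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report(result.metrics).to_csv(out / "metrics.csv", index=False)
    result.metrics.to_csv(out / "metrics_full_precision.csv", index=False)
    result.curves.to_csv(out / "curves.csv", index=False)
    result.curve_comparison.to_csv(out / "curve_comparison.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("wrote reports to %s", out)


def report(metrics: pd.DataFrame) -> pd.DataFrame:
    """Display-ready metric table, rounded to 3 decimal places.

    Mirrors the canonical results-table layout: analysis, model, subgroup,
    n, mean (SD) of trial and model outcomes, then Q², R², MAE, MSE, bias.
    """
    if metrics.empty:
        return pd.DataFrame(
            columns=["analysis", "model", "subgroup", "n", "trial_mean_sd",
                     "model_mean_sd", "q2", "r2", "mae", "mse", "bias"]
        )
    out = metrics.copy()
    out["trial_mean_sd"] = [
        f"{m:.3f} ({s:.3f})" for m, s in zip(out.mean_trial, out.sd_trial)
    ]
    out["model_mean_sd"] = [
        f"{m:.3f} ({s:.3f})" for m, s in zip(out.mean_model, out.sd_model)
    ]
    cols = ["analysis", "model", "subgroup", "n", "trial_mean_sd",
            "model_mean_sd", "q2", "r2", "mae", "mse", "bias"]
    out = out[cols]
    for c in ("q2", "r2", "mae", "mse", "bias"):
        out[c] = out[c].round(3)
    return out
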