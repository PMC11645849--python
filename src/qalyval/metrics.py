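"""Prediction-accuracy metrics for paired model/trial outcomes.

Five metrics quantify how well a simulation model's per-patient predictions
``M_i`` reproduce the observed per-patient outcomes ``T_i`` (QALYs or
life-years over each participant's follow-up):

* ``bias``  — mean residual, ``mean(M - T)``; negative = underestimation.
* ``mse``   — mean squared error (N denominator).
* ``mae``   — mean absolute error.
* ``r2``    — coefficient of determination from regressing T on M by OLS;
  the regression recalibrates slope and intercept, so R² measures
  discrimination only and is blind to bias.
* ``q2``    — proportional reduction in error, ``1 - MSE / SD²`` where SD is
  the sample standard deviation of the observed outcomes (N−1 denominator).
  Q² captures both discrimination and bias, can be compared across samples
  and outcomes, and — unlike R² — can be negative for very poor predictors.

Note the deliberate denominator asymmetry in Q²: MSE uses N while SD² uses
N−1, exactly as the metric is defined; the resulting (N−1)/N factor is part
of the definition and is not "harmonized" away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .qaly import InputError

__all__ = [
    "PairedPrediction",
    "CalibrationFit",
    "MetricReport",
    "bias",
    "mse",
    "mae",
    "r_squared",
    "q_squared",
    "q_squared_from_summary",
    "compute_report",
    "evaluate",
]


@dataclass(frozen=True)
class PairedPrediction:
    """Per-patient paired (model, trial) outcomes with subgroup labels."""

    model: np.ndarray
    trial: np.ndarray
    subgroups: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.model, dtype=float)
        t = np.asarray(self.trial, dtype=float)
        object.__setattr__(self, "model", m)
        object.__setattr__(self, "trial", t)
        if m.shape != t.shape or m.ndim != 1:
            raise InputError("model and trial must be 1-d arrays of equal length")
        if m.size < 2:
            raise InputError("at least 2 paired observations are required")
        if np.isnan(m).any() or np.isnan(t).any():
            raise InputError("paired predictions must not contain missing values")
        if self.subgroups is not None and len(self.subgroups) != m.size:
            raise InputError("subgroup labels must cover every patient")

    def __len__(self) -> int:
        return self.model.size


@dataclass(frozen=True)
class CalibrationFit:
    """OLS fit of trial outcomes on model outcomes: ``T ≈ slope·M + intercept``."""

    slope: float
    intercept: float


@dataclass(frozen=True)
class MetricReport:
    analysis: str
    model: str
    subgroup: str
    n: int
    mean_trial: float
    sd_trial: float
    mean_model: float
    sd_model: float
    q2: float
    r2: float
    mae: float
    mse: float
    bias: float


def _arrays(model, trial) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(model, dtype=float)
    t = np.asarray(trial, dtype=float)
    if m.shape != t.shape:
        raise InputError("model and trial must have equal length")
    if m.size == 0:
        raise InputError("metrics are undefined for empty inputs")
    return m, t


def bias(model: Sequence[float], trial: Sequence[float]) -> float:
    """Mean residual ``mean(M - T)``; negative values mean underestimation."""
    m, t = _arrays(model, trial)
    return float(np.mean(m - t))


def mse(model: Sequence[float], trial: Sequence[float]) -> float:
    """Mean squared error ``mean((M - T)²)`` (N denominator)."""
    m, t = _arrays(model, trial)
    return float(np.mean((m - t) ** 2))


def mae(model: Sequence[float], trial: Sequence[float]) -> float:
    """Mean absolute error ``mean(|M - T|)``."""
    m, t = _arrays(model, trial)
    return float(np.mean(np.abs(m - t)))


def r_squared(
    model: Sequence[float], trial: Sequence[float]
) -> tuple[float, CalibrationFit]:
    """R² of the OLS recalibration of trial on model outcomes.

    Equals the squared Pearson correlation of M and T, hence invariant to
    affine transforms of the predictions. A constant predictor (zero model
    variance) explains nothing: returns 0 with a warning, slope undefined
    (reported as 0 with intercept ``mean(T)``).
    """
    m, t = _arrays(model, trial)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise InputError("r_squared is undefined when trial outcomes are constant")
    var_m = float(np.var(m))
    if var_m == 0.0:
        warnings.warn(
            "model predictions are constant; regression slope undefined, R2 = 0",
            stacklevel=2,
        )
        return 0.0, CalibrationFit(0.0, float(t.mean()))
    slope = float(np.cov(m, t, bias=True)[0, 1] / var_m)
    intercept = float(t.mean() - slope * m.mean())
    ss_res = float(np.sum((slope * m + intercept - t) ** 2))
    return 1.0 - ss_res / ss_tot, CalibrationFit(slope, intercept)


def q_squared(model: Sequence[float], trial: Sequence[float]) -> float:
    """Proportional reduction in error ``1 - MSE / SD²``.

    SD is the sample standard deviation (N−1 denominator) of the observed
    outcomes; MSE uses the N denominator. Equals 1 only for a perfect
    predictor and can be negative for very poor ones.
    """
    m, t = _arrays(model, trial)
    if m.size < 2:
        raise InputError("q_squared requires at least 2 observations")
    sd2 = float(np.var(t, ddof=1))
    if sd2 == 0.0:
        raise InputError("q_squared is undefined when trial outcomes are constant")
    return 1.0 - float(np.mean((m - t) ** 2)) / sd2


def q_squared_from_summary(mse_value: float, sd: float) -> float:
    """Q² from summary statistics: ``1 - mse / sd²``.

    Allows the metric to be recomputed from a reported MSE and observed-
    outcome standard deviation without patient-level data.
    """
    if sd <= 0:
        raise InputError("sd must be > 0")
    if mse_value < 0:
        raise InputError("mse must be >= 0")
    return 1.0 - mse_value / sd**2


def compute_report(
    model: Sequence[float],
    trial: Sequence[float],
    analysis: str = "base_case",
    model_name: str = "model",
    subgroup: str = "overall",
) -> MetricReport:
    """All five metrics plus summary statistics for one (analysis, subgroup)."""
    m, t = _arrays(model, trial)
    r2, _ = r_squared(m, t)
    return MetricReport(
        analysis=analysis,
        model=model_name,
        subgroup=subgroup,
        n=int(m.size),
        mean_trial=float(t.mean()),
        sd_trial=float(np.std(t, ddof=1)),
        mean_model=float(m.mean()),
        sd_model=float(np.std(m, ddof=1)),
        q2=q_squared(m, t),
        r2=r2,
        mae=mae(m, t),
        mse=mse(m, t),
        bias=bias(m, t),
    )


def evaluate(
    paired: PairedPrediction,
    subgroup_columns: Sequence[str] | None = None,
    analysis: str = "base_case",
    model_name: str = "model",
) -> list[MetricReport]:
    """Metric reports overall and within each level of each subgroup column.

    Subgroup metrics are computed on subgroup members only. Empty subgroups
    are omitted with a warning.
    """
    reports = [compute_report(paired.model, paired.trial, analysis, model_name)]
    if not subgroup_columns:
        return reports
    if paired.subgroups is None:
        raise InputError("paired prediction carries no subgroup labels")
    for col in subgroup_columns:
        if col not in paired.subgroups.columns:
            raise InputError(f"unknown subgroup column {col!r}")
        labels = paired.subgroups[col]
        for level in pd.unique(labels):
            mask = (labels == level).to_numpy()
            if mask.sum() < 2:
                warnings.warn(
                    f"subgroup {col}={level} has fewer than 2 members; omitted",
                    stacklevel=2,
                )
                continue
            reports.append(
                compute_report(
                    paired.model[mask],
                    paired.trial[mask],
                    analysis,
                    model_name,
                    subgroup=f"{col}={level}",
                )
            )
    return reports


def reports_to_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Tidy DataFrame of metric reports (one row per analysis × subgroup)."""
    return pd.DataFrame([r.__dict__ for r in reports])
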