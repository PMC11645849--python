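"""Cumulative incidence with death as a competing risk.

Observed curves use the Aalen–Johansen estimator
``CIF(t) = Σ_{τ_j ≤ t} Ŝ(τ_j⁻) · d_j / n_j`` with ``Ŝ`` the all-cause
Kaplan–Meier survival among the analysis subset, with pointwise 95%
confidence intervals on the log(−log) scale using an Aalen-type variance.
Predicted curves are the simulator's mean cumulative events over time
divided by the number of individuals at the start of simulation, stepping
at annual cycle boundaries.

Time conventions: an event in annual cycle ``y`` is placed at ``y − 0.5``
(mid-cycle), matching the half-cycle placement of deaths, so event/death
ties at the same recorded time arise naturally and are handled by
processing the event of interest and the competing death simultaneously at
that time (the event is never pre-empted by a same-time death). Observed
curves are interpolated onto cycle boundaries when compared with predicted
curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .microsim import PatientSimResult
from .qaly import EventType, InputError, PatientRecord

__all__ = [
    "CIFCurve",
    "observed_cif",
    "predicted_cif",
    "compare_curves",
    "aalen_johansen",
]

_SUBSET_RULES = ("no_history", "with_history", "all")


@dataclass
class CIFCurve:
    """A cumulative incidence curve (observed or predicted)."""

    event: str
    times: np.ndarray
    cif: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    source: str = "observed"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cif = np.asarray(self.cif, dtype=float)
        if np.any(np.diff(self.cif) < -1e-12):
            raise InputError("CIF must be non-decreasing")
        if np.any((self.cif < 0) | (self.cif > 1 + 1e-12)):
            raise InputError("CIF must lie in [0, 1]")

    def at(self, t) -> np.ndarray:
        """Step-function value(s) at time(s) ``t`` (right-continuous)."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        out = np.where(idx >= 0, self.cif[np.clip(idx, 0, None)], 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        d = {"event": self.event, "source": self.source, "time": self.times,
             "estimate": self.cif}
        if self.lo is not None:
            d["lo"] = self.lo
            d["hi"] = self.hi
        return pd.DataFrame(d)


def aalen_johansen(
    times: Sequence[float],
    causes: Sequence[int],
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Aalen–Johansen CIF for cause 1 with cause 2 competing.

    ``causes``: 1 = event of interest, 2 = competing death, 0 = censored.
    Returns (unique failure times, CIF, lo, hi). The variance is the
    Aalen-type estimator (as used by standard competing-risks software) and
    the CI is computed on the log(−log) scale.
    """
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=int)
    if times.size == 0:
        raise InputError("empty sample")
    if np.any(times < 0):
        raise InputError("times must be >= 0")

    fail_times = np.unique(times[causes > 0])
    cif = np.zeros(fail_times.size)
    surv_left = np.zeros(fail_times.size)  # S(τ−)
    n_at = np.zeros(fail_times.size)
    d_all = np.zeros(fail_times.size)
    d_ev = np.zeros(fail_times.size)

    s = 1.0
    f = 0.0
    for j, tau in enumerate(fail_times):
        at_risk = np.sum(times >= tau)
        d1 = np.sum((times == tau) & (causes == 1))
        d2 = np.sum((times == tau) & (causes == 2))
        surv_left[j] = s
        n_at[j] = at_risk
        d_all[j] = d1 + d2
        d_ev[j] = d1
        f += s * d1 / at_risk
        s *= 1.0 - (d1 + d2) / at_risk
        cif[j] = f

    var = _aalen_variance(cif, surv_left, n_at, d_all, d_ev)
    lo, hi = _loglog_ci(cif, np.sqrt(var), alpha)
    return fail_times, cif, lo, hi


def _aalen_variance(cif, surv_left, n, d_all, d_ev) -> np.ndarray:
    """Pointwise variance of the Aalen–Johansen CIF (Aalen-type estimator)."""
    m = cif.size
    var = np.zeros(m)
    for i in range(m):
        ci = cif[i]
        v = 0.0
        for j in range(i + 1):
            nj, dj, d1j = n[j], d_all[j], d_ev[j]
            diff = ci - cif[j]
            if nj > dj:
                v += diff**2 * dj / (nj * (nj - dj))
            v += surv_left[j] ** 2 * ((nj - d1j) / nj) * d1j / nj**2
            v -= 2.0 * diff * surv_left[j] * d1j / nj**2
        var[i] = max(v, 0.0)
    return var


def _loglog_ci(cif, se, alpha):
    """95% CI via the log(−log) transform; degenerate points get a flat CI."""
    z = norm.ppf(1 - alpha / 2)
    lo = cif.copy()
    hi = cif.copy()
    ok = (cif > 0) & (cif < 1) & (se > 0)
    theta = np.zeros_like(cif)
    theta[ok] = z * se[ok] / (cif[ok] * np.log(cif[ok]))
    a = cif[ok] ** np.exp(theta[ok])
    b = cif[ok] ** np.exp(-theta[ok])
    lo[ok] = np.minimum(a, b)
    hi[ok] = np.maximum(a, b)
    return lo, hi


def _event_time_cause(
    rec: PatientRecord, event: EventType | str
) -> tuple[float, int]:
    """(time, cause) for one patient: cause 1 event, 2 competing death, 0 censor."""
    death = rec.death_time
    if event == "DEATH":
        if death is not None:
            return float(death), 1
        return float(rec.censor_time), 0
    if event == "ANY_EVENT":
        # first event of any type, death included, so death is never competing
        cand = [occ.year_index - 0.5 for occ in rec.events]
        if death is not None:
            cand.append(float(death))
        if cand:
            return min(cand), 1
        return float(rec.censor_time), 0
    ev = EventType(event)
    occ_cycles = sorted(o.year_index for o in rec.events if o.event_type == ev)
    if occ_cycles:
        return occ_cycles[0] - 0.5, 1
    if death is not None:
        return float(death), 2
    return float(rec.censor_time), 0


def observed_cif(
    records: Sequence[PatientRecord],
    event: EventType | str,
    subset_rule: str = "no_history",
    alpha: float = 0.05,
) -> CIFCurve:
    """Observed cumulative incidence of an event, death competing.

    ``subset_rule``: ``"no_history"`` restricts to patients with no baseline
    history of the event (first events); ``"with_history"`` to patients with
    baseline history (their first in-trial occurrence is a second event);
    ``"all"`` uses everyone (death, any-event composite).
    """
    if subset_rule not in _SUBSET_RULES:
        raise InputError(f"subset_rule must be one of {_SUBSET_RULES}")
    if event in ("DEATH", "ANY_EVENT"):
        subset = list(records)
    else:
        ev = EventType(event)
        if subset_rule == "no_history":
            subset = [r for r in records if r.prior_count(ev) == 0]
        elif subset_rule == "with_history":
            subset = [r for r in records if r.prior_count(ev) > 0]
        else:
            subset = list(records)
    if not subset:
        raise InputError(f"no patients in subset {subset_rule!r} for {event!r}")

    tc = [_event_time_cause(r, event) for r in subset]
    times = np.array([t for t, _ in tc])
    causes = np.array([c for _, c in tc])
    if not np.any(causes == 1):
        warnings.warn(f"no observed occurrences of {event!r}; flat zero curve",
                      stacklevel=2)
        return CIFCurve(str(event), np.array([0.0]), np.array([0.0]),
                        np.array([0.0]), np.array([0.0]), source="observed")
    ft, cif, lo, hi = aalen_johansen(times, causes, alpha)
    ft = np.concatenate([[0.0], ft])
    cif = np.concatenate([[0.0], cif])
    lo = np.concatenate([[0.0], lo])
    hi = np.concatenate([[0.0], hi])
    label = event.value if isinstance(event, EventType) else str(event)
    return CIFCurve(label, ft, cif, lo, hi, source="observed")


def predicted_cif(
    results: Sequence[PatientSimResult],
    event: EventType | str,
    order: int = 1,
    subset_rule: str = "no_history",
) -> CIFCurve:
    """Predicted cumulative incidence: mean events over time / N at start.

    Averages, over the subset's patients, the per-patient fraction of
    Monte Carlo loops in which the ``order``-th simulated occurrence has
    happened by each cycle. Steps at cycle boundaries.
    """
    if event in ("DEATH", "ANY_EVENT"):
        subset = list(results)
    else:
        ev = EventType(event)
        if subset_rule == "no_history":
            subset = [r for r in results if r.record.prior_count(ev) == 0]
        elif subset_rule == "with_history":
            subset = [r for r in results if r.record.prior_count(ev) > 0]
        else:
            subset = list(results)
    if not subset:
        raise InputError(f"no simulated patients in subset {subset_rule!r}")
    horizon = subset[0].horizon
    inc = np.zeros(horizon)
    for res in subset:
        inc += res.incidence_by_cycle(event, order=order)
    inc /= len(subset)
    times = np.concatenate([[0.0], np.arange(1, horizon + 1, dtype=float)])
    cif = np.concatenate([[0.0], inc])
    label = event.value if isinstance(event, EventType) else str(event)
    return CIFCurve(label, times, cif, source="predicted")


def compare_curves(observed: CIFCurve, predicted: CIFCurve) -> pd.DataFrame:
    """Align an observed and a predicted curve on cycle boundaries.

    Returns one row per grid time with both estimates, the observed CI, and
    a flag for whether the prediction lies inside the CI; the
    ``fraction_in_ci`` column repeats the summary share of grid times in-CI.
    """
    if observed.event != predicted.event:
        raise InputError(
            f"event mismatch: {observed.event!r} vs {predicted.event!r}"
        )
    if observed.lo is None:
        raise InputError("observed curve must carry confidence limits")
    grid = predicted.times[predicted.times > 0]
    # restrict to grid times within observed follow-up
    grid = grid[grid <= observed.times.max() + 1.0]
    if grid.size == 0:
        raise InputError("no overlapping grid times")
    obs = observed.at(grid)
    obs_lo = _step_at(observed.times, observed.lo, grid)
    obs_hi = _step_at(observed.times, observed.hi, grid)
    pred = predicted.at(grid)
    in_ci = (pred >= obs_lo) & (pred <= obs_hi)
    frame = pd.DataFrame(
        {
            "event": observed.event,
            "time": grid,
            "observed": obs,
            "obs_lo": obs_lo,
            "obs_hi": obs_hi,
            "predicted": pred,
            "in_ci": in_ci,
        }
    )
    frame["fraction_in_ci"] = in_ci.mean()
    return frame


def _step_at(times, values, grid):
    idx = np.searchsorted(times, grid, side="right") - 1
    return np.where(idx >= 0, np.asarray(values)[np.clip(idx, 0, None)], 0.0)


def plot_comparison(
    observed: CIFCurve,
    predicted: Sequence[CIFCurve] | CIFCurve,
    path=None,
    labels: Sequence[str] | None = None,
):
    """Observed CIF with 95% CI band and predicted step curves overlaid.

    Saves to ``path`` when given (format from the extension), otherwise
    returns the matplotlib figure.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(predicted, CIFCurve):
        predicted = [predicted]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.step(observed.times, observed.cif, where="post", color="black",
            label="observed")
    if observed.lo is not None:
        ax.fill_between(observed.times, observed.lo, observed.hi,
                        step="post", alpha=0.2, color="gray", label="95% CI")
    for i, pred in enumerate(predicted):
        label = labels[i] if labels else f"predicted {i + 1}"
        ax.step(pred.times, pred.cif, where="post", label=label)
    ax.set_xlabel("years since randomization")
    ax.set_ylabel("cumulative incidence")
    ax.set_title(observed.event)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
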