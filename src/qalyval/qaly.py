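"""QALY accounting on an annual-cycle grid with half-cycle correction.

Converts a patient's event history plus follow-up information into an annual
utility trace and a total (optionally discounted) quality-adjusted life-year
count. The same accounting rules serve two purposes:

* **trial QALYs** — the model's utility assumptions applied to the events and
  survival a participant actually experienced in the trial;
* **model QALYs** — the same rules applied to each Monte Carlo loop of the
  microsimulator, then averaged over loops.

Conventions (shared with the simulation engine):

* time is divided into annual cycles ``t = 1, 2, ...``; clinical events occur
  at the *start* of a cycle and decrement utility in that cycle (and possibly
  subsequent cycles);
* death occurs halfway through its cycle, so the death cycle accrues half a
  cycle's utility (half-cycle correction);
* the cycle in which a participant is censored accrues the fraction of the
  year for which they remained under observation.

Utilities are additive: each counted event occurrence subtracts its decrement
from the baseline utility. There is **no floor** — with enough concurrent
decrements the annual utility can go negative. This mirrors the additive
model being validated and is intentional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EventType",
    "SecondEventRule",
    "ConfigurationError",
    "InputError",
    "Decrement",
    "UtilityTable",
    "EventOccurrence",
    "PatientRecord",
    "UtilityTrace",
    "QalyOptions",
    "build_utility_trace",
    "qalys_from_trace",
    "trial_qalys",
    "model_qalys",
    "model_qalys_from_loops",
    "counted_occurrences",
]


class ConfigurationError(Exception):
    """A utility table / equation set is inconsistent with the data."""


class InputError(ValueError):
    """Malformed patient-level input."""


class EventType(str, Enum):
    """Non-fatal clinical events tracked by the framework.

    Death is not an event type: it is carried on the follow-up side of a
    patient record (``death_time``) and on the simulator side as the death
    cycle of a loop.
    """

    IHD = "IHD"
    MI = "MI"
    STROKE = "STROKE"
    CHF = "CHF"
    BLINDNESS = "BLINDNESS"
    AMPUTATION = "AMPUTATION"
    RENAL_FAILURE = "RENAL_FAILURE"
    ULCER = "ULCER"


#: Event types whose second occurrence carries the same utility impact as the
#: first under the default counting rule (third occurrences never count).
SECOND_EVENT_TYPES = frozenset(
    {EventType.MI, EventType.STROKE, EventType.AMPUTATION}
)

#: Event types whose second occurrence since randomization is counted under
#: the count-all sensitivity rule regardless of baseline history.
_COUNT_ALL_SECOND = SECOND_EVENT_TYPES | {EventType.BLINDNESS, EventType.ULCER}


class SecondEventRule(str, Enum):
    """How repeat occurrences of the same event are counted for utility."""

    DEFAULT = "default"
    COUNT_ALL_SINCE_RANDOMIZATION = "count_all_since_randomization"
    EXCLUDE_SECOND_EVENTS = "exclude_second_events"
    EXCLUDE_SECOND_EVENTS_AND_ULCER = "exclude_second_events_and_ulcer"


@dataclass(frozen=True)
class Decrement:
    """Utility decrement magnitudes for one event type (applied subtractively)."""

    event_year: float
    subsequent: float

    def __post_init__(self) -> None:
        if self.event_year < 0 or self.subsequent < 0:
            raise ConfigurationError(
                "decrements are stored as magnitudes and must be >= 0"
            )


@dataclass(frozen=True)
class UtilityTable:
    """Baseline utility plus per-event decrements and occurrence caps."""

    baseline_utility: float
    decrements: Mapping[EventType, Decrement]
    max_counted: Mapping[EventType, int]

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_utility <= 1.0:
            raise ConfigurationError("baseline_utility must lie in (0, 1]")
        for ev, cap in self.max_counted.items():
            if cap < 1:
                raise ConfigurationError(f"max_counted[{ev}] must be >= 1")

    def decrement(self, event: EventType) -> Decrement:
        try:
            return self.decrements[event]
        except KeyError:
            raise ConfigurationError(
                f"utility table has no decrement for event type {event!r}"
            ) from None

    @classmethod
    def default(cls) -> "UtilityTable":
        """Default table: baseline 0.807, additive decrements.

        MI carries its decrement for the event year only; stroke and renal
        failure decrement permanently; IHD and blindness carry no decrement
        in the base case. The CHF, amputation, and ulcer values are labeled
        placeholders borrowed from the alternative set (their primary-source
        defaults are not printed in the validation study this package
        operationalises).
        """
        dec = {
            EventType.IHD: Decrement(0.0, 0.0),
            EventType.MI: Decrement(0.065, 0.0),
            EventType.STROKE: Decrement(0.165, 0.165),
            EventType.CHF: Decrement(0.108, 0.108),  # placeholder (alt set)
            EventType.BLINDNESS: Decrement(0.0, 0.0),
            EventType.AMPUTATION: Decrement(0.280, 0.280),  # placeholder
            EventType.RENAL_FAILURE: Decrement(0.330, 0.330),
            EventType.ULCER: Decrement(0.170, 0.170),  # placeholder (alt set)
        }
        return cls(0.807, dec, _default_caps())

    @classmethod
    def alternative(cls) -> "UtilityTable":
        """Alternative published utility set (sensitivity analysis SA4).

        Initial utility 0.785; every event decrements in the event year and
        identically in all subsequent years.
        """
        vals = {
            EventType.IHD: 0.090,
            EventType.MI: 0.055,
            EventType.STROKE: 0.164,
            EventType.CHF: 0.108,
            EventType.BLINDNESS: 0.074,
            EventType.ULCER: 0.170,
            EventType.AMPUTATION: 0.280,
            EventType.RENAL_FAILURE: 0.204,
        }
        dec = {ev: Decrement(v, v) for ev, v in vals.items()}
        return cls(0.785, dec, _default_caps())

    def to_dict(self) -> dict:
        return {
            "baseline_utility": self.baseline_utility,
            "decrements": {
                ev.value: {
                    "event_year": d.event_year,
                    "subsequent": d.subsequent,
                }
                for ev, d in self.decrements.items()
            },
            "max_counted": {ev.value: c for ev, c in self.max_counted.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "UtilityTable":
        try:
            dec = {
                EventType(ev): Decrement(
                    float(d["event_year"]), float(d["subsequent"])
                )
                for ev, d in data["decrements"].items()
            }
            caps = {EventType(ev): int(c) for ev, c in data["max_counted"].items()}
            return cls(float(data["baseline_utility"]), dec, caps)
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"bad utility table config: {exc}") from exc


def _default_caps() -> dict[EventType, int]:
    return {
        ev: (2 if ev in SECOND_EVENT_TYPES else 1) for ev in EventType
    }


@dataclass(frozen=True)
class EventOccurrence:
    """One in-trial (or in-loop) occurrence of an event.

    ``occurrence_index`` counts occurrences since randomization (1-based,
    consecutive per patient and event type); ``year_index`` is the 1-based
    annual cycle in which the event occurred.
    """

    event_type: EventType
    occurrence_index: int
    year_index: int


@dataclass
class PatientRecord:
    """Baseline covariates, event history, and follow-up for one participant.

    ``prior_events`` holds baseline history counts per event type (events
    before randomization). ``censor_time`` is the time the participant was
    (or would have been) censored; ``administrative_end_time`` is the
    follow-up the participant would have had absent death, used to truncate
    model predictions for decedents.
    """

    patient_id: str
    age: float
    female: bool
    diabetes_duration: float
    prior_events: dict[EventType, int] = field(default_factory=dict)
    events: list[EventOccurrence] = field(default_factory=list)
    death_time: float | None = None
    censor_time: float = 0.0
    administrative_end_time: float | None = None

    def __post_init__(self) -> None:
        if self.censor_time < 0:
            raise InputError("censor_time must be >= 0")
        if self.death_time is not None and self.death_time <= 0:
            raise InputError("death_time must be > 0")
        if self.administrative_end_time is None:
            self.administrative_end_time = self.censor_time
        by_type: dict[EventType, list[int]] = {}
        for occ in self.events:
            if occ.year_index < 1:
                raise InputError("year_index must be >= 1")
            by_type.setdefault(occ.event_type, []).append(occ.occurrence_index)
        for ev, idx in by_type.items():
            if sorted(idx) != list(range(1, len(idx) + 1)):
                raise InputError(
                    f"occurrence_index for {ev.value} must be consecutive from 1"
                )

    def prior_count(self, event: EventType) -> int:
        return int(self.prior_events.get(event, 0))


@dataclass
class UtilityTrace:
    """Per-annual-cycle utilities with accrual weights.

    ``weights[t-1]`` is 1 for a complete year, 0.5 for the death year, the
    fractional part of the censor time for a partial censor year, and 0 for
    cycles after exit. ``censor_cycle`` marks the (1-based) partial censor
    year when one exists, so sensitivity analyses can drop that term.
    """

    utilities: np.ndarray
    weights: np.ndarray
    censor_cycle: int | None = None

    def __post_init__(self) -> None:
        self.utilities = np.asarray(self.utilities, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.utilities.shape != self.weights.shape:
            raise InputError("utilities and weights must have equal length")
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise InputError("weights must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.utilities)


@dataclass(frozen=True)
class QalyOptions:
    """Analysis options controlling QALY accrual.

    discount_rate
        Per-annum discount fraction; cycle ``t`` is weighted by
        ``1/(1+r)**(t-1)`` (first year undiscounted, consistent with
        events occurring at the start of each year). Default 0.
    horizon_years
        Truncate accrual after this many cycles (``None`` = full follow-up).
    exclude_censor_year
        Drop the partial censor-year term (sensitivity analysis).
    life_years_mode
        Replace all utilities by 1, yielding life-years.
    second_event_rule
        Occurrence-counting rule, see :class:`SecondEventRule`.
    """

    discount_rate: float = 0.0
    horizon_years: int | None = None
    exclude_censor_year: bool = False
    life_years_mode: bool = False
    second_event_rule: SecondEventRule = SecondEventRule.DEFAULT

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise InputError("discount_rate must be >= 0")
        if self.horizon_years is not None and self.horizon_years < 1:
            raise InputError("horizon_years must be >= 1")


def counted_occurrences(
    events: Iterable[EventOccurrence],
    prior_events: Mapping[EventType, int],
    table: UtilityTable,
    rule: SecondEventRule = SecondEventRule.DEFAULT,
) -> list[EventOccurrence]:
    """Filter occurrences down to those that carry a utility decrement.

    Under the default rule an occurrence counts if its cumulative number —
    baseline history plus in-trial occurrence index — does not exceed the
    table's cap (2 for MI/stroke/amputation, 1 otherwise), so e.g. a third
    stroke or a second ulcer changes nothing.
    """
    out: list[EventOccurrence] = []
    for occ in events:
        ev = occ.event_type
        cap = table.max_counted.get(ev, 1)
        if rule is SecondEventRule.DEFAULT:
            counted = int(prior_events.get(ev, 0)) + occ.occurrence_index <= cap
        elif rule is SecondEventRule.COUNT_ALL_SINCE_RANDOMIZATION:
            cap_all = max(cap, 2) if ev in _COUNT_ALL_SECOND else cap
            counted = occ.occurrence_index <= cap_all
        elif rule is SecondEventRule.EXCLUDE_SECOND_EVENTS:
            counted = int(prior_events.get(ev, 0)) + occ.occurrence_index <= 1
        elif rule is SecondEventRule.EXCLUDE_SECOND_EVENTS_AND_ULCER:
            if ev is EventType.ULCER:
                counted = False
            else:
                counted = int(prior_events.get(ev, 0)) + occ.occurrence_index <= 1
        else:  # pragma: no cover - closed enum
            raise ConfigurationError(f"unknown second-event rule {rule!r}")
        if counted:
            out.append(occ)
    return out


def _exit_cycles(end_time: float, died: bool) -> tuple[int, float, int | None]:
    """Return (n_cycles, last-cycle weight, censor_cycle) for an exit time."""
    if end_time < 0:
        raise InputError("follow-up times must be >= 0")
    if died:
        h = int(math.ceil(end_time))
        return h, 0.5, None
    frac = end_time - math.floor(end_time)
    if frac > 0:
        return int(math.floor(end_time)) + 1, frac, int(math.floor(end_time)) + 1
    return int(end_time), 1.0, None


def _utilities_for_cycles(
    occurrences: Sequence[EventOccurrence],
    table: UtilityTable,
    n_cycles: int,
) -> np.ndarray:
    u = np.full(n_cycles, table.baseline_utility, dtype=float)
    for occ in occurrences:
        d = table.decrement(occ.event_type)
        y = occ.year_index
        if y <= n_cycles:
            u[y - 1] -= d.event_year
        if y < n_cycles:
            u[y:] -= d.subsequent
    return u


def build_utility_trace(
    record: PatientRecord,
    table: UtilityTable,
    options: QalyOptions = QalyOptions(),
) -> UtilityTrace:
    """Annual utility trace for a participant's *observed* history.

    Follow-up ends at death (half-weight death cycle) or at censoring
    (fraction-of-year weight in the censor cycle). Event decrements apply
    from the event's cycle onwards per the table; occurrence counting
    follows ``options.second_event_rule``.
    """
    died = record.death_time is not None
    end = record.death_time if died else record.censor_time
    h, last_w, censor_cycle = _exit_cycles(float(end), died)
    counted = counted_occurrences(
        record.events, record.prior_events, table, options.second_event_rule
    )
    u = _utilities_for_cycles(counted, table, h)
    w = np.ones(h)
    if h:
        w[-1] = last_w
    return UtilityTrace(u, w, censor_cycle=censor_cycle)


def _discount_factors(n: int, rate: float) -> np.ndarray:
    if rate == 0.0:
        return np.ones(n)
    return (1.0 + rate) ** -np.arange(n, dtype=float)


def qalys_from_trace(trace: UtilityTrace, options: QalyOptions = QalyOptions()) -> float:
    """Total (discounted) QALYs for a utility trace.

    Sum of ``utility[t] * weight[t] / (1+r)**(t-1)`` truncated at the
    horizon; in life-years mode utilities are replaced by 1; the partial
    censor-year term is dropped when ``exclude_censor_year`` is set.
    """
    u = np.ones(len(trace)) if options.life_years_mode else trace.utilities.copy()
    w = trace.weights.copy()
    if options.exclude_censor_year and trace.censor_cycle is not None:
        w[trace.censor_cycle - 1] = 0.0
    if options.horizon_years is not None:
        w[options.horizon_years:] = 0.0
    disc = _discount_factors(len(trace), options.discount_rate)
    return float(np.sum(u * w * disc))


def trial_qalys(
    record: PatientRecord,
    table: UtilityTable,
    options: QalyOptions = QalyOptions(),
) -> float:
    """QALYs implied by a participant's observed events and survival."""
    return qalys_from_trace(build_utility_trace(record, table, options), options)


@dataclass(frozen=True)
class LoopHistory:
    """One simulated realization of a patient's trajectory over the horizon."""

    events: tuple[EventOccurrence, ...]
    death_cycle: int | None


def model_qalys_from_loops(
    utilities: np.ndarray,
    death_cycles: np.ndarray,
    censor_time: float,
    options: QalyOptions = QalyOptions(),
) -> np.ndarray:
    """Per-loop QALYs truncated at the patient's censoring time.

    ``utilities`` is (n_loops, horizon); ``death_cycles`` holds the 1-based
    death cycle per loop, 0 for loops where the simulated patient survives
    the horizon. Loops in which the simulated patient dies in or before the
    censor year accrue the half-cycle death-year weight; surviving loops
    accrue the fraction-of-year censor weight. This is the within-loop
    adjustment for deaths occurring in the censor year.
    """
    utilities = np.asarray(utilities, dtype=float)
    death_cycles = np.asarray(death_cycles, dtype=int)
    n_loops, horizon = utilities.shape
    c_cycles, c_weight, censor_cycle = _exit_cycles(float(censor_time), died=False)
    if c_cycles > horizon:
        raise InputError(
            f"censor_time {censor_time} exceeds the simulated horizon {horizon}"
        )

    w = np.zeros_like(utilities)
    if c_cycles:
        w[:, :c_cycles] = 1.0
        w[:, c_cycles - 1] = c_weight
        if options.exclude_censor_year and censor_cycle is not None:
            w[:, censor_cycle - 1] = 0.0
    # loops dying in or before the censor year: half-weight death year, 0 after
    dead = (death_cycles > 0) & (death_cycles <= c_cycles)
    if np.any(dead):
        d = death_cycles[dead]
        cols = np.arange(1, horizon + 1)
        wd = np.where(cols[None, :] < d[:, None], 1.0, 0.0)
        wd[np.arange(d.size), d - 1] = 0.5
        w[dead] = wd
    if options.horizon_years is not None:
        w[:, options.horizon_years:] = 0.0
    u = np.ones_like(utilities) if options.life_years_mode else utilities
    disc = _discount_factors(horizon, options.discount_rate)
    return (u * w * disc).sum(axis=1)


def model_qalys(
    loop_histories: Sequence[LoopHistory],
    record: PatientRecord,
    table: UtilityTable,
    options: QalyOptions = QalyOptions(),
    horizon: int = 7,
) -> float:
    """Mean model QALYs over Monte Carlo loops for one participant.

    Each loop spans the full simulation horizon; accrual is truncated at the
    participant's censor time (administrative end time for participants who
    died during the trial, reflecting the follow-up they would have had).
    """
    if len(loop_histories) == 0:
        raise InputError("model_qalys requires at least one loop")
    censor = (
        record.administrative_end_time
        if record.death_time is not None
        else record.censor_time
    )
    n = len(loop_histories)
    utilities = np.empty((n, horizon))
    deaths = np.zeros(n, dtype=int)
    for i, loop in enumerate(loop_histories):
        counted = counted_occurrences(
            loop.events, record.prior_events, table, options.second_event_rule
        )
        utilities[i] = _utilities_for_cycles(counted, table, horizon)
        deaths[i] = loop.death_cycle or 0
    per_loop = model_qalys_from_loops(utilities, deaths, float(censor), options)
    return float(per_loop.mean())
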