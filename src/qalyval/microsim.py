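"""Coefficient-driven annual-cycle patient-level microsimulation.

The engine is deliberately generic: it simulates any set of annual event and
death probability equations supplied as coefficient files (logistic or
complementary log-log link), in the style of the published diabetes outcome
models, without embedding any published coefficient values.

Within-year policy (declared, documented): at the start of each cycle all
eligible event probabilities are evaluated on the start-of-year state and
drawn *simultaneously* and independently; death is drawn last, with the
death equation allowed to see same-year event indicators (``new_<EVENT>``
terms); event history updates at the end of the year. Events in the death
cycle therefore still decrement utility before the half-year death weight.

Randomness: each patient gets an independent substream derived from the
master seed, and within a patient the uniforms are laid out on a fixed
``(loop, cycle, channel)`` grid. Two consequences worth relying on:

* the scalar reference path (:func:`simulate_loop`) and the vectorized path
  (:func:`run_patient`) consume identical draws, so they agree bit-exactly;
* the running mean over the first ``k`` loops equals the mean of a run with
  ``n_loops = k``, and changing one patient's loop count never reshuffles
  another patient's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .qaly import (
    ConfigurationError,
    EventOccurrence,
    EventType,
    InputError,
    LoopHistory,
    PatientRecord,
    QalyOptions,
    SECOND_EVENT_TYPES,
    SecondEventRule,
    UtilityTable,
    model_qalys_from_loops,
)

__all__ = [
    "RiskEquation",
    "RiskEquationSet",
    "PatientState",
    "SimConfig",
    "LoopOutcome",
    "PatientSimResult",
    "annual_probabilities",
    "simulate_loop",
    "run_patient",
    "convergence_diagnostic",
]

#: Fixed channel order for uniform draws: one per event type, death last.
EVENT_ORDER: tuple[EventType, ...] = tuple(EventType)
_DEATH_CHANNEL = len(EVENT_ORDER)


@dataclass(frozen=True)
class RiskEquation:
    """One annual-probability equation.

    ``form`` is ``"logistic"`` (p = expit(lp)) or ``"cloglog"``
    (p = 1 - exp(-exp(lp))); ``coefficients`` maps covariate terms to
    values. Recognised terms: ``intercept``, ``age`` (current age),
    ``age_base``, ``female``, ``diabetes_duration``, ``hist_<EVENT>``
    (any occurrence before this cycle, baseline history included),
    ``count_<EVENT>``, and — in the death equation only — ``new_<EVENT>``
    (event drawn in the current cycle).
    """

    form: str
    coefficients: Mapping[str, float]
    second_event: bool = False

    def __post_init__(self) -> None:
        if self.form not in ("logistic", "cloglog"):
            raise ConfigurationError(f"unknown equation form {self.form!r}")

    def probability(self, lp):
        """Annual probability from a linear predictor; always in [0, 1]."""
        lp = np.asarray(lp, dtype=float)
        if self.form == "logistic":
            p = expit(lp)
        else:
            p = -np.expm1(-np.exp(lp))
        return p


@dataclass(frozen=True)
class RiskEquationSet:
    """Annual event and death equations driving the simulator."""

    events: Mapping[EventType, RiskEquation]
    death: RiskEquation

    def __post_init__(self) -> None:
        for ev, eq in self.events.items():
            if eq.second_event and ev not in SECOND_EVENT_TYPES:
                raise ConfigurationError(
                    f"second occurrences are only defined for "
                    f"{sorted(e.value for e in SECOND_EVENT_TYPES)}, not {ev.value}"
                )

    def max_occurrences(self, event: EventType) -> int:
        return 2 if self.events[event].second_event else 1

    def to_dict(self) -> dict:
        out = {
            ev.value: {
                "form": eq.form,
                "coefficients": dict(eq.coefficients),
                "second_event": eq.second_event,
            }
            for ev, eq in self.events.items()
        }
        out["DEATH"] = {
            "form": self.death.form,
            "coefficients": dict(self.death.coefficients),
        }
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "RiskEquationSet":
        try:
            death_cfg = data["DEATH"]
        except KeyError:
            raise ConfigurationError("equation set must define a DEATH equation")
        events = {}
        for key, cfg in data.items():
            if key == "DEATH":
                continue
            events[EventType(key)] = RiskEquation(
                form=cfg["form"],
                coefficients={k: float(v) for k, v in cfg["coefficients"].items()},
                second_event=bool(cfg.get("second_event", False)),
            )
        death = RiskEquation(
            form=death_cfg["form"],
            coefficients={k: float(v) for k, v in death_cfg["coefficients"].items()},
        )
        return cls(events, death)


@dataclass
class PatientState:
    """Start-of-cycle state of one simulated patient.

    ``counts`` are total occurrence counts per event (baseline history plus
    simulated occurrences so far); ``new_events`` flags events drawn in the
    current cycle (visible to the death equation only).
    """

    age: float
    female: bool
    diabetes_duration: float
    counts: dict[EventType, int]
    cycle: int = 1
    alive: bool = True
    new_events: frozenset[EventType] = frozenset()
    age_base: float | None = None

    def __post_init__(self) -> None:
        if self.age_base is None:
            self.age_base = self.age


def _term_value(term: str, state: PatientState) -> float:
    if term == "intercept":
        return 1.0
    if term == "age":
        return state.age
    if term == "age_base":
        return float(state.age_base)
    if term == "female":
        return 1.0 if state.female else 0.0
    if term == "diabetes_duration":
        return state.diabetes_duration
    if term.startswith("hist_"):
        ev = _parse_event(term[5:], term)
        return 1.0 if state.counts.get(ev, 0) > 0 else 0.0
    if term.startswith("count_"):
        ev = _parse_event(term[6:], term)
        return float(state.counts.get(ev, 0))
    if term.startswith("new_"):
        ev = _parse_event(term[4:], term)
        return 1.0 if ev in state.new_events else 0.0
    raise ConfigurationError(f"unknown covariate term {term!r}")


def _parse_event(name: str, term: str) -> EventType:
    try:
        return EventType(name)
    except ValueError:
        raise ConfigurationError(f"term {term!r} names no known event type") from None


def _linear_predictor(eq: RiskEquation, state: PatientState) -> float:
    return sum(c * _term_value(t, state) for t, c in eq.coefficients.items())


def annual_probabilities(
    state: PatientState, eqs: RiskEquationSet
) -> dict[str, float]:
    """Per-event and death annual probabilities for a start-of-cycle state.

    Deterministic in the state; every probability is in [0, 1] by
    construction of the link functions. The death probability is evaluated
    with the state's current ``new_events`` indicators (empty at the start
    of a cycle).
    """
    probs = {
        ev.value: float(eq.probability(_linear_predictor(eq, state)))
        for ev, eq in eqs.events.items()
    }
    probs["DEATH"] = float(
        eqs.death.probability(_linear_predictor(eqs.death, state))
    )
    return probs


@dataclass(frozen=True)
class SimConfig:
    """Simulation controls: loop count, master seed, and horizon (years)."""

    n_loops: int = 50_000
    seed: int = 0
    horizon_years: int = 7

    def __post_init__(self) -> None:
        if self.n_loops < 1:
            raise InputError("n_loops must be >= 1")
        if self.horizon_years < 1:
            raise InputError("horizon_years must be >= 1")


@dataclass(frozen=True)
class LoopOutcome:
    """One stochastic realization of a patient's trajectory."""

    events: tuple[EventOccurrence, ...]
    death_cycle: int | None
    utilities: np.ndarray  # length horizon; counted-decrement utilities
    weights: np.ndarray  # 1 alive, 0.5 death year, 0 after death
    qalys: float  # over the full horizon, no censoring
    life_years: float

    @property
    def history(self) -> LoopHistory:
        return LoopHistory(self.events, self.death_cycle)


def patient_key(record: PatientRecord) -> int:
    """Stable integer substream key for a patient (id-derived)."""
    try:
        return int(record.patient_id)
    except (TypeError, ValueError):
        return zlib.crc32(str(record.patient_id).encode())


def _patient_uniforms(
    record: PatientRecord, config: SimConfig, n_loops: int
) -> np.ndarray:
    """Uniform draws on the fixed (loop, cycle, channel) grid."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), patient_key(record)])
    )
    return rng.random((n_loops, config.horizon_years, _DEATH_CHANNEL + 1))


def _initial_counts(record: PatientRecord) -> dict[EventType, int]:
    return {ev: record.prior_count(ev) for ev in EventType}


def simulate_loop(
    record: PatientRecord,
    eqs: RiskEquationSet,
    table: UtilityTable,
    config: SimConfig,
    uniforms: np.ndarray | None = None,
    rule: SecondEventRule = SecondEventRule.DEFAULT,
) -> LoopOutcome:
    """Scalar reference simulation of a single loop.

    ``uniforms`` is an (horizon, n_channels) slice of the patient's draw
    grid; omitted, the first loop's draws are used. This path is the
    readable specification of the cycle logic; :func:`run_patient` is the
    vectorized equivalent and consumes the same draws.
    """
    if uniforms is None:
        uniforms = _patient_uniforms(record, config, 1)[0]
    h = config.horizon_years
    counts = _initial_counts(record)
    sim_counts = {ev: 0 for ev in EventType}
    events: list[EventOccurrence] = []
    death_cycle: int | None = None
    state = PatientState(
        age=record.age,
        female=record.female,
        diabetes_duration=record.diabetes_duration,
        counts=counts,
        age_base=record.age,
    )
    for t in range(1, h + 1):
        state.cycle = t
        state.age = record.age + (t - 1)
        state.new_events = frozenset()
        new: list[EventType] = []
        for j, ev in enumerate(EVENT_ORDER):
            eq = eqs.events.get(ev)
            if eq is None:
                continue
            if counts[ev] >= eqs.max_occurrences(ev):
                continue
            p = eq.probability(_linear_predictor(eq, state))
            if uniforms[t - 1, j] < p:
                new.append(ev)
        state.new_events = frozenset(new)
        p_death = eqs.death.probability(_linear_predictor(eqs.death, state))
        died = uniforms[t - 1, _DEATH_CHANNEL] < p_death
        for ev in new:
            sim_counts[ev] += 1
            events.append(EventOccurrence(ev, sim_counts[ev], t))
        # history updates at year end
        for ev in new:
            counts[ev] += 1
        if died:
            death_cycle = t
            break

    from .qaly import _utilities_for_cycles, counted_occurrences

    counted = counted_occurrences(events, record.prior_events, table, rule)
    utilities = _utilities_for_cycles(counted, table, h)
    weights = np.ones(h)
    if death_cycle is not None:
        weights[death_cycle - 1] = 0.5
        weights[death_cycle:] = 0.0
    return LoopOutcome(
        events=tuple(events),
        death_cycle=death_cycle,
        utilities=utilities,
        weights=weights,
        qalys=float(np.sum(utilities * weights)),
        life_years=float(np.sum(weights)),
    )


@dataclass
class PatientSimResult:
    """All Monte Carlo loops for one patient, in array form.

    ``occurrence_cycles[event]`` is (n_loops, 2): the cycle of the first and
    second simulated occurrence (0 = did not occur). ``death_cycles`` is
    (n_loops,) with 0 for loops surviving the horizon. Utilities and QALYs
    under any utility table / counting rule / censoring derive from these
    arrays without resimulating.
    """

    record: PatientRecord
    horizon: int
    n_loops: int
    occurrence_cycles: dict[EventType, np.ndarray]
    death_cycles: np.ndarray
    table: UtilityTable

    def loop_utilities(
        self,
        table: UtilityTable | None = None,
        rule: SecondEventRule = SecondEventRule.DEFAULT,
    ) -> np.ndarray:
        """(n_loops, horizon) utility traces under the counting rule."""
        table = table or self.table
        prior = self.record.prior_events
        u = np.full((self.n_loops, self.horizon), table.baseline_utility)
        cols = np.arange(1, self.horizon + 1)
        for ev, occ in self.occurrence_cycles.items():
            d = table.decrement(ev)
            if d.event_year == 0.0 and d.subsequent == 0.0:
                continue
            cap = table.max_counted.get(ev, 1)
            for k in (1, 2):
                c = occ[:, k - 1]
                if not np.any(c):
                    continue
                if not _occurrence_counts(ev, k, int(prior.get(ev, 0)), cap, rule):
                    continue
                here = c[:, None] == cols[None, :]
                after = (c[:, None] > 0) & (c[:, None] < cols[None, :])
                u -= d.event_year * here + d.subsequent * after
        return u

    def loop_weights(self) -> np.ndarray:
        """(n_loops, horizon) accrual weights: 1 alive, 0.5 death year, 0 after."""
        cols = np.arange(1, self.horizon + 1)
        d = self.death_cycles[:, None]
        w = np.where((d > 0) & (cols[None, :] > d), 0.0, 1.0)
        w = np.where((d > 0) & (cols[None, :] == d), 0.5, w)
        return w

    def loop_qalys(
        self,
        table: UtilityTable | None = None,
        rule: SecondEventRule = SecondEventRule.DEFAULT,
    ) -> np.ndarray:
        """Per-loop QALYs over the full horizon (no censoring)."""
        return (self.loop_utilities(table, rule) * self.loop_weights()).sum(axis=1)

    def loop_life_years(self) -> np.ndarray:
        return self.loop_weights().sum(axis=1)

    @property
    def mean_qalys(self) -> float:
        return float(self.loop_qalys().mean())

    @property
    def mean_life_years(self) -> float:
        return float(self.loop_life_years().mean())

    def model_qalys(self, options: QalyOptions = QalyOptions()) -> float:
        """Mean model QALYs truncated at the patient's censoring time.

        Uses the administrative end time for patients who died during the
        trial (the follow-up they would have had absent death).
        """
        rec = self.record
        censor = (
            rec.administrative_end_time
            if rec.death_time is not None
            else rec.censor_time
        )
        per_loop = model_qalys_from_loops(
            self.loop_utilities(rule=options.second_event_rule),
            self.death_cycles,
            float(censor),
            options,
        )
        return float(per_loop.mean())

    def cumulative_event_counts(self) -> np.ndarray:
        """(horizon,) mean cumulative simulated occurrences per cycle (all events)."""
        cols = np.arange(1, self.horizon + 1)
        total = np.zeros(self.horizon)
        for occ in self.occurrence_cycles.values():
            for k in (0, 1):
                c = occ[:, k]
                total += ((c[:, None] > 0) & (c[:, None] <= cols[None, :])).mean(0)
        return total

    def incidence_by_cycle(self, event: EventType | str, order: int = 1) -> np.ndarray:
        """(horizon,) fraction of loops with the order-th occurrence by cycle t.

        ``event`` may be an :class:`EventType`, ``"DEATH"``, or
        ``"ANY_EVENT"`` (first event of any type, death included).
        """
        cols = np.arange(1, self.horizon + 1)
        if event == "DEATH":
            c = self.death_cycles
        elif event == "ANY_EVENT":
            stacks = [occ[:, 0] for occ in self.occurrence_cycles.values()]
            stacks.append(self.death_cycles)
            arr = np.stack(stacks)
            arr = np.where(arr == 0, self.horizon + 1, arr)
            c = arr.min(axis=0)
            c = np.where(c > self.horizon, 0, c)
        else:
            c = self.occurrence_cycles[EventType(event)][:, order - 1]
        return ((c[:, None] > 0) & (c[:, None] <= cols[None, :])).mean(axis=0)


def _occurrence_counts(
    ev: EventType, k: int, prior: int, cap: int, rule: SecondEventRule
) -> bool:
    """Whether the k-th simulated occurrence carries a utility decrement."""
    if rule is SecondEventRule.DEFAULT:
        return prior + k <= cap
    if rule is SecondEventRule.COUNT_ALL_SINCE_RANDOMIZATION:
        cap_all = max(cap, 2) if ev in _COUNT_ALL_SECOND_MS else cap
        return k <= cap_all
    if rule is SecondEventRule.EXCLUDE_SECOND_EVENTS:
        return prior + k <= 1
    if rule is SecondEventRule.EXCLUDE_SECOND_EVENTS_AND_ULCER:
        return ev is not EventType.ULCER and prior + k <= 1
    raise ConfigurationError(f"unknown second-event rule {rule!r}")


_COUNT_ALL_SECOND_MS = SECOND_EVENT_TYPES | {EventType.BLINDNESS, EventType.ULCER}


def _vector_term(term: str, record: PatientRecord, t: int, counts) -> np.ndarray | float:
    if term == "intercept":
        return 1.0
    if term == "age":
        return record.age + (t - 1)
    if term == "age_base":
        return record.age
    if term == "female":
        return 1.0 if record.female else 0.0
    if term == "diabetes_duration":
        return record.diabetes_duration
    if term.startswith("hist_"):
        ev = _parse_event(term[5:], term)
        return (counts[ev] > 0).astype(float)
    if term.startswith("count_"):
        ev = _parse_event(term[6:], term)
        return counts[ev].astype(float)
    raise ConfigurationError(f"unknown covariate term {term!r}")


def run_patient(
    record: PatientRecord,
    eqs: RiskEquationSet,
    table: UtilityTable,
    config: SimConfig,
) -> PatientSimResult:
    """Simulate all Monte Carlo loops for one patient (vectorized over loops).

    Bit-reproducible: (seed, config, inputs) determine every output, and the
    first loop agrees exactly with :func:`simulate_loop`.
    """
    n, h = config.n_loops, config.horizon_years
    u01 = _patient_uniforms(record, config, n)
    counts = {
        ev: np.full(n, record.prior_count(ev), dtype=np.int64) for ev in EventType
    }
    sim_occ = {ev: np.zeros((n, 2), dtype=np.int64) for ev in eqs.events}
    death_cycles = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)

    for t in range(1, h + 1):
        new: dict[EventType, np.ndarray] = {}
        for j, ev in enumerate(EVENT_ORDER):
            eq = eqs.events.get(ev)
            if eq is None:
                continue
            lp = 0.0
            for term, coef in eq.coefficients.items():
                lp = lp + coef * _vector_term(term, record, t, counts)
            p = eq.probability(np.broadcast_to(np.asarray(lp, dtype=float), (n,)))
            eligible = alive & (counts[ev] < eqs.max_occurrences(ev))
            occurred = eligible & (u01[:, t - 1, j] < p)
            if np.any(occurred):
                first = occurred & (sim_occ[ev][:, 0] == 0)
                second = occurred & ~first
                sim_occ[ev][first, 0] = t
                sim_occ[ev][second, 1] = t
            new[ev] = occurred
        lp_d = 0.0
        for term, coef in eqs.death.coefficients.items():
            if term.startswith("new_"):
                ev = _parse_event(term[4:], term)
                val = new.get(ev, np.zeros(n, dtype=bool)).astype(float)
            else:
                val = _vector_term(term, record, t, counts)
            lp_d = lp_d + coef * val
        p_d = eqs.death.probability(np.broadcast_to(np.asarray(lp_d, dtype=float), (n,)))
        died = alive & (u01[:, t - 1, _DEATH_CHANNEL] < p_d)
        death_cycles[died] = t
        # history updates at year end; dead-this-cycle loops keep their events
        for ev, occurred in new.items():
            counts[ev] += occurred
        alive &= ~died

    return PatientSimResult(
        record=record,
        horizon=h,
        n_loops=n,
        occurrence_cycles=sim_occ,
        death_cycles=death_cycles,
        table=table,
    )


def convergence_diagnostic(
    record: PatientRecord,
    eqs: RiskEquationSet,
    table: UtilityTable,
    loop_grid: Sequence[int],
    seed: int = 0,
    horizon_years: int = 7,
    tolerance: float = 0.01,
):
    """Running mean QALYs at increasing loop counts.

    Because the draw layout makes prefix means equal smaller runs, a single
    simulation at ``max(loop_grid)`` loops yields every grid point.
    Convergence is declared at the first grid point whose mean differs from
    its predecessor's by less than ``tolerance``.
    """
    import pandas as pd

    grid = sorted(int(k) for k in loop_grid)
    if grid != list(loop_grid):
        raise InputError("loop_grid must be ascending")
    config = SimConfig(n_loops=grid[-1], seed=seed, horizon_years=horizon_years)
    result = run_patient(record, eqs, table, config)
    per_loop = result.loop_qalys()
    cum = np.cumsum(per_loop)
    means = [cum[k - 1] / k for k in grid]
    converged = [False] + [
        abs(means[i] - means[i - 1]) < tolerance for i in range(1, len(grid))
    ]
    return pd.DataFrame(
        {"n_loops": grid, "running_mean_qalys": means, "converged": converged}
    )
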