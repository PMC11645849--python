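"""QALY accounting: utility traces, half-cycle correction, counting rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qalyval.qaly import (
    Decrement,
    EventOccurrence,
    EventType,
    InputError,
    LoopHistory,
    PatientRecord,
    QalyOptions,
    SecondEventRule,
    UtilityTable,
    UtilityTrace,
    build_utility_trace,
    counted_occurrences,
    model_qalys,
    qalys_from_trace,
    trial_qalys,
)


def _patient(events=(), death=None, censor=2.0, prior=None, **kw):
    return PatientRecord(
        "p", 62.0, False, 12.0, prior_events=prior or {},
        events=list(events), death_time=death, censor_time=censor, **kw
    )


class TestBuildUtilityTrace:
    def test_event_free_two_full_years(self, default_table):
        trace = build_utility_trace(_patient(censor=2.0), default_table)
        assert np.allclose(trace.utilities, [0.807, 0.807])
        assert np.allclose(trace.weights, [1.0, 1.0])

    def test_mi_decrements_event_year_only(self, default_table):
        rec = _patient([EventOccurrence(EventType.MI, 1, 1)], censor=3.0)
        trace = build_utility_trace(rec, default_table)
        assert trace.utilities[0] == pytest.approx(0.807 - 0.065)
        assert np.allclose(trace.utilities[1:], 0.807)

    def test_stroke_renal_death_trace(self, default_table, stroke_renal_decedent):
        trace = build_utility_trace(stroke_renal_decedent, default_table)
        assert np.allclose(trace.utilities, [0.807, 0.642, 0.312, 0.312])
        assert np.allclose(trace.weights, [1.0, 1.0, 1.0, 0.5])

    def test_fractional_censor_weight(self, default_table):
        trace = build_utility_trace(_patient(censor=2.5), default_table)
        assert np.allclose(trace.weights, [1.0, 1.0, 0.5])
        assert trace.censor_cycle == 3

    def test_death_cycle_is_ceiling_of_death_time(self, default_table):
        for death in (3.05, 3.5, 3.95, 4.0):
            trace = build_utility_trace(
                _patient(death=death, censor=death), default_table
            )
            assert len(trace) == 4
            assert trace.weights[-1] == 0.5

    def test_negative_times_rejected(self):
        with pytest.raises(InputError):
            _patient(censor=-1.0)

    def test_unknown_event_type_is_config_error(self, default_table):
        from qalyval.qaly import ConfigurationError

        table = UtilityTable(
            0.807,
            {EventType.MI: Decrement(0.065, 0.0)},
            {EventType.MI: 2},
        )
        rec = _patient([EventOccurrence(EventType.STROKE, 1, 1)], censor=2.0)
        with pytest.raises(ConfigurationError):
            build_utility_trace(rec, table)


class TestQalysFromTrace:
    def test_two_baseline_years(self):
        trace = UtilityTrace([0.807, 0.807], [1.0, 1.0])
        assert qalys_from_trace(trace) == pytest.approx(1.614)

    def test_stroke_renal_death_total(self, default_table, stroke_renal_decedent):
        q = trial_qalys(stroke_renal_decedent, default_table)
        assert q == pytest.approx(0.807 + 0.642 + 0.312 + 0.5 * 0.312)

    def test_discounted_life_years(self):
        trace = UtilityTrace([1.0, 1.0, 1.0], [1.0, 1.0, 0.5])
        q = qalys_from_trace(
            trace, QalyOptions(discount_rate=0.035, life_years_mode=True)
        )
        assert q == pytest.approx(1 + 1 / 1.035 + 0.5 / 1.035**2)

    def test_zero_discount_bit_identical(self, default_table, stroke_renal_decedent):
        trace = build_utility_trace(stroke_renal_decedent, default_table)
        assert qalys_from_trace(trace, QalyOptions(discount_rate=0.0)) == \
            qalys_from_trace(trace)

    def test_horizon_one_is_first_weighted_term(self, default_table):
        rec = _patient([EventOccurrence(EventType.MI, 1, 1)], censor=3.0)
        trace = build_utility_trace(rec, default_table)
        q1 = qalys_from_trace(trace, QalyOptions(horizon_years=1))
        assert q1 == pytest.approx(trace.utilities[0] * trace.weights[0])

    def test_exclude_censor_year_drops_partial_term(self, default_table):
        rec = _patient(censor=2.5)
        full = trial_qalys(rec, default_table)
        trimmed = trial_qalys(rec, default_table, QalyOptions(exclude_censor_year=True))
        assert trimmed == pytest.approx(full - 0.5 * 0.807)


class TestTrialQalys:
    def test_fractional_censor(self, default_table):
        assert trial_qalys(_patient(censor=2.5), default_table) == \
            pytest.approx(0.807 * 2.5)

    def test_life_years_death_at_3_2(self, default_table):
        rec = _patient(death=3.2, censor=3.2)
        ly = trial_qalys(rec, default_table, QalyOptions(life_years_mode=True))
        assert ly == pytest.approx(3.5)

    def test_sa1_counts_second_stroke_despite_history(self, default_table):
        events = [
            EventOccurrence(EventType.STROKE, 1, 1),
            EventOccurrence(EventType.STROKE, 2, 2),
        ]
        prior = {EventType.STROKE: 1}
        opts = QalyOptions(
            second_event_rule=SecondEventRule.COUNT_ALL_SINCE_RANDOMIZATION
        )
        with_history = trial_qalys(
            _patient(events, censor=3.0, prior=prior), default_table, opts
        )
        no_history = trial_qalys(
            _patient(events, censor=3.0), default_table, opts
        )
        assert with_history == pytest.approx(no_history)
        # both strokes decrement: year3 utility = 0.807 - 2*0.165
        assert with_history == pytest.approx(
            (0.807 - 0.165) + (0.807 - 0.165 - 0.165) * 2
        )

    def test_default_rule_third_stroke_and_second_ulcer_inert(self, default_table):
        base_events = [
            EventOccurrence(EventType.STROKE, 1, 1),
            EventOccurrence(EventType.STROKE, 2, 2),
            EventOccurrence(EventType.ULCER, 1, 1),
        ]
        extra = base_events + [
            EventOccurrence(EventType.STROKE, 3, 3),
            EventOccurrence(EventType.ULCER, 2, 3),
        ]
        a = trial_qalys(_patient(base_events, censor=5.0), default_table)
        b = trial_qalys(_patient(extra, censor=5.0), default_table)
        assert a == pytest.approx(b)

    def test_default_rule_prior_history_shifts_count(self, default_table):
        # with one prior ulcer the in-trial ulcer is a second -> no decrement
        ev = [EventOccurrence(EventType.ULCER, 1, 1)]
        with_prior = trial_qalys(
            _patient(ev, censor=2.0, prior={EventType.ULCER: 1}), default_table
        )
        assert with_prior == pytest.approx(0.807 * 2)

    def test_exclude_second_events_rule(self, default_table):
        ev = [
            EventOccurrence(EventType.MI, 1, 1),
            EventOccurrence(EventType.MI, 2, 2),
        ]
        opts = QalyOptions(second_event_rule=SecondEventRule.EXCLUDE_SECOND_EVENTS)
        q = trial_qalys(_patient(ev, censor=2.0), default_table, opts)
        assert q == pytest.approx((0.807 - 0.065) + 0.807)


class TestModelQalys:
    def test_degenerate_loops_exact(self, default_table):
        loops = [LoopHistory((), None)] * 5
        rec = _patient(censor=3.0)
        assert model_qalys(loops, rec, default_table) == pytest.approx(3 * 0.807)

    def test_two_loop_death_average(self, default_table):
        loops = [LoopHistory((), 1), LoopHistory((), None)]
        rec = _patient(censor=1.0)
        assert model_qalys(loops, rec, default_table) == \
            pytest.approx((0.5 * 0.807 + 0.807) / 2)

    def test_decedent_truncated_at_administrative_end(self, default_table):
        rec = _patient(death=1.5, censor=1.5, administrative_end_time=3.0)
        loops = [LoopHistory((), None)]
        # model accrues the full administrative follow-up, not the death time
        assert model_qalys(loops, rec, default_table) == pytest.approx(3 * 0.807)

    def test_empty_loop_set_rejected(self, default_table):
        with pytest.raises(InputError):
            model_qalys([], _patient(), default_table)


decrement_values = st.floats(0.0, 0.5)


class TestProperties:
    @given(d1=decrement_values, d2=decrement_values)
    @settings(max_examples=30, deadline=None)
    def test_qalys_non_increasing_in_decrements(self, d1, d2):
        table = UtilityTable(
            0.807,
            {EventType.STROKE: Decrement(min(d1, d2), min(d1, d2))},
            {EventType.STROKE: 2},
        )
        table_hi = UtilityTable(
            0.807,
            {EventType.STROKE: Decrement(max(d1, d2), max(d1, d2))},
            {EventType.STROKE: 2},
        )
        rec = _patient([EventOccurrence(EventType.STROKE, 1, 1)], censor=3.0)
        assert trial_qalys(rec, table_hi) <= trial_qalys(rec, table)

    @given(censor=st.floats(0.1, 6.9), u0=st.floats(0.1, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_life_years_dominate_qalys(self, censor, u0):
        table = UtilityTable(
            u0, {EventType.MI: Decrement(0.065, 0.0)}, {EventType.MI: 2}
        )
        rec = _patient([EventOccurrence(EventType.MI, 1, 1)], censor=censor)
        q = trial_qalys(rec, table)
        ly = trial_qalys(rec, table, QalyOptions(life_years_mode=True))
        assert ly >= q - 1e-12

    @given(censor=st.floats(0.1, 6.9))
    @settings(max_examples=30, deadline=None)
    def test_zero_decrements_scale_life_years(self, censor):
        table = UtilityTable(
            0.807,
            {ev: Decrement(0.0, 0.0) for ev in EventType},
            {ev: 2 for ev in EventType},
        )
        rec = _patient(
            [EventOccurrence(EventType.STROKE, 1, 1)], censor=censor
        )
        q = trial_qalys(rec, table)
        ly = trial_qalys(rec, table, QalyOptions(life_years_mode=True))
        assert q == pytest.approx(0.807 * ly)


class TestCountedOccurrences:
    @pytest.mark.parametrize(
        "rule,prior,n_counted",
        [
            (SecondEventRule.DEFAULT, 0, 2),
            (SecondEventRule.DEFAULT, 1, 1),
            (SecondEventRule.DEFAULT, 2, 0),
            (SecondEventRule.COUNT_ALL_SINCE_RANDOMIZATION, 2, 2),
            (SecondEventRule.EXCLUDE_SECOND_EVENTS, 0, 1),
            (SecondEventRule.EXCLUDE_SECOND_EVENTS, 1, 0),
        ],
    )
    def test_mi_counting(self, default_table, rule, prior, n_counted):
        events = [
            EventOccurrence(EventType.MI, 1, 1),
            EventOccurrence(EventType.MI, 2, 3),
        ]
        counted = counted_occurrences(
            events, {EventType.MI: prior}, default_table, rule
        )
        assert len(counted) == n_counted

    def test_ulcer_excluded_under_sa3(self, default_table):
        events = [EventOccurrence(EventType.ULCER, 1, 1)]
        counted = counted_occurrences(
            events, {}, default_table,
            SecondEventRule.EXCLUDE_SECOND_EVENTS_AND_ULCER,
        )
        assert counted == []
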