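"""Microsimulation engine: link functions, loop logic, convergence, RNG."""

import numpy as np
import pytest

from qalyval.microsim import (
    PatientState,
    RiskEquation,
    RiskEquationSet,
    SimConfig,
    annual_probabilities,
    convergence_diagnostic,
    run_patient,
    simulate_loop,
)
from qalyval.qaly import (
    ConfigurationError,
    EventType,
    PatientRecord,
    UtilityTable,
)
from conftest import constant_hazard_equations


def _rec(censor=7.0, **kw):
    return PatientRecord("101", 62.0, False, 12.0, censor_time=censor, **kw)


def _state(**kw):
    defaults = dict(age=62.0, female=False, diabetes_duration=12.0,
                    counts={ev: 0 for ev in EventType})
    defaults.update(kw)
    return PatientState(**defaults)


class TestAnnualProbabilities:
    def test_zero_coefficients_give_half(self):
        eqs = RiskEquationSet(
            {ev: RiskEquation("logistic", {}) for ev in EventType},
            RiskEquation("logistic", {}),
        )
        probs = annual_probabilities(_state(), eqs)
        assert all(p == pytest.approx(0.5) for p in probs.values())

    def test_large_negative_intercept_vanishes(self):
        eqs = RiskEquationSet(
            {EventType.MI: RiskEquation("logistic", {"intercept": -40.0})},
            RiskEquation("logistic", {"intercept": -40.0}),
        )
        probs = annual_probabilities(_state(), eqs)
        assert probs["MI"] == pytest.approx(0.0, abs=1e-12)

    def test_logistic_closed_form(self):
        eq = RiskEquation("logistic", {"intercept": 1.2})
        assert float(eq.probability(1.2)) == pytest.approx(1 / (1 + np.exp(-1.2)))

    def test_cloglog_closed_form(self):
        eq = RiskEquation("cloglog", {"intercept": 0.0})
        # lp = 0 -> p = 1 - exp(-1)
        assert float(eq.probability(0.0)) == pytest.approx(1 - np.exp(-1))

    def test_history_term_shifts_probability(self):
        eq = RiskEquation("logistic", {"intercept": -2.0, "hist_MI": 1.0})
        eqs = RiskEquationSet({EventType.STROKE: eq}, RiskEquation("logistic", {"intercept": -40.0}))
        p0 = annual_probabilities(_state(), eqs)["STROKE"]
        p1 = annual_probabilities(
            _state(counts={**{ev: 0 for ev in EventType}, EventType.MI: 1}), eqs
        )["STROKE"]
        assert p1 > p0

    def test_unknown_term_is_config_error(self):
        eq = RiskEquation("logistic", {"bogus_term": 1.0})
        eqs = RiskEquationSet({}, eq)
        with pytest.raises(ConfigurationError):
            annual_probabilities(_state(), eqs)

    def test_second_event_flag_restricted(self):
        with pytest.raises(ConfigurationError):
            RiskEquationSet(
                {EventType.ULCER: RiskEquation("logistic", {}, second_event=True)},
                RiskEquation("logistic", {}),
            )


class TestSimulateLoop:
    def test_zero_probability_event_free(self, zero_risk_equations, default_table):
        out = simulate_loop(_rec(), zero_risk_equations, default_table,
                            SimConfig(n_loops=1, seed=0))
        assert out.events == ()
        assert out.death_cycle is None
        assert out.qalys == pytest.approx(7 * 0.807)

    def test_certain_death_first_cycle(self, default_table):
        eqs = RiskEquationSet({}, RiskEquation("logistic", {"intercept": 50.0}))
        out = simulate_loop(_rec(), eqs, default_table, SimConfig(n_loops=1, seed=0))
        assert out.death_cycle == 1
        assert out.life_years == pytest.approx(0.5)

    def test_fixed_seed_bit_identical(self, default_table):
        eqs = constant_hazard_equations(0.3)
        cfg = SimConfig(n_loops=1, seed=17)
        a = simulate_loop(_rec(), eqs, default_table, cfg)
        b = simulate_loop(_rec(), eqs, default_table, cfg)
        assert a.events == b.events
        assert a.death_cycle == b.death_cycle
        assert np.array_equal(a.utilities, b.utilities)

    def test_no_events_after_death(self, default_table):
        eqs = RiskEquationSet(
            {EventType.MI: RiskEquation("logistic", {"intercept": 3.0},
                                        second_event=True)},
            RiskEquation("logistic", {"intercept": 3.0}),
        )
        for seed in range(20):
            out = simulate_loop(_rec(), eqs, default_table,
                                SimConfig(n_loops=1, seed=seed))
            if out.death_cycle is not None:
                assert all(o.year_index <= out.death_cycle for o in out.events)

    def test_occurrence_cap_respected(self, default_table):
        eqs = RiskEquationSet(
            {EventType.MI: RiskEquation("logistic", {"intercept": 50.0},
                                        second_event=True)},
            RiskEquation("logistic", {"intercept": -50.0}),
        )
        out = simulate_loop(_rec(), eqs, default_table, SimConfig(n_loops=1, seed=0))
        assert len(out.events) == 2  # capped at second occurrence
        assert [o.occurrence_index for o in out.events] == [1, 2]

    def test_prior_history_reduces_remaining_occurrences(self, default_table):
        eqs = RiskEquationSet(
            {EventType.MI: RiskEquation("logistic", {"intercept": 50.0},
                                        second_event=True)},
            RiskEquation("logistic", {"intercept": -50.0}),
        )
        rec = _rec(prior_events={EventType.MI: 1})
        out = simulate_loop(rec, eqs, default_table, SimConfig(n_loops=1, seed=0))
        assert len(out.events) == 1


class TestRunPatient:
    def test_first_loop_matches_scalar_reference(self, default_table):
        eqs = RiskEquationSet(
            {
                EventType.MI: RiskEquation(
                    "logistic", {"intercept": -1.0, "hist_MI": 0.5},
                    second_event=True,
                ),
                EventType.STROKE: RiskEquation("logistic", {"intercept": -1.5}),
            },
            RiskEquation("logistic", {"intercept": -2.0, "new_MI": 1.0}),
        )
        cfg = SimConfig(n_loops=30, seed=5)
        res = run_patient(_rec(), eqs, default_table, cfg)
        for i in range(5):
            # re-draw the uniform grid slice for loop i
            from qalyval.microsim import _patient_uniforms

            u = _patient_uniforms(_rec(), cfg, cfg.n_loops)[i]
            loop = simulate_loop(_rec(), eqs, default_table, cfg, uniforms=u)
            assert (loop.death_cycle or 0) == res.death_cycles[i]
            np.testing.assert_array_equal(loop.utilities,
                                          res.loop_utilities()[i])

    def test_degenerate_equations_zero_variance(self, zero_risk_equations,
                                                default_table):
        res = run_patient(_rec(), zero_risk_equations, default_table,
                          SimConfig(n_loops=50, seed=0))
        q = res.loop_qalys()
        assert np.all(q == q[0])
        assert res.mean_qalys == pytest.approx(7 * 0.807)
        assert res.mean_life_years == pytest.approx(7.0)

    def test_constant_hazard_closed_form(self, default_table):
        p, d, u0, h = 0.1, 0.165, 0.807, 7
        eqs = constant_hazard_equations(p)
        res = run_patient(_rec(), eqs, default_table,
                          SimConfig(n_loops=20_000, seed=12))
        closed = sum(u0 - d * (1 - (1 - p) ** t) for t in range(1, h + 1))
        q = res.loop_qalys()
        se = q.std(ddof=1) / np.sqrt(q.size)
        assert abs(q.mean() - closed) < 3 * se

    def test_two_seeds_differ_at_clt_scale(self, default_table):
        eqs = constant_hazard_equations(0.2)
        n = 5000
        m = [
            run_patient(_rec(), eqs, default_table,
                        SimConfig(n_loops=n, seed=s)).mean_qalys
            for s in (1, 2)
        ]
        # per-loop sd is ~0.3; means should agree within ~6 standard errors
        assert abs(m[0] - m[1]) < 6 * 0.3 / np.sqrt(n)
        assert m[0] != m[1]

    def test_cumulative_counts_monotone_and_bounded(self, default_table):
        eqs = RiskEquationSet(
            {EventType.MI: RiskEquation("logistic", {"intercept": 0.0},
                                        second_event=True)},
            RiskEquation("logistic", {"intercept": -2.0}),
        )
        res = run_patient(_rec(), eqs, default_table, SimConfig(n_loops=500, seed=3))
        counts = res.cumulative_event_counts()
        assert np.all(np.diff(counts) >= -1e-12)
        assert counts[-1] <= 2.0 + 1e-12

    def test_zero_decrements_factorize_qalys(self, default_table):
        table = UtilityTable(
            0.807,
            {ev: default_table.decrements[ev].__class__(0.0, 0.0)
             for ev in EventType},
            dict(default_table.max_counted),
        )
        eqs = RiskEquationSet(
            {EventType.MI: RiskEquation("logistic", {"intercept": -1.0})},
            RiskEquation("logistic", {"intercept": -1.5}),
        )
        res = run_patient(_rec(), eqs, table, SimConfig(n_loops=200, seed=8))
        np.testing.assert_allclose(
            res.loop_qalys(table), 0.807 * res.loop_life_years()
        )

    def test_prefix_mean_equals_smaller_run(self, default_table):
        eqs = constant_hazard_equations(0.25)
        big = run_patient(_rec(), eqs, default_table, SimConfig(n_loops=400, seed=2))
        small = run_patient(_rec(), eqs, default_table, SimConfig(n_loops=100, seed=2))
        assert big.loop_qalys()[:100].mean() == pytest.approx(
            small.mean_qalys, abs=1e-12
        )


class TestConvergence:
    def test_flat_for_degenerate_equations(self, zero_risk_equations,
                                           default_table):
        diag = convergence_diagnostic(
            _rec(), zero_risk_equations, default_table, [10, 100, 1000], seed=0
        )
        assert np.allclose(diag.running_mean_qalys, 7 * 0.807)
        assert diag.converged.iloc[1:].all()

    def test_running_mean_near_closed_form(self, default_table):
        p, d, u0 = 0.1, 0.165, 0.807
        eqs = constant_hazard_equations(p)
        grid = [1000, 5000, 10_000, 25_000, 50_000]
        diag = convergence_diagnostic(_rec(), eqs, default_table, grid, seed=4)
        closed = sum(u0 - d * (1 - (1 - p) ** t) for t in range(1, 8))
        assert abs(diag.running_mean_qalys.iloc[-1] - closed) < 0.01

    def test_batch_se_shrinks(self, default_table):
        eqs = constant_hazard_equations(0.15)
        res = run_patient(_rec(), eqs, default_table,
                          SimConfig(n_loops=20_000, seed=6))
        q = res.loop_qalys()
        ses = [q[:k].std(ddof=1) / np.sqrt(k) for k in (1000, 5000, 20_000)]
        assert ses[0] > ses[1] > ses[2]
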