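"""Strategy effects: RR rate-transform, persistence/reversion, cost stream."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demcea import (
    AnalysisSettings,
    CareSetting,
    CareTransition,
    CohortTrace,
    Severity,
    StateValueEffect,
    Strategy,
    TransitionEffect,
    adjust_probability,
    build_strategy_parameters,
    intervention_cost_stream,
    run_strategy,
    time_in_state,
)
from demcea.states import state_index

from conftest import make_params, make_values

HOME_TO_INST = CareTransition(CareSetting.HOME_CARE, CareSetting.INSTITUTIONAL_CARE)
ALL_LIVING = frozenset(range(9))
COMMUNITY = [CareSetting.NO_FORMAL_CARE, CareSetting.HOME_CARE]


class TestAdjustProbability:
    def test_identity_at_rr_one_is_exact(self):
        for p in (0.0, 0.3, 0.999, 1.0):
            assert adjust_probability(p, 1.0) == p

    def test_zero_probability_stays_zero(self):
        assert adjust_probability(0.0, 0.3) == 0.0
        assert adjust_probability(0.0, 7.0) == 0.0

    def test_closed_form(self):
        got = adjust_probability(0.3, 0.5)
        assert got == pytest.approx(1 - 0.7**0.5, abs=1e-15)
        assert 0.0 < got < 0.3

    @settings(max_examples=300, derandomize=True)
    @given(p=st.floats(0.0, 0.999999), rr=st.floats(0.001, 50.0))
    def test_stays_in_unit_interval_and_directional(self, p, rr):
        q = adjust_probability(p, rr)
        assert 0.0 <= q < 1.0
        # strict direction holds wherever 1-p is representable away from 1
        if 1e-12 < p < 1:
            if rr < 1:
                assert q < p
            elif rr > 1:
                assert q > p

    def test_errors(self):
        with pytest.raises(ValueError):
            adjust_probability(0.3, 0.0)
        with pytest.raises(ValueError):
            adjust_probability(1.0, 0.5)
        with pytest.raises(ValueError):
            adjust_probability(1.2, 1.0)


def strategy_with(effects, persistence=4, eligibility=ALL_LIVING, **kw):
    return Strategy(name="tech", effects=effects, eligibility=eligibility,
                    persistence_cycles=persistence, **kw)


class TestBuildStrategyParameters:
    def test_empty_strategy_returns_baseline_objects(self, random_params):
        params, values = random_params(0)
        null = Strategy.null()
        for t in (0, 5, 100):
            p, v = build_strategy_parameters(params, values, null, t)
            assert p is params and v is values

    def test_value_effect_locality(self, random_params):
        params, values = random_params(1)
        target = state_index(Severity.MILD, CareSetting.NO_FORMAL_CARE)
        strat = strategy_with(
            [StateValueEffect("patient_utility", 0.05)],
            eligibility=frozenset({target}),
        )
        _, v = build_strategy_parameters(params, values, strat, 0)
        assert v.patient_utility[target] == pytest.approx(
            values.patient_utility[target] + 0.05
        )
        mask = np.ones(9, bool)
        mask[target] = False
        assert np.array_equal(v.patient_utility[mask], values.patient_utility[mask])
        assert np.array_equal(v.informal_hours, values.informal_hours)

    def test_transition_effect_only_touches_eligible_rows(self, random_params):
        params, _ = random_params(2)
        values = make_values()
        eligible = frozenset({state_index(Severity.MILD, CareSetting.HOME_CARE)})
        strat = strategy_with([TransitionEffect(HOME_TO_INST, 0.5)],
                              eligibility=eligible)
        p, _ = build_strategy_parameters(params, values, strat, 0)
        base = params.p_care[Severity.MILD, 1, 2]
        assert p.p_care[Severity.MILD, 1, 2] == pytest.approx(1 - (1 - base) ** 0.5)
        # moderate/severe home rows are not eligible: untouched
        assert np.array_equal(p.p_care[1:], params.p_care[1:])
        assert np.array_equal(p.p_death, params.p_death)
        assert np.array_equal(p.p_progress, params.p_progress)

    def test_reversion_is_bitwise_after_window(self, random_params):
        params, values = random_params(3)
        strat = strategy_with(
            [TransitionEffect(HOME_TO_INST, 0.5),
             StateValueEffect("patient_utility", 0.05)],
            persistence=4,
        )
        p, v = build_strategy_parameters(params, values, strat, 10)
        assert p is params and v is values
        p4, _ = build_strategy_parameters(params, values, strat, 4)
        assert p4 is params

    def test_linear_waning_interpolates(self, random_params):
        params, values = random_params(4)
        strat = strategy_with(
            [TransitionEffect(HOME_TO_INST, 0.5),
             StateValueEffect("patient_utility", 0.06)],
            persistence=2, waning="linear", waning_cycles=2,
        )
        base_p = params.p_care[0, 1, 2]
        # tail cycle 2 -> fraction 2/3, cycle 3 -> 1/3, cycle 4 -> baseline
        p, v = build_strategy_parameters(params, values, strat, 2)
        assert p.p_care[0, 1, 2] == pytest.approx(1 - (1 - base_p) ** (0.5 ** (2 / 3)))
        assert v.patient_utility[0] == pytest.approx(
            values.patient_utility[0] + 0.06 * 2 / 3
        )
        p, _ = build_strategy_parameters(params, values, strat, 4)
        assert p is params

    def test_utility_clamped_with_warning(self, random_params):
        params, _ = random_params(5)
        values = make_values(patient_utility=0.98)
        strat = strategy_with([StateValueEffect("patient_utility", 0.1)])
        with pytest.warns(UserWarning, match="clamped"):
            _, v = build_strategy_parameters(params, values, strat, 0)
        assert np.all(v.patient_utility <= 1.0)

    def test_hours_floored_with_warning(self, random_params):
        params, _ = random_params(5)
        values = make_values(informal_hours=1.0)
        strat = strategy_with([StateValueEffect("informal_hours", -5.0)])
        with pytest.warns(UserWarning, match="floored"):
            _, v = build_strategy_parameters(params, values, strat, 0)
        assert np.all(v.informal_hours >= 0.0)

    def test_structurally_zero_target_rejected(self, random_params):
        params, values = random_params(6)
        reversal = CareTransition(CareSetting.INSTITUTIONAL_CARE,
                                  CareSetting.HOME_CARE)
        strat = strategy_with([TransitionEffect(reversal, 0.5)])
        with pytest.raises(ValueError, match="structurally-zero"):
            build_strategy_parameters(params, values, strat, 0)


class TestInterventionCostStream:
    def trace(self, occupancy_rows):
        occ = np.asarray(occupancy_rows, dtype=float)
        return CohortTrace(occupancy=occ, cycle_length=1.0 / 12.0)

    def full_in(self, idx):
        row = np.zeros(10)
        row[idx] = 1.0
        return row

    def test_zero_cost_gives_zero_stream(self):
        strat = strategy_with([], persistence=5)
        trace = self.trace([self.full_in(0)] * 4)
        assert np.array_equal(intervention_cost_stream(strat, trace), np.zeros(3))

    def test_pro_rated_per_cycle(self):
        strat = strategy_with([StateValueEffect("patient_utility", 0.01)],
                              persistence=10, intervention_cost=1200.0)
        trace = self.trace([self.full_in(0)] * 5)
        np.testing.assert_allclose(intervention_cost_stream(strat, trace),
                                   np.full(4, 100.0))

    def test_weighted_by_eligible_occupancy(self):
        strat = Strategy(name="t", effects=[], intervention_cost=1200.0,
                         eligibility=frozenset({0}), persistence_cycles=10)
        row = np.zeros(10)
        row[0], row[3] = 0.6, 0.4
        trace = self.trace([row] * 3)
        np.testing.assert_allclose(intervention_cost_stream(strat, trace),
                                   np.full(2, 60.0))

    def test_stops_at_persistence_window(self):
        strat = Strategy(name="t", effects=[], intervention_cost=1200.0,
                         eligibility=frozenset({0}), persistence_cycles=2)
        trace = self.trace([self.full_in(0)] * 6)
        np.testing.assert_allclose(intervention_cost_stream(strat, trace),
                                   [100.0, 100.0, 0.0, 0.0, 0.0])


class TestDirectionOfEffect:
    @pytest.mark.parametrize("seed", range(20))
    def test_lower_institutionalization_rr_never_reduces_community_time(
        self, random_params, seed
    ):
        params, values = random_params(seed)
        settings_ = AnalysisSettings(horizon_years=20.0,
                                     extinction_threshold=None)
        init = np.zeros(10)
        init[0] = 1.0
        base = run_strategy(params, values, Strategy.null(), init, settings_)
        strat = strategy_with([TransitionEffect(HOME_TO_INST, 0.7)],
                              persistence=10**6)
        treated = run_strategy(params, values, strat, init, settings_)
        community_base = time_in_state(base.trace, COMMUNITY)
        community_treated = time_in_state(treated.trace, COMMUNITY)
        assert community_treated >= community_base - 1e-12
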