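"""PSA sampling, CEAC, tornado ordering, and scenario tables."""

import numpy as np
import pytest

from demcea import (
    ParameterPrior,
    PSAResult,
    apply_overrides,
    ceac,
    run_cea,
    run_psa,
    run_scenarios,
    sample_parameters,
    tornado,
)
from demcea.fixtures import FixtureSpec, fixture_config

STRATEGY = "community_technology"


@pytest.fixture(scope="module")
def toy_config():
    """Fixture config shrunk to a short horizon so PSA draws are cheap."""
    cfg = fixture_config(FixtureSpec(seed=3))
    return apply_overrides(cfg, {"analysis.horizon_years": 10.0})


def degenerate_priors(cfg):
    out = []
    for pc in cfg.psa.priors:
        if pc.family == "dirichlet":
            continue
        out.append(ParameterPrior(path=pc.path, family=pc.family,
                                  mean=pc.mean, se=0.0))
    return out


class TestSampleParameters:
    def test_same_seed_identical_draws(self, toy_config):
        priors = [ParameterPrior.from_config(p) for p in toy_config.psa.priors]
        a = sample_parameters(priors, seed=42, n=20)
        b = sample_parameters(priors, seed=42, n=20)
        assert a == b
        c = sample_parameters(priors, seed=43, n=20)
        assert a != c

    def test_beta_moment_matching_clt_bound(self):
        prior = ParameterPrior(path="x", family="beta", mean=0.3, se=0.05)
        draws = sample_parameters([prior], seed=0, n=10_000)
        xs = np.array([d["x"] for d in draws])
        assert abs(xs.mean() - 0.3) < 3 * 0.05 / np.sqrt(10_000)
        assert abs(xs.std(ddof=1) - 0.05) < 0.005
        assert np.all((xs > 0) & (xs < 1))

    def test_gamma_and_lognormal_moment_matching(self):
        priors = [
            ParameterPrior(path="g", family="gamma", mean=1000.0, se=150.0),
            ParameterPrior(path="l", family="lognormal", mean=0.8, se=0.1),
        ]
        draws = sample_parameters(priors, seed=1, n=20_000)
        g = np.array([d["g"] for d in draws])
        ln = np.array([d["l"] for d in draws])
        assert abs(g.mean() - 1000.0) < 3 * 150 / np.sqrt(20_000)
        assert abs(ln.mean() - 0.8) < 3 * 0.1 / np.sqrt(20_000)
        assert np.all(g > 0) and np.all(ln > 0)

    def test_dirichlet_row_on_simplex(self):
        prior = ParameterPrior(path="row", family="dirichlet",
                               counts=(80.0, 15.0, 5.0),
                               keys=("home_care", "institutional_care"))
        draws = sample_parameters([prior], seed=2, n=50)
        for d in draws:
            row = d["row"]
            assert set(row) == {"home_care", "institutional_care"}
            total = sum(row.values())
            assert 0.0 < total < 1.0  # stay probability is the residual

    def test_infeasible_beta_se_rejected(self):
        prior = ParameterPrior(path="x", family="beta", mean=0.5, se=0.6)
        with pytest.raises(ValueError, match="infeasible"):
            sample_parameters([prior], seed=0, n=2)


class TestRunPsa:
    def test_degenerate_priors_reproduce_base_case(self, toy_config):
        base, _, _ = run_cea(toy_config, STRATEGY)
        result = run_psa(toy_config, STRATEGY, seed=5, n=8,
                         priors=degenerate_priors(toy_config))
        np.testing.assert_allclose(result.delta_cost, base.delta_cost,
                                   rtol=1e-9)
        np.testing.assert_allclose(result.delta_qaly, base.delta_qaly,
                                   rtol=1e-9)

    def test_null_strategy_all_zero_increments(self, toy_config):
        cfg = apply_overrides(
            toy_config,
            {
                "strategies.community_technology.pilot_effects.0.effect": 0.0,
                "strategies.community_technology.pilot_effects.1.effect": 0.0,
                "strategies.community_technology.pilot_effects.2.effect": 0.0,
                "strategies.community_technology.intervention_cost_per_year": 0.0,
            },
        )
        result = run_psa(cfg, STRATEGY, seed=5, n=5,
                         priors=degenerate_priors(cfg))
        assert np.all(result.delta_cost == 0.0)
        assert np.all(result.delta_qaly == 0.0)

    def test_seed_determinism_bitwise(self, toy_config):
        a = run_psa(toy_config, STRATEGY, seed=11, n=20)
        b = run_psa(toy_config, STRATEGY, seed=11, n=20)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)
        assert np.array_equal(a.ceac, b.ceac)

    def test_mean_recovery_with_priors_centered_on_base(self, toy_config):
        # with priors centered on the base case, the PSA mean approaches the
        # base-case increments; checked in the small-variance regime where
        # the model's nonlinearity bias (O(sigma^2)) is negligible next to
        # the 3-standard-error Monte-Carlo band
        base, _, _ = run_cea(toy_config, STRATEGY)
        priors = [
            ParameterPrior(path=p.path, family=p.family, mean=p.mean,
                           se=0.25 * p.se)
            for p in toy_config.psa.priors
            if p.family != "dirichlet"
        ]
        result = run_psa(toy_config, STRATEGY, seed=17, n=2000, priors=priors)
        for draws, target in ((result.delta_qaly, base.delta_qaly),
                              (result.delta_cost, base.delta_cost)):
            se = draws.std(ddof=1) / np.sqrt(result.n)
            assert abs(draws.mean() - target) < 3 * se

    def test_ceac_matches_brute_force_count(self, toy_config):
        result = run_psa(toy_config, STRATEGY, seed=11, n=100)
        wtp_grid = np.array([0.0, 30_000.0, 80_000.0])
        curve = ceac(result, wtp_grid)
        for k, wtp in enumerate(wtp_grid):
            count = sum(
                1
                for dq, dc in zip(result.delta_qaly, result.delta_cost)
                if wtp * dq - dc > 0
            )
            assert curve[k] == count / result.n


class TestCeac:
    def fabricate(self, dq, dc):
        return PSAResult(n=len(dq), seed=0, delta_qaly=np.array(dq),
                         delta_cost=np.array(dc), wtp_grid=np.array([0.0]))

    def test_all_dominant_curve_is_one(self):
        psa = self.fabricate([0.1, 0.2], [-100.0, -50.0])
        assert np.all(ceac(psa, [0, 10_000, 1e6]) == 1.0)

    def test_all_dominated_curve_is_zero(self):
        psa = self.fabricate([-0.1, -0.2], [100.0, 50.0])
        assert np.all(ceac(psa, [0, 10_000, 1e6]) == 0.0)

    def test_hand_counted_mixed_draws(self):
        psa = self.fabricate([0.1, 0.1], [1000.0, 3000.0])
        assert ceac(psa, [20_000.0])[0] == 0.5

    def test_ties_count_as_not_cost_effective(self):
        psa = self.fabricate([0.1], [2000.0])
        assert ceac(psa, [20_000.0])[0] == 0.0

    def test_monotone_in_wtp_when_all_gains(self, toy_config):
        result = run_psa(toy_config, STRATEGY, seed=3, n=40)
        if np.all(result.delta_qaly >= 0):
            curve = ceac(result, np.linspace(0, 1e5, 11))
            assert np.all(np.diff(curve) >= 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ceac(self.fabricate([0.1], [0.0]), [])


class TestTornado:
    def test_zero_width_when_range_collapsed(self, toy_config):
        base = toy_config.psa.priors[0].mean
        path = "transitions.p_death.moderate.home_care"
        bars = tornado(toy_config, STRATEGY, ranges=[(path, base, base)],
                       wtp=50_000.0)
        assert bars[0].width == 0.0

    def test_parameter_without_downstream_influence_gives_zero_width(
        self, toy_config
    ):
        # with caregiver QALYs excluded, a caregiver utility delta cannot
        # reach any output
        path = "values.states.severe|institutional_care.caregiver_utility_delta"
        cfg = apply_overrides(toy_config,
                              {"analysis.include_caregiver_qalys": False})
        bars = tornado(cfg, STRATEGY, ranges=[(path, -0.5, 0.5)], wtp=50_000.0)
        assert bars[0].width == pytest.approx(0.0, abs=1e-9)

    def test_ordering_matches_independent_recomputation(self, toy_config):
        ranges = [(r.path, r.low, r.high) for r in toy_config.tornado.ranges]
        wtp = toy_config.tornado.wtp
        bars = tornado(toy_config, STRATEGY)
        widths = {}
        for path, low, high in ranges:
            nmb = []
            for value in (low, high):
                res, _, _ = run_cea(apply_overrides(toy_config, {path: value}),
                                    STRATEGY)
                nmb.append(wtp * res.delta_qaly - res.delta_cost)
            widths[path] = abs(nmb[1] - nmb[0])
        expected_order = sorted(widths, key=widths.get, reverse=True)
        assert [b.path for b in bars] == expected_order
        for b in bars:
            assert b.width == pytest.approx(widths[b.path], rel=1e-9)

    def test_range_not_bracketing_base_rejected(self, toy_config):
        path = "transitions.p_death.moderate.home_care"
        with pytest.raises(ValueError, match="low <= base <= high"):
            tornado(toy_config, STRATEGY, ranges=[(path, 0.9, 0.95)],
                    wtp=50_000.0)


class TestScenarios:
    def test_empty_scenario_equals_base_case(self, toy_config):
        table = run_scenarios(toy_config, STRATEGY, scenarios={"noop": {}})
        base = table[table.scenario == "base_case"].iloc[0]
        noop = table[table.scenario == "noop"].iloc[0]
        assert noop.delta_qaly == base.delta_qaly
        assert noop.delta_cost == base.delta_cost

    def test_worst_case_null_links_leave_only_cost(self, toy_config):
        table = run_scenarios(toy_config, STRATEGY)
        worst = table[table.scenario == "worst_case"].iloc[0]
        assert worst.delta_qaly == 0.0
        assert worst.delta_cost > 0.0
        assert worst.icer == "undefined (dQ=0)"

    def test_best_case_nmb_at_least_worst_case(self, toy_config):
        table = run_scenarios(toy_config, STRATEGY)
        best = table[table.scenario == "best_case"].iloc[0].nmb
        worst = table[table.scenario == "worst_case"].iloc[0].nmb
        assert best >= worst

    def test_invalid_override_path_rejected(self, toy_config):
        with pytest.raises(Exception, match="no key"):
            run_scenarios(toy_config, STRATEGY,
                          scenarios={"bad": {"transitions.nope": 0.1}})
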