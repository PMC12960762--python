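"""Composition layer: run strategies end-to-end and compare them.

Both the usual-care (null) strategy and any technology strategy go through
the same code path — the cohort is propagated through per-cycle matrices
built from the strategy-effective parameters, and QALY/cost streams use the
strategy-effective state values cycle by cycle.  A strategy with no effects
and no cost therefore reproduces the control results bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    ModelConfig,
    to_baseline_parameters,
    to_initial_distribution,
    to_state_values,
    to_strategy,
)
from .engine import (
    CohortTrace,
    _discount_factors,
    n_cycles_for_horizon,
    run_cohort,
)
from .intervention import (
    Strategy,
    build_strategy_parameters,
    effect_fraction,
    intervention_cost_stream,
)
from .states import BaselineParameters, N_LIVING, build_cycle_matrix
from .valuation import (
    CEAResult,
    StateValues,
    StrategyOutcome,
    WEEKS_PER_YEAR,
    compare,
)

__all__ = ["AnalysisSettings", "StrategyRun", "run_strategy", "run_cea"]

USUAL_CARE = "usual_care"


@dataclass
class AnalysisSettings:
    """Run-level settings shared by every strategy in a comparison."""

    horizon_years: float = 40.0
    discount_rate_effects: float = 0.015
    discount_rate_costs: float = 0.04
    half_cycle_correction: bool = True
    include_caregiver_qalys: bool = True
    wtp_grid: np.ndarray = None  # type: ignore[assignment]
    extinction_threshold: float | None = 1e-8

    def __post_init__(self) -> None:
        if self.wtp_grid is None:
            self.wtp_grid = np.array([0.0, 20000.0, 50000.0, 80000.0, 100000.0])
        self.wtp_grid = np.asarray(self.wtp_grid, dtype=float)

    @classmethod
    def from_config(cls, cfg: ModelConfig) -> "AnalysisSettings":
        a = cfg.analysis
        return cls(
            horizon_years=a.horizon_years,
            discount_rate_effects=a.discount_rate_effects,
            discount_rate_costs=a.discount_rate_costs,
            half_cycle_correction=a.half_cycle_correction,
            include_caregiver_qalys=a.include_caregiver_qalys,
            wtp_grid=np.asarray(a.wtp_grid, dtype=float),
            extinction_threshold=a.extinction_threshold or None,
        )


@dataclass
class StrategyRun:
    """A strategy's cohort trace and discounted outcome totals."""

    strategy: Strategy
    trace: CohortTrace
    outcome: StrategyOutcome


def run_strategy(
    baseline: BaselineParameters,
    values: StateValues,
    strategy: Strategy,
    init: np.ndarray,
    settings: AnalysisSettings,
) -> StrategyRun:
    """Propagate the cohort under a strategy and value the trace.

    Effective parameters depend on the cycle only through the effect
    fraction (1 while persistent, linear tail under waning, 0 after), so
    matrices and value vectors are cached per fraction.
    """
    n_cycles = n_cycles_for_horizon(settings.horizon_years, baseline.cycle_length)

    cache: dict[float, tuple[np.ndarray, StateValues]] = {}

    def effective(t: int) -> tuple[np.ndarray, StateValues]:
        f = effect_fraction(strategy, t) if strategy.effects else 0.0
        if f not in cache:
            p_eff, v_eff = build_strategy_parameters(baseline, values, strategy, t)
            cache[f] = (build_cycle_matrix(p_eff).entries, v_eff)
        return cache[f]

    trace = run_cohort(
        lambda t: effective(t)[0],
        init,
        n_cycles,
        cycle_length=baseline.cycle_length,
        extinction_threshold=settings.extinction_threshold,
    )

    n = trace.n_cycles
    occ = trace.occupancy
    if settings.half_cycle_correction:
        weights = 0.5 * (occ[:-1, :N_LIVING] + occ[1:, :N_LIVING])
    else:
        weights = occ[1:, :N_LIVING]
    disc_e = _discount_factors(n, settings.discount_rate_effects, trace.cycle_length)
    disc_c = _discount_factors(n, settings.discount_rate_costs, trace.cycle_length)
    cl = trace.cycle_length

    fractions = np.array(
        [effect_fraction(strategy, t) if strategy.effects else 0.0 for t in range(n)]
    )
    qaly_patient = qaly_caregiver = cost_formal = cost_informal = 0.0
    for f in np.unique(fractions):
        mask = fractions == f
        v = effective(int(np.argmax(mask)))[1]
        block = weights[mask]
        qaly_patient += float(disc_e[mask] @ (block @ v.patient_utility)) * cl
        if settings.include_caregiver_qalys:
            qaly_caregiver += (
                float(disc_e[mask] @ (block @ v.caregiver_utility_delta)) * cl
            )
        cost_formal += float(disc_c[mask] @ (block @ v.formal_cost)) * cl
        informal_rate = v.informal_hours * WEEKS_PER_YEAR * v.unit_wage
        cost_informal += float(disc_c[mask] @ (block @ informal_rate)) * cl

    stream = intervention_cost_stream(strategy, trace)
    cost_intervention = float(np.sum(stream * disc_c))

    return StrategyRun(
        strategy=strategy,
        trace=trace,
        outcome=StrategyOutcome(
            name=strategy.name,
            qaly_patient=qaly_patient,
            qaly_caregiver=qaly_caregiver,
            cost_formal=cost_formal,
            cost_informal=cost_informal,
            cost_intervention=cost_intervention,
        ),
    )


def run_cea(
    cfg: ModelConfig, strategy_name: str
) -> tuple[CEAResult, StrategyRun, StrategyRun]:
    """Run usual care and a named strategy on a config and compare them."""
    baseline = to_baseline_parameters(cfg)
    values = to_state_values(cfg)
    init = to_initial_distribution(cfg)
    settings = AnalysisSettings.from_config(cfg)
    control = run_strategy(baseline, values, Strategy.null(USUAL_CARE), init, settings)
    strategy = to_strategy(cfg, strategy_name)
    intervention = run_strategy(baseline, values, strategy, init, settings)
    result = compare(control.outcome, intervention.outcome, settings.wtp_grid)
    return result, control, intervention
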