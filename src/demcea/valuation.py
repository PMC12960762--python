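"""State values, discounted QALY/cost accumulation, and strategy comparison.

The model adopts a societal perspective: total cost is formal care cost plus
informal caregiving time valued at an opportunity-cost wage (hours/week x
weeks/year x unit wage), plus the intervention's own cost while in use.
Patient and caregiver quality-of-life streams are accumulated separately;
the caregiver stream is a per-cycle utility increment/decrement tied to the
patient's state (one caregiver per patient, ceasing at patient death).

Costs and effects are discounted at separate per-year rates (defaults 4% and
1.5%, the Dutch guideline convention; both overridable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import CohortTrace, _discount_factors, accumulate_stream
from .states import N_LIVING, ValidationReport

__all__ = [
    "WEEKS_PER_YEAR",
    "StateValues",
    "StrategyOutcome",
    "CEAResult",
    "validate_values",
    "accumulate_qalys",
    "accumulate_costs",
    "compare",
]

#: average weeks per year used to annualize weekly informal-care hours
WEEKS_PER_YEAR = 52.18


@dataclass
class StateValues:
    """Annualized values attached to each of the 9 living states.

    Utilities are per year of occupancy (dimensionless); ``formal_cost`` is
    currency/year; ``informal_hours`` is hours/week of informal care; the
    single ``unit_wage`` (currency/hour) values informal time.  Death carries
    all-zero values by construction (streams are restricted to living states).
    """

    patient_utility: np.ndarray  # (9,)
    caregiver_utility_delta: np.ndarray  # (9,)
    formal_cost: np.ndarray  # (9,)
    informal_hours: np.ndarray  # (9,)
    unit_wage: float
    currency: str = "EUR"

    def __post_init__(self) -> None:
        for name in ("patient_utility", "caregiver_utility_delta",
                     "formal_cost", "informal_hours"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def copy(self) -> "StateValues":
        return replace(
            self,
            patient_utility=self.patient_utility.copy(),
            caregiver_utility_delta=self.caregiver_utility_delta.copy(),
            formal_cost=self.formal_cost.copy(),
            informal_hours=self.informal_hours.copy(),
        )


def validate_values(values: StateValues) -> ValidationReport:
    report = ValidationReport()
    for name in ("patient_utility", "caregiver_utility_delta",
                 "formal_cost", "informal_hours"):
        arr = getattr(values, name)
        if arr.shape != (N_LIVING,):
            report.add(f"{name} must have shape ({N_LIVING},), got {arr.shape}")
    if not report:
        return report
    for name in ("patient_utility", "caregiver_utility_delta"):
        arr = getattr(values, name)
        bad = np.flatnonzero((arr < -1.0) | (arr > 1.0))
        for i in bad:
            report.add(f"{name}[{i}] = {arr[i]} outside [-1, 1]")
    for name in ("formal_cost", "informal_hours"):
        arr = getattr(values, name)
        for i in np.flatnonzero(arr < 0):
            report.add(f"{name}[{i}] = {arr[i]} negative")
    if values.unit_wage < 0:
        report.add(f"unit_wage = {values.unit_wage} negative")
    return report


def accumulate_qalys(
    trace: CohortTrace,
    values: StateValues,
    discount_rate: float = 0.015,
    half_cycle: bool = True,
    include_caregiver: bool = True,
) -> tuple[float, float]:
    """Discounted (patient, caregiver) QALYs over the trace.

    Per-cycle contribution is occupancy x utility x cycle length, with the
    same half-cycle and discounting conventions as life-years.  The caregiver
    stream uses ``caregiver_utility_delta`` and is reported separately
    (0.0 when ``include_caregiver`` is off).
    """
    living = trace.occupancy[:, :N_LIVING]
    patient = accumulate_stream(
        trace, living @ values.patient_utility, discount_rate, half_cycle
    )
    caregiver = 0.0
    if include_caregiver:
        caregiver = accumulate_stream(
            trace, living @ values.caregiver_utility_delta, discount_rate, half_cycle
        )
    return patient, caregiver


def accumulate_costs(
    trace: CohortTrace,
    values: StateValues,
    intervention_stream: np.ndarray | None = None,
    discount_rate: float = 0.04,
    half_cycle: bool = True,
) -> dict[str, float]:
    """Discounted cost breakdown: formal, informal, intervention, total.

    Informal care is valued as hours/week x 52.18 weeks/year x unit wage.
    ``intervention_stream`` is a per-cycle currency amount (already pro-rated
    to the cycle); it is discounted at the cost rate but, being a payment
    stream rather than an occupancy stream, receives no half-cycle trapezoid.
    """
    report = validate_values(values)
    if not report:
        raise ValueError("invalid state values:\n  " + "\n  ".join(report.messages))
    living = trace.occupancy[:, :N_LIVING]
    formal = accumulate_stream(
        trace, living @ values.formal_cost, discount_rate, half_cycle
    )
    informal_rate = values.informal_hours * WEEKS_PER_YEAR * values.unit_wage
    informal = accumulate_stream(
        trace, living @ informal_rate, discount_rate, half_cycle
    )
    intervention = 0.0
    if intervention_stream is not None:
        stream = np.asarray(intervention_stream, dtype=float)
        if stream.shape != (trace.n_cycles,):
            raise ValueError(
                f"intervention stream must have {trace.n_cycles} entries, "
                f"got {stream.shape}"
            )
        disc = _discount_factors(trace.n_cycles, discount_rate, trace.cycle_length)
        intervention = float(np.sum(stream * disc))
    return {
        "formal": formal,
        "informal": informal,
        "intervention": intervention,
        "total": formal + informal + intervention,
    }


@dataclass
class StrategyOutcome:
    """Discounted totals for one strategy run."""

    name: str
    qaly_patient: float
    qaly_caregiver: float
    cost_formal: float
    cost_informal: float
    cost_intervention: float

    @property
    def qaly_total(self) -> float:
        return self.qaly_patient + self.qaly_caregiver

    @property
    def cost_total(self) -> float:
        return self.cost_formal + self.cost_informal + self.cost_intervention


#: absolute |dQ| below which the ICER is reported as a label, not a ratio
ICER_QALY_EPS = 1e-12


@dataclass
class CEAResult:
    """Incremental comparison of an intervention strategy against control.

    ``icer`` is the incremental cost-effectiveness ratio dC/dQ when
    |dQ| > 1e-12; otherwise a label: "dominant" (cheaper and more effective),
    "dominated" (dearer and less effective), or "undefined (dQ=0)".
    ``nmb[i] = wtp_grid[i] * dQ - dC`` (net monetary benefit).
    """

    control: StrategyOutcome
    intervention: StrategyOutcome
    delta_qaly: float
    delta_cost: float
    icer: float | str
    wtp_grid: np.ndarray
    nmb: np.ndarray
    components: dict[str, float] = field(default_factory=dict)


def _icer(delta_cost: float, delta_qaly: float) -> float | str:
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    if abs(delta_qaly) <= ICER_QALY_EPS:
        return "undefined (dQ=0)"
    return delta_cost / delta_qaly


def compare(
    control: StrategyOutcome,
    intervention: StrategyOutcome,
    wtp_grid: np.ndarray | list[float],
) -> CEAResult:
    """Pairwise incremental CEA of intervention vs control.

    Both outcomes must come from runs on identical horizon and discount
    settings (the caller's responsibility; the model runner enforces it).
    """
    wtp = np.asarray(wtp_grid, dtype=float)
    dq = intervention.qaly_total - control.qaly_total
    dc = intervention.cost_total - control.cost_total
    return CEAResult(
        control=control,
        intervention=intervention,
        delta_qaly=dq,
        delta_cost=dc,
        icer=_icer(dc, dq),
        wtp_grid=wtp,
        nmb=wtp * dq - dc,
        components={
            "delta_qaly_patient": intervention.qaly_patient - control.qaly_patient,
            "delta_qaly_caregiver": intervention.qaly_caregiver - control.qaly_caregiver,
            "delta_cost_formal": intervention.cost_formal - control.cost_formal,
            "delta_cost_informal": intervention.cost_informal - control.cost_informal,
            "delta_cost_intervention": intervention.cost_intervention
            - control.cost_intervention,
        },
    )
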