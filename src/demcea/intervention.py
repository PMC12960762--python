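"""Technology strategies as time-varying modifications of baseline inputs.

A strategy carries (1) transition effects — a relative risk applied to a
named care transition on the rate scale, ``p' = 1 - (1 - p)^rr``, so the
reported RR is treated as a hazard ratio under cycle-constant rates and the
result is a valid probability for any rr > 0 — and (2) state-value effects —
absolute per-year deltas on a value stream in eligible states.

Effects are active for ``persistence_cycles`` cycles, optionally followed by
a linear waning tail; beyond the window the effective parameters are the
baseline objects themselves (bitwise reversion: once use stops, effects are
not sustained and the cohort reverts to usual-care dynamics).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .states import (
    BaselineParameters,
    CareSetting,
    Severity,
    state_index,
)
from .valuation import StateValues
from .engine import CohortTrace

__all__ = [
    "CareTransition",
    "TransitionEffect",
    "StateValueEffect",
    "Strategy",
    "adjust_probability",
    "effect_fraction",
    "build_strategy_parameters",
    "intervention_cost_stream",
    "VALUE_STREAMS",
]

VALUE_STREAMS = (
    "patient_utility",
    "caregiver_utility_delta",
    "informal_hours",
    "formal_cost",
)


@dataclass(frozen=True)
class CareTransition:
    """A named care-setting transition, optionally severity-specific."""

    from_setting: CareSetting
    to_setting: CareSetting
    severity: Severity | None = None

    def __post_init__(self) -> None:
        if self.from_setting == self.to_setting:
            raise ValueError("care transition must change setting")

    @property
    def name(self) -> str:
        base = f"{self.from_setting.label}->{self.to_setting.label}"
        return base if self.severity is None else f"{base}|{self.severity.label}"


@dataclass(frozen=True)
class TransitionEffect:
    """Relative risk on a care transition, applied via the rate transform."""

    target: CareTransition
    rr: float

    def __post_init__(self) -> None:
        if not self.rr > 0:
            raise ValueError(f"relative risk must be > 0, got {self.rr}")


@dataclass(frozen=True)
class StateValueEffect:
    """Absolute per-year delta on a value stream in eligible states.

    ``states`` optionally restricts the effect to a subset of the strategy's
    eligibility (None = all eligible states).
    """

    stream: str
    delta: float
    states: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.stream not in VALUE_STREAMS:
            raise ValueError(
                f"unknown value stream {self.stream!r}; expected one of {VALUE_STREAMS}"
            )


@dataclass
class Strategy:
    """A named technology strategy.

    ``eligibility`` is the set of living-state indices where the technology
    is in use; effects apply only there and the per-year
    ``intervention_cost`` accrues only over eligible occupancy while active.
    ``persistence_cycles`` (required, no default: persistence is an explicit
    scenario choice) is how many cycles effects stay at full strength;
    ``waning="linear"`` adds a tail of ``waning_cycles`` over which deltas
    shrink linearly and RRs interpolate toward 1 on the log scale.

    Null effects (delta exactly 0, or rr exactly 1) are dropped on
    construction, so a nominally-null strategy takes the same code path as
    usual care and reproduces it exactly.
    """

    name: str
    effects: list[TransitionEffect | StateValueEffect]
    eligibility: frozenset[int]
    persistence_cycles: int
    waning: str = "none"
    waning_cycles: int = 0
    intervention_cost: float = 0.0

    def __post_init__(self) -> None:
        self.effects = [e for e in self.effects if not is_null_effect(e)]
        self.eligibility = frozenset(int(i) for i in self.eligibility)
        if self.persistence_cycles < 0:
            raise ValueError("persistence_cycles must be >= 0")
        if self.intervention_cost < 0:
            raise ValueError("intervention_cost must be >= 0")
        if self.waning not in ("none", "linear"):
            raise ValueError(f"unknown waning mode {self.waning!r}")
        if self.waning == "none" and self.waning_cycles:
            raise ValueError("waning_cycles requires waning='linear'")
        if self.effects and not self.eligibility:
            raise ValueError("a strategy with effects needs non-empty eligibility")

    @classmethod
    def null(cls, name: str = "usual_care") -> "Strategy":
        """The no-effect, no-cost strategy (usual care)."""
        return cls(name=name, effects=[], eligibility=frozenset(),
                   persistence_cycles=0)


def is_null_effect(effect: TransitionEffect | StateValueEffect) -> bool:
    """True for effects that cannot change any model quantity."""
    if isinstance(effect, TransitionEffect):
        return effect.rr == 1.0
    return effect.delta == 0.0


def adjust_probability(p: float, rr: float) -> float:
    """Apply a relative risk to a per-cycle probability on the rate scale.

    Returns ``1 - (1 - p)^rr`` (constant-rate transform), which stays in
    [0, 1) for any ``0 <= p < 1`` and ``rr > 0``.  ``p = 1`` is only legal
    with ``rr = 1``.
    """
    if not rr > 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p == 1.0:
        if rr == 1.0:
            return 1.0
        raise ValueError("cannot apply rr != 1 to a probability of exactly 1")
    if rr == 1.0:
        return p
    q = 1.0 - (1.0 - p) ** rr
    # the transform is < 1 exactly; guard against float rounding to 1.0
    return min(q, math.nextafter(1.0, 0.0))


def effect_fraction(strategy: Strategy, cycle_index: int) -> float:
    """Effect strength at a cycle: 1 during persistence, 0 after the window,
    linearly decreasing over the waning tail (log-scale for RRs)."""
    if cycle_index < strategy.persistence_cycles:
        return 1.0
    if strategy.waning == "linear" and strategy.waning_cycles > 0:
        into_tail = cycle_index - strategy.persistence_cycles
        if into_tail < strategy.waning_cycles:
            return (strategy.waning_cycles - into_tail) / (strategy.waning_cycles + 1)
    return 0.0


def _apply_transition_effect(
    params: BaselineParameters,
    effect: TransitionEffect,
    eligibility: frozenset[int],
    fraction: float,
) -> None:
    tgt = effect.target
    c_from, c_to = tgt.from_setting, tgt.to_setting
    if c_to < c_from and not params.allow_care_reversal:
        raise ValueError(
            f"effect targets structurally-zero transition {tgt.name} "
            "(care reversal disallowed)"
        )
    rr_eff = effect.rr ** fraction  # log-scale interpolation toward rr=1
    severities = [tgt.severity] if tgt.severity is not None else list(Severity)
    for s in severities:
        if state_index(s, c_from) not in eligibility:
            continue
        params.p_care[s, c_from, c_to] = adjust_probability(
            params.p_care[s, c_from, c_to], rr_eff
        )


def _apply_value_effect(
    values: StateValues,
    effect: StateValueEffect,
    eligibility: frozenset[int],
    fraction: float,
) -> None:
    states = eligibility if effect.states is None else (eligibility & effect.states)
    if not states:
        return
    idx = sorted(states)
    arr = getattr(values, effect.stream)
    arr[idx] += effect.delta * fraction
    if effect.stream in ("patient_utility", "caregiver_utility_delta"):
        out = (arr[idx] < -1.0) | (arr[idx] > 1.0)
        if np.any(out):
            warnings.warn(
                f"{effect.stream} clamped to [-1, 1] in {int(out.sum())} state(s)",
                stacklevel=2,
            )
            arr[idx] = np.clip(arr[idx], -1.0, 1.0)
    else:
        neg = arr[idx] < 0.0
        if np.any(neg):
            warnings.warn(
                f"{effect.stream} floored at 0 in {int(neg.sum())} state(s)",
                stacklevel=2,
            )
            arr[idx] = np.maximum(arr[idx], 0.0)


def build_strategy_parameters(
    baseline: BaselineParameters,
    values: StateValues,
    strategy: Strategy,
    cycle_index: int,
) -> tuple[BaselineParameters, StateValues]:
    """Effective (parameters, values) for a strategy at a given cycle.

    While the strategy is active, transition effects modify care-transition
    probabilities whose source state is eligible (the row is re-closed by
    the residual stay probability, leaving untargeted transitions unchanged)
    and value effects shift value streams in eligible states.  Beyond the
    persistence window (including any waning tail) the baseline objects are
    returned unchanged — reversion is exact, not approximate.
    """
    fraction = effect_fraction(strategy, cycle_index)
    if fraction == 0.0 or not strategy.effects:
        return baseline, values
    params_eff = baseline.copy()
    values_eff = values.copy()
    for effect in strategy.effects:
        if isinstance(effect, TransitionEffect):
            _apply_transition_effect(
                params_eff, effect, strategy.eligibility, fraction
            )
        else:
            _apply_value_effect(values_eff, effect, strategy.eligibility, fraction)
    return params_eff, values_eff


def intervention_cost_stream(
    strategy: Strategy, trace: CohortTrace
) -> np.ndarray:
    """Undiscounted per-cycle intervention cost, pro-rated to cycle length.

    Cost accrues only over start-of-cycle occupancy of eligible states and
    only within the persistence window (not over the waning tail, which
    represents residual effect after use has stopped).
    """
    n = trace.n_cycles
    stream = np.zeros(n)
    if strategy.intervention_cost == 0.0 or not strategy.eligibility:
        return stream
    idx = sorted(strategy.eligibility)
    active = min(strategy.persistence_cycles, n)
    occ = trace.occupancy[:active, idx].sum(axis=1)
    stream[:active] = occ * strategy.intervention_cost * trace.cycle_length
    return stream
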