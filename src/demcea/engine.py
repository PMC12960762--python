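"""Cohort propagation over the cycle matrix and life-year accumulation.

A Markov cohort model is deterministic: each cycle the state-occupancy row
vector is multiplied by the (possibly time-varying) one-cycle transition
matrix.  Occupancy is recorded at cycle boundaries; "time in state" credits
end-of-boundary occupancy (standard cohort convention), optionally with the
trapezoid half-cycle correction.  Discounting uses per-year rates compounded
per cycle via the exponent ``t * cycle_length`` with the first cycle
discounted (t = 1 convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from .states import (
    DEATH_INDEX,
    N_LIVING,
    N_STATES,
    STATE_INDEX_BY_NAME,
    CareSetting,
    CycleMatrix,
    Severity,
    state_index,
)

__all__ = [
    "CohortTrace",
    "initial_distribution",
    "run_cohort",
    "life_years",
    "time_in_state",
    "n_cycles_for_horizon",
]

MatrixLike = Union[CycleMatrix, np.ndarray]
MatrixSource = Union[MatrixLike, Sequence[MatrixLike], Callable[[int], MatrixLike]]


@dataclass
class CohortTrace:
    """State occupancy at each cycle boundary.

    ``occupancy[t]`` is the distribution over the 10 states at boundary ``t``
    (row 0 = initial distribution); every row sums to 1 and the death column
    is non-decreasing in ``t``.
    """

    occupancy: np.ndarray  # (n_cycles + 1, 10)
    cycle_length: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def living_mass(self) -> np.ndarray:
        """Total living occupancy at each boundary."""
        return self.occupancy[:, :N_LIVING].sum(axis=1)

    @property
    def years(self) -> np.ndarray:
        """Model time in years at each boundary."""
        return np.arange(self.occupancy.shape[0]) * self.cycle_length


def initial_distribution(
    mass: dict[str, float] | np.ndarray | None = None,
) -> np.ndarray:
    """Build a validated initial distribution over the 10 states.

    ``None`` gives the default cohort entry point: 100% in
    (mild, no formal care), the community-dwelling early-stage population the
    exemplar technologies target.  A dict maps serialized state names to mass.
    """
    if mass is None:
        init = np.zeros(N_STATES)
        init[state_index(Severity.MILD, CareSetting.NO_FORMAL_CARE)] = 1.0
        return init
    if isinstance(mass, dict):
        init = np.zeros(N_STATES)
        for name, m in mass.items():
            if name not in STATE_INDEX_BY_NAME:
                raise ValueError(f"unknown state name {name!r}")
            init[STATE_INDEX_BY_NAME[name]] = m
    else:
        init = np.asarray(mass, dtype=float)
        if init.shape != (N_STATES,):
            raise ValueError(f"initial distribution must have shape ({N_STATES},)")
    if np.any(init < 0):
        raise ValueError("initial distribution has negative mass")
    if init[DEATH_INDEX] != 0.0:
        raise ValueError("initial distribution must place no mass on death")
    if abs(init.sum() - 1.0) > 1e-12:
        raise ValueError(f"initial distribution sums to {init.sum()}, not 1")
    return init


def _as_array(matrix: MatrixLike) -> np.ndarray:
    m = matrix.entries if isinstance(matrix, CycleMatrix) else np.asarray(matrix, float)
    if m.shape != (N_STATES, N_STATES):
        raise ValueError(f"cycle matrix must be {N_STATES}x{N_STATES}, got {m.shape}")
    return m


def run_cohort(
    matrices: MatrixSource,
    init: np.ndarray,
    n_cycles: int,
    cycle_length: float = 1.0 / 12.0,
    extinction_threshold: float | None = None,
) -> CohortTrace:
    """Propagate the cohort: ``occupancy[t+1] = occupancy[t] @ matrix[t]``.

    Parameters
    ----------
    matrices
        A single matrix (time-invariant), a sequence of length ``n_cycles``,
        or a callable ``t -> matrix`` (supports effect persistence/waning).
    init
        Initial distribution over the 10 states (validated).
    n_cycles
        Maximum number of cycles (>= 1).
    extinction_threshold
        If set, stop early once living mass drops below it ("lifetime"
        horizon realized as fixed maximum plus convergence stop).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    init = initial_distribution(init) if not isinstance(init, np.ndarray) else init
    if init.shape != (N_STATES,):
        raise ValueError(f"init must have shape ({N_STATES},)")

    if callable(matrices) and not isinstance(matrices, (CycleMatrix, np.ndarray)):
        get = lambda t: _as_array(matrices(t))  # noqa: E731
    elif isinstance(matrices, (CycleMatrix, np.ndarray)):
        m_const = _as_array(matrices)
        get = lambda t: m_const  # noqa: E731
    else:
        seq = [_as_array(m) for m in matrices]
        if len(seq) < n_cycles:
            raise ValueError(
                f"need {n_cycles} matrices, got {len(seq)}"
            )
        get = lambda t: seq[t]  # noqa: E731

    rows = [init]
    x = init
    for t in range(n_cycles):
        x = x @ get(t)
        rows.append(x)
        if (
            extinction_threshold is not None
            and x[:N_LIVING].sum() < extinction_threshold
        ):
            break
    return CohortTrace(occupancy=np.vstack(rows), cycle_length=cycle_length)


def _discount_factors(
    n_cycles: int, discount_rate: float, cycle_length: float
) -> np.ndarray:
    """Discount factor for cycles t = 1..n: (1 + r)^(-t * cycle_length)."""
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    t = np.arange(1, n_cycles + 1)
    return (1.0 + discount_rate) ** (-t * cycle_length)


def accumulate_stream(
    trace: CohortTrace,
    per_boundary: np.ndarray,
    discount_rate: float = 0.0,
    half_cycle: bool = False,
) -> float:
    """Accumulate a per-boundary annualized stream over the trace.

    Without half-cycle correction cycle ``t``'s contribution is the stream at
    boundary ``t``; with it, the trapezoid of boundaries ``t-1`` and ``t``.
    Each contribution is scaled by cycle length and discounted at cycle ``t``.
    """
    per_boundary = np.asarray(per_boundary, dtype=float)
    n = trace.n_cycles
    disc = _discount_factors(n, discount_rate, trace.cycle_length)
    if half_cycle:
        per_cycle = 0.5 * (per_boundary[:-1] + per_boundary[1:])
    else:
        per_cycle = per_boundary[1:]
    return float(np.sum(per_cycle * disc) * trace.cycle_length)


def life_years(
    trace: CohortTrace,
    half_cycle: bool = True,
    discount_rate: float = 0.0,
) -> float:
    """Total (discounted) life-years lived by the cohort over the trace."""
    return accumulate_stream(trace, trace.living_mass, discount_rate, half_cycle)


def _selector_to_indices(selector) -> list[int]:
    if isinstance(selector, Severity):
        return [state_index(selector, c) for c in CareSetting]
    if isinstance(selector, CareSetting):
        return [state_index(s, selector) for s in Severity]
    if isinstance(selector, tuple) and len(selector) == 2:
        return [state_index(selector[0], selector[1])]
    if isinstance(selector, str):
        if selector == "living":
            return list(range(N_LIVING))
        if selector in STATE_INDEX_BY_NAME and selector != "death":
            return [STATE_INDEX_BY_NAME[selector]]
        raise ValueError(f"unknown state selector {selector!r}")
    if isinstance(selector, (int, np.integer)):
        if not 0 <= int(selector) < N_LIVING:
            raise ValueError(f"living-state index out of range: {selector}")
        return [int(selector)]
    try:
        return [i for s in selector for i in _selector_to_indices(s)]
    except TypeError:
        raise ValueError(f"unknown state selector {selector!r}") from None


def time_in_state(
    trace: CohortTrace,
    selector,
    half_cycle: bool = True,
    discount_rate: float = 0.0,
) -> float:
    """Years spent in the selected living state(s).

    ``selector`` may be a single ``(Severity, CareSetting)`` pair, a state
    name, a :class:`Severity` (slice over care settings), a
    :class:`CareSetting` (slice over severities), ``"living"`` for all living
    states, or an iterable of any of these.  Summed over all living states
    this equals :func:`life_years` under the same conventions.
    """
    idx = sorted(set(_selector_to_indices(selector)))
    stream = trace.occupancy[:, idx].sum(axis=1)
    return accumulate_stream(trace, stream, discount_rate, half_cycle)


def n_cycles_for_horizon(horizon_years: float, cycle_length: float) -> int:
    """Number of whole cycles covering the horizon (at least 1)."""
    return max(1, int(round(horizon_years / cycle_length)))
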