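"""State space and per-cycle transition matrix assembly.

The model tracks a dementia cohort over a 3x3 grid of disease severity
(mild, moderate, severe) by care setting (no formal care, home care,
institutional care), plus one absorbing death state: 10 states in total.

Transitions factor into three conditional components supplied per cycle:

* severity progression (stepwise, mild -> moderate -> severe, no regression),
* care-setting transitions conditional on severity (forward moves and forward
  skips allowed; reversals structurally zero unless ``allow_care_reversal``),
* death, conditional on both severity and care setting.

Within a cycle the components compose as: death is resolved first, survivors
progress in severity, and care transitions condition on the START-of-cycle
severity.  The joint probability of moving from living state (s, c) to
(s', c') in one cycle is therefore

    (1 - p_death(s, c)) * P_sev(s -> s') * P_care(c -> c' | s)

and the probability of dying is ``p_death(s, c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "Severity",
    "CareSetting",
    "StateSpace",
    "BaselineParameters",
    "CycleMatrix",
    "ValidationReport",
    "enumerate_states",
    "state_name",
    "state_index",
    "build_cycle_matrix",
    "validate_parameters",
    "N_LIVING",
    "N_STATES",
    "DEATH_INDEX",
    "STATE_NAMES",
]


class Severity(IntEnum):
    """Dementia severity stage; totally ordered mild < moderate < severe."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2

    @property
    def label(self) -> str:
        return self.name.lower()


class CareSetting(IntEnum):
    """Care setting; ordered by intensity: none < home care < institutional."""

    NO_FORMAL_CARE = 0
    HOME_CARE = 1
    INSTITUTIONAL_CARE = 2

    @property
    def label(self) -> str:
        return self.name.lower()


N_LIVING = 9
N_STATES = 10
DEATH_INDEX = 9


def state_name(severity: Severity, care: CareSetting) -> str:
    return f"{severity.label}|{care.label}"


def state_index(severity: Severity, care: CareSetting) -> int:
    """Canonical index of a living state: severity-major, care-minor."""
    return int(severity) * 3 + int(care)


@dataclass(frozen=True)
class StateSpace:
    """The 9 living (severity, care) states plus absorbing death, in canonical
    severity-major order; death is always the last index."""

    living_states: tuple[tuple[Severity, CareSetting], ...]
    death_index: int = DEATH_INDEX

    @property
    def names(self) -> list[str]:
        return [state_name(s, c) for s, c in self.living_states] + ["death"]

    @property
    def size(self) -> int:
        return len(self.living_states) + 1

    def index(self, severity: Severity, care: CareSetting) -> int:
        return state_index(severity, care)


def enumerate_states() -> StateSpace:
    """Enumerate the canonical state space (stable across calls)."""
    living = tuple((s, c) for s in Severity for c in CareSetting)
    return StateSpace(living_states=living)


STATE_NAMES = enumerate_states().names

#: map from serialized state name to canonical index (death included)
STATE_INDEX_BY_NAME = {n: i for i, n in enumerate(STATE_NAMES)}


@dataclass
class BaselineParameters:
    """Usual-care per-cycle transition probabilities.

    Attributes
    ----------
    p_progress : ndarray, shape (2,)
        Per-cycle probability of the severity steps mild->moderate and
        moderate->severe.  Skips (mild->severe in one cycle) are structurally
        zero; severity never regresses.
    p_care : ndarray, shape (3, 3, 3)
        ``p_care[s, c, c']`` is the per-cycle probability of moving from care
        setting ``c`` to ``c'`` given start-of-cycle severity ``s``.  The
        diagonal must be zero (staying is the residual); entries below the
        diagonal (care reversals) must be zero unless ``allow_care_reversal``.
    p_death : ndarray, shape (3, 3)
        ``p_death[s, c]``: per-cycle death probability by severity and care.
    cycle_length : float
        Cycle duration in years.  All probabilities are per cycle; no rate
        rescaling is applied to inputs.
    allow_care_reversal : bool
        Permit non-zero care-reversal probabilities (off by default).
    """

    p_progress: np.ndarray
    p_care: np.ndarray
    p_death: np.ndarray
    cycle_length: float = 1.0 / 12.0
    allow_care_reversal: bool = False

    def __post_init__(self) -> None:
        self.p_progress = np.asarray(self.p_progress, dtype=float)
        self.p_care = np.asarray(self.p_care, dtype=float)
        self.p_death = np.asarray(self.p_death, dtype=float)

    def copy(self) -> "BaselineParameters":
        return replace(
            self,
            p_progress=self.p_progress.copy(),
            p_care=self.p_care.copy(),
            p_death=self.p_death.copy(),
        )


@dataclass(frozen=True)
class CycleMatrix:
    """A 10x10 row-stochastic one-cycle transition matrix."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=float))


@dataclass
class ValidationReport:
    ok: bool = True
    messages: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.ok = False
        self.messages.append(message)

    def __bool__(self) -> bool:
        return self.ok


def validate_parameters(params: BaselineParameters) -> ValidationReport:
    """Check all structural invariants; a passing report guarantees that
    :func:`build_cycle_matrix` produces a valid row-stochastic matrix."""
    report = ValidationReport()

    if params.p_progress.shape != (2,):
        report.add(f"p_progress must have shape (2,), got {params.p_progress.shape}")
        return report
    if params.p_care.shape != (3, 3, 3):
        report.add(f"p_care must have shape (3, 3, 3), got {params.p_care.shape}")
        return report
    if params.p_death.shape != (3, 3):
        report.add(f"p_death must have shape (3, 3), got {params.p_death.shape}")
        return report
    if not params.cycle_length > 0:
        report.add(f"cycle_length must be positive, got {params.cycle_length}")

    steps = ["mild->moderate", "moderate->severe"]
    for i, label in enumerate(steps):
        p = params.p_progress[i]
        if not 0.0 <= p <= 1.0:
            report.add(f"p_progress[{label}] = {p} outside [0, 1]")

    for s in Severity:
        for c in CareSetting:
            p = params.p_death[s, c]
            if not 0.0 <= p <= 1.0:
                report.add(f"p_death[{s.label}, {c.label}] = {p} outside [0, 1]")

    for s in Severity:
        for c_from in CareSetting:
            for c_to in CareSetting:
                p = params.p_care[s, c_from, c_to]
                if c_from == c_to:
                    if p != 0.0:
                        report.add(
                            f"p_care[{s.label}, {c_from.label}->{c_to.label}]: "
                            "diagonal must be 0 (staying is the residual)"
                        )
                    continue
                if not 0.0 <= p <= 1.0:
                    report.add(
                        f"p_care[{s.label}, {c_from.label}->{c_to.label}] = {p} "
                        "outside [0, 1]"
                    )
                if c_to < c_from and not params.allow_care_reversal and p != 0.0:
                    report.add(
                        f"p_care[{s.label}, {c_from.label}->{c_to.label}] = {p}: "
                        "care reversal disallowed (allow_care_reversal is off)"
                    )
            row_out = params.p_care[s, c_from].sum()
            if row_out > 1.0 + 1e-12:
                report.add(
                    f"p_care[{s.label}, from {c_from.label}]: outgoing "
                    f"probabilities sum to {row_out} > 1"
                )
    return report


def _severity_kernel(params: BaselineParameters) -> np.ndarray:
    """3x3 stepwise severity-progression kernel (no skips, no regression)."""
    k = np.zeros((3, 3))
    k[0, 0] = 1.0 - params.p_progress[0]
    k[0, 1] = params.p_progress[0]
    k[1, 1] = 1.0 - params.p_progress[1]
    k[1, 2] = params.p_progress[1]
    k[2, 2] = 1.0
    return k


def _care_kernel(params: BaselineParameters, severity: Severity) -> np.ndarray:
    """3x3 care-transition kernel for a given start-of-cycle severity; the
    diagonal is the residual stay probability."""
    k = params.p_care[severity].copy()
    np.fill_diagonal(k, 1.0 - k.sum(axis=1))
    return k


def build_cycle_matrix(params: BaselineParameters) -> CycleMatrix:
    """Assemble the 10x10 one-cycle matrix from the conditional components.

    Raises
    ------
    ValueError
        If ``params`` fails :func:`validate_parameters`.
    """
    report = validate_parameters(params)
    if not report:
        raise ValueError(
            "invalid baseline parameters:\n  " + "\n  ".join(report.messages)
        )

    sev_k = _severity_kernel(params)
    m = np.zeros((N_STATES, N_STATES))
    for s in Severity:
        care_k = _care_kernel(params, s)
        for c in CareSetting:
            i = state_index(s, c)
            p_die = params.p_death[s, c]
            m[i, DEATH_INDEX] = p_die
            for s2 in Severity:
                for c2 in CareSetting:
                    m[i, state_index(s2, c2)] = (
                        (1.0 - p_die) * sev_k[s, s2] * care_k[c, c2]
                    )
    m[DEATH_INDEX, DEATH_INDEX] = 1.0
    return CycleMatrix(entries=m)
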