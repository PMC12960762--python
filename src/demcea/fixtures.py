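"""Synthetic, structurally valid model inputs for testing and demos.

No empirical parameter table exists for this model; the generator emulates
the qualitative structure of the dementia care pathway instead — utility
declines with severity, costs rise steeply toward institutional care,
mortality and care escalation increase with severity — with seeded jitter
so that every seed yields a distinct but valid parameter set.  All default
magnitudes are ILLUSTRATIVE; they are not estimates from any study.

Monotone orderings are preserved under jitter by drawing one jitter factor
per base quantity (shared across the graded dimension), never one per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .config import ModelConfig, validate_config
from .states import (
    BaselineParameters,
    CareSetting,
    Severity,
    state_name,
)
from .surrogate import SurrogateEffect
from .valuation import StateValues

__all__ = [
    "FixtureSpec",
    "generate_parameter_set",
    "generate_pilot_effects",
    "fixture_config",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic generator (all gradient strengths >= 0).

    ``utility_decline`` is the utility drop per severity step;
    ``care_utility_drop`` per care-intensity step.  ``mortality_rise`` and
    ``care_escalation`` scale how steeply death risk and care-transition
    probabilities grow with severity (per-step multiplier ``1 + strength``).
    ``cost_rise`` scales the care-setting cost gradient.  Pilot effects are
    scaled by ``pilot_effect_scale`` (0 = null pilot) with standard errors
    scaled by ``pilot_se_scale``.
    """

    seed: int = 0
    utility_decline: float = 0.20
    care_utility_drop: float = 0.03
    cost_rise: float = 1.0
    mortality_rise: float = 1.0
    care_escalation: float = 1.0
    pilot_effect_scale: float = 1.0
    pilot_se_scale: float = 1.0
    jitter: float = 0.08

    def __post_init__(self) -> None:
        for name in ("utility_decline", "care_utility_drop", "cost_rise",
                     "mortality_rise", "care_escalation", "pilot_effect_scale",
                     "pilot_se_scale", "jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# illustrative per-cycle (monthly) base rates and annual values
_P_PROGRESS = np.array([0.015, 0.020])  # mild->moderate, moderate->severe
_P_CARE_BASE = {  # from -> to, mild-severity base probability per month
    (CareSetting.NO_FORMAL_CARE, CareSetting.HOME_CARE): 0.010,
    (CareSetting.NO_FORMAL_CARE, CareSetting.INSTITUTIONAL_CARE): 0.002,
    (CareSetting.HOME_CARE, CareSetting.INSTITUTIONAL_CARE): 0.006,
}
_P_DEATH_BASE = np.array([0.002, 0.003, 0.006])  # by care setting, mild severity
_FORMAL_COST_CARE_GRADIENT = np.array([0.0, 13200.0, 64200.0])  # EUR/yr above base
_FORMAL_COST_FLOOR = 800.0
_INFORMAL_HOURS = np.array(  # hours/week by (severity, care)
    [[15.0, 10.0, 1.0], [25.0, 18.0, 2.0], [35.0, 26.0, 3.0]]
)
_CAREGIVER_DELTA = np.array(  # caregiver utility delta by (severity, care)
    [[-0.02, -0.03, -0.01], [-0.04, -0.05, -0.02], [-0.07, -0.08, -0.03]]
)
_UNIT_WAGE = 15.0


def _jitter_factor(rng: np.random.Generator, half_width: float) -> float:
    return 1.0 + half_width * rng.uniform(-1.0, 1.0)


def generate_parameter_set(
    spec: FixtureSpec,
) -> tuple[BaselineParameters, StateValues]:
    """Generate a valid (parameters, values) pair; deterministic per seed.

    Guarantees (at positive gradient strengths): patient utility strictly
    decreasing in severity at fixed care; total annual cost strictly
    increasing in care intensity at fixed severity; death risk and
    institutional-admission risk non-decreasing in severity.
    """
    rng = np.random.default_rng(spec.seed)
    j = spec.jitter

    p_progress = _P_PROGRESS * np.array(
        [_jitter_factor(rng, j), _jitter_factor(rng, j)]
    )

    sev_care_mult = (1.0 + spec.care_escalation) ** np.arange(3)
    p_care = np.zeros((3, 3, 3))
    for (c_from, c_to), base in _P_CARE_BASE.items():
        f = _jitter_factor(rng, j)  # one factor per transition type
        for s in Severity:
            p_care[s, c_from, c_to] = base * f * sev_care_mult[s]

    sev_death_mult = (1.0 + spec.mortality_rise) ** np.arange(3)
    p_death = np.zeros((3, 3))
    for c in CareSetting:
        f = _jitter_factor(rng, j)  # one factor per care setting
        p_death[:, c] = _P_DEATH_BASE[c] * f * sev_death_mult

    base_utility = 0.85 * _jitter_factor(rng, j / 2)
    decline = spec.utility_decline * _jitter_factor(rng, j / 2)
    care_drop = spec.care_utility_drop * _jitter_factor(rng, j / 2)
    cost_f = _jitter_factor(rng, j)
    wage = _UNIT_WAGE * _jitter_factor(rng, j)

    n = 9
    patient_utility = np.zeros(n)
    caregiver_delta = np.zeros(n)
    formal_cost = np.zeros(n)
    informal_hours = np.zeros(n)
    for s in Severity:
        for c in CareSetting:
            i = s * 3 + c
            patient_utility[i] = base_utility - decline * s - care_drop * c
            caregiver_delta[i] = _CAREGIVER_DELTA[s, c]
            formal_cost[i] = (
                _FORMAL_COST_FLOOR * (1.0 + 0.15 * s)
                + _FORMAL_COST_CARE_GRADIENT[c] * spec.cost_rise * cost_f
            )
            informal_hours[i] = _INFORMAL_HOURS[s, c]

    params = BaselineParameters(
        p_progress=np.clip(p_progress, 0.0, 1.0),
        p_care=np.clip(p_care, 0.0, 1.0),
        p_death=np.clip(p_death, 0.0, 1.0),
        cycle_length=1.0 / 12.0,
    )
    values = StateValues(
        patient_utility=np.clip(patient_utility, -1.0, 1.0),
        caregiver_utility_delta=caregiver_delta,
        formal_cost=formal_cost,
        informal_hours=informal_hours,
        unit_wage=wage,
    )
    return params, values


#: pilot outcomes emitted by the generator; admission_risk effects are on
#: the log-RR scale so a zero effect is always the null
_PILOT_TEMPLATE = [
    # (outcome, effect, se)
    ("utility", 0.02, 0.010),
    ("caregiving_hours", -2.0, 0.8),
    ("resource_use", -400.0, 200.0),
    ("admission_risk", float(np.log(0.85)), 0.10),
    ("ADCS-ADL", 1.5, 0.7),
    ("behavioral_symptoms", -1.2, 0.6),
    ("caregiver_burden", -2.0, 1.0),
]


def generate_pilot_effects(spec: FixtureSpec) -> list[SurrogateEffect]:
    """Seeded pilot-study effect estimates for every implemented outcome.

    Effect sizes scale with ``pilot_effect_scale`` (0 gives all-zero
    effects), SEs with ``pilot_se_scale``; follow-up lengths are drawn
    uniformly from 2-12 weeks, the short pilot horizon this evidence
    tier is expected to have.
    """
    rng = np.random.default_rng(spec.seed + 1)
    effects = []
    for outcome, effect, se in _PILOT_TEMPLATE:
        effects.append(
            SurrogateEffect(
                outcome=outcome,
                effect=effect * spec.pilot_effect_scale,
                se=se * spec.pilot_se_scale,
                follow_up_weeks=float(rng.integers(2, 13)),
            )
        )
    return effects


def fixture_config(spec: FixtureSpec | None = None) -> ModelConfig:
    """A complete, validated exemplar configuration document.

    Ships one community technology strategy whose evidence enters through
    compatible pathways (caregiving hours directly; ADCS-ADL via the
    utility link; caregiver burden via the institutionalization link), plus
    illustrative PSA priors, tornado ranges, and a best/worst-case scenario
    pair over surrogate validity and persistence.
    """
    spec = spec or FixtureSpec()
    params, values = generate_parameter_set(spec)
    sev_labels = [s.label for s in Severity]
    care_labels = [c.label for c in CareSetting]

    p_care: dict[str, dict[str, dict[str, float]]] = {}
    for s in Severity:
        rows: dict[str, dict[str, float]] = {}
        for c_from in CareSetting:
            dests = {
                care_labels[c_to]: float(params.p_care[s, c_from, c_to])
                for c_to in CareSetting
                if params.p_care[s, c_from, c_to] > 0
            }
            if dests:
                rows[care_labels[c_from]] = dests
        p_care[sev_labels[s]] = rows

    state_entries = {}
    for s in Severity:
        for c in CareSetting:
            i = s * 3 + c
            state_entries[state_name(s, c)] = {
                "patient_utility": float(values.patient_utility[i]),
                "caregiver_utility_delta": float(values.caregiver_utility_delta[i]),
                "formal_cost": float(values.formal_cost[i]),
                "informal_hours": float(values.informal_hours[i]),
            }

    scale, se_scale = spec.pilot_effect_scale, spec.pilot_se_scale
    p_home_inst_moderate = float(params.p_care[1, 1, 2])
    doc: dict[str, Any] = {
        "schema_version": 1,
        "model": {"cycle_length_years": 1.0 / 12.0},
        "transitions": {
            "p_progress": {
                "mild_to_moderate": float(params.p_progress[0]),
                "moderate_to_severe": float(params.p_progress[1]),
            },
            "p_care": p_care,
            "p_death": {
                sev_labels[s]: {
                    care_labels[c]: float(params.p_death[s, c])
                    for c in CareSetting
                }
                for s in Severity
            },
        },
        "values": {"unit_wage": float(values.unit_wage), "states": state_entries},
        "initial_distribution": {"mild|no_formal_care": 1.0},
        "surrogate": {
            "direct_qol_measured": False,
            "links": {
                "ADCS-ADL": {
                    "pathway": "to_utility",
                    "coefficient": 0.008,
                    "citation": "functional ability to utility, literature-derived",
                },
                "caregiver_burden": {
                    "pathway": "to_transition",
                    "coefficient": 0.08,
                    "target": "home_care->institutional_care",
                    "citation": "burden to institutionalization risk, ILLUSTRATIVE",
                },
            },
        },
        "strategies": {
            "community_technology": {
                "eligibility": [
                    "mild|no_formal_care",
                    "mild|home_care",
                    "moderate|no_formal_care",
                    "moderate|home_care",
                ],
                "persistence_cycles": 24,
                "intervention_cost_per_year": 1200.0,
                "pilot_effects": [
                    {"outcome": "caregiving_hours", "effect": -2.0 * scale,
                     "se": 0.8 * se_scale, "follow_up_weeks": 8},
                    {"outcome": "ADCS-ADL", "effect": 1.5 * scale,
                     "se": 0.7 * se_scale, "follow_up_weeks": 8},
                    {"outcome": "caregiver_burden", "effect": -2.0 * scale,
                     "se": 1.0 * se_scale, "follow_up_weeks": 10},
                ],
            }
        },
        "analysis": {"seed": int(spec.seed) if spec.seed else 12345},
        "psa": {
            "n": 500,
            "priors": [
                {"path": "transitions.p_death.moderate.home_care",
                 "family": "beta",
                 "mean": float(params.p_death[1, 1]),
                 "se": 0.2 * float(params.p_death[1, 1])},
                {"path": "transitions.p_care.mild.home_care.institutional_care",
                 "family": "beta",
                 "mean": float(params.p_care[0, 1, 2]),
                 "se": 0.3 * float(params.p_care[0, 1, 2])},
                {"path": "values.states.mild|home_care.formal_cost",
                 "family": "gamma",
                 "mean": float(values.formal_cost[1]),
                 "se": 0.15 * float(values.formal_cost[1])},
                {"path": "surrogate.links.caregiver_burden.coefficient",
                 "family": "lognormal", "mean": 0.08, "se": 0.03},
                {"path": "transitions.p_care.moderate.home_care",
                 "family": "dirichlet",
                 "counts": [(1.0 - p_home_inst_moderate) * 200.0,
                            p_home_inst_moderate * 200.0],
                 "keys": ["institutional_care"]},
            ],
        },
        "tornado": {
            "wtp": 50000.0,
            "ranges": [
                {"path": "transitions.p_death.moderate.home_care",
                 "low": 0.5 * float(params.p_death[1, 1]),
                 "high": 1.5 * float(params.p_death[1, 1])},
                {"path": "surrogate.links.ADCS-ADL.coefficient",
                 "low": 0.0, "high": 0.016},
                {"path": "strategies.community_technology.intervention_cost_per_year",
                 "low": 600.0, "high": 2400.0},
            ],
        },
        "scenarios": {
            "best_case": {
                "surrogate.links.ADCS-ADL.coefficient": 0.012,
                "surrogate.links.caregiver_burden.coefficient": 0.12,
                "strategies.community_technology.persistence_cycles": 48,
            },
            "worst_case": {
                "surrogate.links.ADCS-ADL.coefficient": 0.0,
                "surrogate.links.caregiver_burden.coefficient": 0.0,
                "strategies.community_technology.pilot_effects.0.effect": 0.0,
            },
        },
    }
    return validate_config(doc)
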