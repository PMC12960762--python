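"""Translating short-term pilot effects into model effects.

Early pilot studies of care technologies report short-term (2-12 week)
effects on outcomes close to the intervention's mechanism.  Two routes bring
such evidence into the model:

* **Direct application** — outcomes that already are model quantities
  (utility, caregiving hours/week, formal resource use, admission risk)
  become effects verbatim.
* **Surrogate translation** — other outcomes (e.g., ADCS-ADL function
  scores, caregiver burden, behavioral symptoms) are mapped onto model
  parameters through literature-derived links: utility per point,
  hours per point, or log-RR per point on a care transition.

Because a surrogate can plausibly feed several parameters, assembling a
strategy is guarded against double-counting: a direct quality-of-life
measurement excludes any surrogate-to-utility link, and no single outcome
may feed both the utility and the transition pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .intervention import (
    CareTransition,
    StateValueEffect,
    Strategy,
    TransitionEffect,
)
from .states import CareSetting

__all__ = [
    "SurrogateEffect",
    "SurrogateLink",
    "PathwayRegistry",
    "DIRECT_OUTCOMES",
    "ADCS_ADL_UTILITY_LINK",
    "DEFAULT_LINKS",
    "translate",
    "check_double_counting",
    "assemble_strategy",
]

#: outcomes that map onto model quantities without a surrogate link;
#: admission_risk effect sizes are log relative risks (0 = null effect)
DIRECT_OUTCOMES = {
    "utility": ("value", "patient_utility"),
    "caregiving_hours": ("value", "informal_hours"),
    "resource_use": ("value", "formal_cost"),
    "admission_risk": ("transition", None),
}

PATHWAYS = ("to_utility", "to_transition", "to_care_hours")


@dataclass(frozen=True)
class SurrogateEffect:
    """A pilot-study effect estimate on a named outcome.

    ``effect`` is signed, in the outcome's own units (for ``admission_risk``
    it is a relative risk); ``se`` is the standard error in the same units;
    ``follow_up_weeks`` is the pilot follow-up length.
    """

    outcome: str
    effect: float
    se: float | None = None
    follow_up_weeks: float = 8.0

    def __post_init__(self) -> None:
        if not self.follow_up_weeks > 0:
            raise ValueError("follow_up_weeks must be > 0")
        if self.se is not None and self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass(frozen=True)
class SurrogateLink:
    """A literature-derived mapping from a surrogate outcome to a model
    parameter: one pathway, one per-unit coefficient, a citation label.

    ``coefficient`` is utility/point (``to_utility``), hours-per-week/point
    (``to_care_hours``), or log-RR/point on ``target`` (``to_transition``).
    """

    outcome: str
    pathway: str
    coefficient: float
    target: CareTransition | None = None
    citation: str = ""

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if not math.isfinite(self.coefficient):
            raise ValueError("link coefficient must be finite")
        if self.pathway == "to_transition" and self.target is None:
            raise ValueError("to_transition link needs a target care transition")
        if self.pathway != "to_transition" and self.target is not None:
            raise ValueError(f"{self.pathway} link must not carry a transition target")


#: default exemplar link: one ADCS-ADL point corresponds to 0.008 utility
ADCS_ADL_UTILITY_LINK = SurrogateLink(
    outcome="ADCS-ADL",
    pathway="to_utility",
    coefficient=0.008,
    citation="functional ability (ADCS-ADL) to utility mapping, literature-derived",
)

DEFAULT_LINKS: tuple[SurrogateLink, ...] = (ADCS_ADL_UTILITY_LINK,)


@dataclass
class PathwayRegistry:
    """Which (outcome, pathway) pairs a strategy enables, plus whether
    quality of life was measured directly in the pilot."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    direct_qol_measured: bool = False


def translate(
    effect: SurrogateEffect, link: SurrogateLink
) -> TransitionEffect | StateValueEffect:
    """Map a pilot effect through a surrogate link into a model effect.

    Linear in effect size for the value pathways (delta = effect x
    coefficient); log-linear for transitions (rr = exp(effect x log-RR/unit),
    so rr(e1 + e2) = rr(e1) * rr(e2)).
    """
    if effect.outcome != link.outcome:
        raise ValueError(
            f"outcome mismatch: effect is {effect.outcome!r}, link is "
            f"{link.outcome!r}"
        )
    if link.pathway == "to_utility":
        return StateValueEffect("patient_utility", effect.effect * link.coefficient)
    if link.pathway == "to_care_hours":
        return StateValueEffect("informal_hours", effect.effect * link.coefficient)
    return TransitionEffect(link.target, math.exp(effect.effect * link.coefficient))


def check_double_counting(registry: PathwayRegistry) -> list[str]:
    """Return double-counting violations (empty list = ok).

    (a) direct quality-of-life measurement plus any surrogate-to-utility
    link duplicates the utility effect; (b) the same outcome feeding both
    the utility and the transition pathway conflates causal pathways.
    Outcomes feeding only ``to_transition`` are always fine.
    """
    violations: list[str] = []
    if registry.direct_qol_measured:
        for outcome, pathway in sorted(registry.pairs):
            if pathway == "to_utility":
                violations.append(
                    f"quality of life is directly measured; the {outcome!r} "
                    "to_utility link would double-count the utility effect"
                )
    by_outcome: dict[str, set[str]] = {}
    for outcome, pathway in registry.pairs:
        by_outcome.setdefault(outcome, set()).add(pathway)
    for outcome, pathways in sorted(by_outcome.items()):
        if "to_utility" in pathways and "to_transition" in pathways:
            violations.append(
                f"outcome {outcome!r} feeds both the utility and the "
                "transition pathway (double-counting)"
            )
    return violations


def _direct_effect(effect: SurrogateEffect) -> TransitionEffect | StateValueEffect:
    kind, stream = DIRECT_OUTCOMES[effect.outcome]
    if kind == "value":
        return StateValueEffect(stream, effect.effect)
    # admission risk: the pilot estimate is a log relative risk on
    # home -> institutional placement (so 0 is the null)
    return TransitionEffect(
        CareTransition(CareSetting.HOME_CARE, CareSetting.INSTITUTIONAL_CARE),
        math.exp(effect.effect),
    )


def assemble_strategy(
    pilot_effects: list[SurrogateEffect],
    links: list[SurrogateLink],
    registry: PathwayRegistry,
    persistence_cycles: int,
    eligibility: frozenset[int],
    intervention_cost: float = 0.0,
    name: str = "intervention",
    waning: str = "none",
    waning_cycles: int = 0,
) -> Strategy:
    """Build a fully-formed strategy from pilot evidence.

    Directly-applicable outcomes bypass links; every other outcome must pass
    through a link whose (outcome, pathway) pair the registry enables.
    Multiple transition effects landing on the same transition simply stack
    in the effect list — sequential application of the rate transform makes
    their relative risks compose multiplicatively.
    """
    violations = check_double_counting(registry)
    if violations:
        raise ValueError("double-counting violations:\n  " + "\n  ".join(violations))

    by_outcome = {link.outcome: link for link in links}
    effects: list[TransitionEffect | StateValueEffect] = []
    for effect in pilot_effects:
        if effect.effect == 0.0:
            continue
        if effect.outcome in DIRECT_OUTCOMES:
            effects.append(_direct_effect(effect))
            continue
        link = by_outcome.get(effect.outcome)
        if link is None:
            raise ValueError(
                f"surrogate outcome {effect.outcome!r} has no link and is not "
                "directly applicable"
            )
        if (link.outcome, link.pathway) not in registry.pairs:
            raise ValueError(
                f"link pathway ({link.outcome!r}, {link.pathway!r}) is not "
                "enabled in the registry"
            )
        effects.append(translate(effect, link))

    return Strategy(
        name=name,
        effects=effects,
        eligibility=eligibility,
        persistence_cycles=persistence_cycles,
        waning=waning,
        waning_cycles=waning_cycles,
        intervention_cost=intervention_cost,
    )
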