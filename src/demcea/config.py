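"""Declarative model configuration: schema, loading, dumping, overrides.

One structured document (YAML accepted, JSON canonical) carries every model
input: transition probabilities, state values, strategies (direct effects
and/or pilot effects with surrogate links), and analysis settings.  The
schema is strict — unknown keys are rejected and violations are reported
with the path to the offending field — and the dotted paths into this
document are also the parameter-addressing scheme used by the sensitivity
machinery (PSA priors, tornado ranges, scenario overrides).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Literal, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .intervention import (
    CareTransition,
    StateValueEffect,
    Strategy,
    TransitionEffect,
)
from .states import (
    BaselineParameters,
    CareSetting,
    Severity,
    STATE_INDEX_BY_NAME,
    STATE_NAMES,
    validate_parameters,
)
from .surrogate import (
    PathwayRegistry,
    SurrogateEffect,
    SurrogateLink,
    assemble_strategy,
)
from .valuation import StateValues, validate_values

__all__ = [
    "ModelConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "apply_overrides",
    "get_config_value",
    "to_baseline_parameters",
    "to_state_values",
    "to_strategy",
    "to_initial_distribution",
]

SEVERITY_LABELS = [s.label for s in Severity]
CARE_LABELS = [c.label for c in CareSetting]
LIVING_STATE_NAMES = STATE_NAMES[:-1]

_SEVERITY_BY_LABEL = {s.label: s for s in Severity}
_CARE_BY_LABEL = {c.label: c for c in CareSetting}


class ConfigError(ValueError):
    """A configuration document failed to parse or validate."""


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Base):
    cycle_length_years: float = Field(default=1.0 / 12.0, gt=0)
    allow_care_reversal: bool = False
    currency: str = "EUR"


class ProgressConfig(_Base):
    mild_to_moderate: float = Field(ge=0, le=1)
    moderate_to_severe: float = Field(ge=0, le=1)


class TransitionsConfig(_Base):
    """Per-cycle probabilities; p_care is severity -> from-setting ->
    to-setting -> probability (absent destinations are structural zeros)."""

    p_progress: ProgressConfig
    p_care: dict[str, dict[str, dict[str, float]]]
    p_death: dict[str, dict[str, float]]

    @model_validator(mode="after")
    def _check_labels(self) -> "TransitionsConfig":
        for sev in self.p_care:
            if sev not in SEVERITY_LABELS:
                raise ValueError(f"p_care: unknown severity {sev!r}")
            for c_from, dests in self.p_care[sev].items():
                if c_from not in CARE_LABELS:
                    raise ValueError(f"p_care.{sev}: unknown care setting {c_from!r}")
                for c_to in dests:
                    if c_to not in CARE_LABELS:
                        raise ValueError(
                            f"p_care.{sev}.{c_from}: unknown destination {c_to!r}"
                        )
        for sev, row in self.p_death.items():
            if sev not in SEVERITY_LABELS:
                raise ValueError(f"p_death: unknown severity {sev!r}")
            for care in row:
                if care not in CARE_LABELS:
                    raise ValueError(f"p_death.{sev}: unknown care setting {care!r}")
        return self


class StateValueEntry(_Base):
    patient_utility: float = Field(ge=-1, le=1)
    caregiver_utility_delta: float = Field(default=0.0, ge=-1, le=1)
    formal_cost: float = Field(default=0.0, ge=0)
    informal_hours: float = Field(default=0.0, ge=0)


class ValuesConfig(_Base):
    unit_wage: float = Field(ge=0)
    states: dict[str, StateValueEntry]

    @model_validator(mode="after")
    def _check_states(self) -> "ValuesConfig":
        missing = [n for n in LIVING_STATE_NAMES if n not in self.states]
        unknown = [n for n in self.states if n not in LIVING_STATE_NAMES]
        if missing:
            raise ValueError(f"values.states missing entries for {missing}")
        if unknown:
            raise ValueError(f"values.states has unknown state names {unknown}")
        return self


class TransitionEffectConfig(_Base):
    type: Literal["transition"] = "transition"
    target: str  # "home_care->institutional_care", optionally "|mild"
    rr: float = Field(gt=0)


class ValueEffectConfig(_Base):
    type: Literal["value"] = "value"
    stream: Literal[
        "patient_utility", "caregiver_utility_delta", "informal_hours", "formal_cost"
    ]
    delta: float
    states: Optional[list[str]] = None


EffectConfig = Union[TransitionEffectConfig, ValueEffectConfig]


class PilotEffectConfig(_Base):
    outcome: str
    effect: float
    se: Optional[float] = Field(default=None, ge=0)
    follow_up_weeks: float = Field(default=8.0, gt=0)


class StrategyConfig(_Base):
    eligibility: list[str] = Field(default_factory=list)
    persistence_cycles: int = Field(ge=0)
    waning: Literal["none", "linear"] = "none"
    waning_cycles: int = Field(default=0, ge=0)
    intervention_cost_per_year: float = Field(default=0.0, ge=0)
    effects: list[EffectConfig] = Field(default_factory=list)
    pilot_effects: list[PilotEffectConfig] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_states(self) -> "StrategyConfig":
        unknown = [n for n in self.eligibility if n not in LIVING_STATE_NAMES]
        if unknown:
            raise ValueError(f"eligibility has unknown state names {unknown}")
        return self


class LinkConfig(_Base):
    pathway: Literal["to_utility", "to_transition", "to_care_hours"]
    coefficient: float
    target: Optional[str] = None
    citation: str = ""


class SurrogateSection(_Base):
    direct_qol_measured: bool = False
    links: dict[str, LinkConfig] = Field(default_factory=dict)


class PriorConfig(_Base):
    path: str
    family: Literal["beta", "gamma", "lognormal", "dirichlet"]
    mean: Optional[float] = None
    se: Optional[float] = Field(default=None, ge=0)
    counts: Optional[list[float]] = None
    keys: Optional[list[str]] = None  # dirichlet destination keys (stay first)


class PSAConfig(_Base):
    n: int = Field(default=1000, ge=1)
    priors: list[PriorConfig] = Field(default_factory=list)


class TornadoRangeConfig(_Base):
    path: str
    low: float
    high: float


class TornadoConfig(_Base):
    wtp: float = 50000.0
    ranges: list[TornadoRangeConfig] = Field(default_factory=list)


class AnalysisConfig(_Base):
    horizon_years: float = Field(default=40.0, gt=0)
    discount_rate_effects: float = Field(default=0.015, ge=0)
    discount_rate_costs: float = Field(default=0.04, ge=0)
    half_cycle_correction: bool = True
    include_caregiver_qalys: bool = True
    wtp_grid: list[float] = Field(
        default_factory=lambda: [0.0, 20000.0, 50000.0, 80000.0, 100000.0]
    )
    wtp_reference: float = 50000.0
    extinction_threshold: float = Field(default=1e-8, ge=0)
    seed: int = Field(default=12345, ge=0)


class ModelConfig(_Base):
    """The full declarative model document (schema version 1)."""

    schema_version: int = 1
    model: ModelSection = Field(default_factory=ModelSection)
    transitions: TransitionsConfig
    values: ValuesConfig
    initial_distribution: Optional[dict[str, float]] = None
    surrogate: SurrogateSection = Field(default_factory=SurrogateSection)
    strategies: dict[str, StrategyConfig] = Field(default_factory=dict)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    psa: Optional[PSAConfig] = None
    tornado: Optional[TornadoConfig] = None
    scenarios: dict[str, dict[str, Any]] = Field(default_factory=dict)


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<document>"
        lines.append(f"{path}: {err['msg']}")
    return "\n".join(lines)


def load_config(path: str | Path) -> ModelConfig:
    """Load and schema-validate a YAML or JSON configuration file.

    Unknown keys are rejected; violations name the exact field path.
    Module-level invariants (probability ranges, row sums, state coverage)
    are also checked so a loaded config is ready to run.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: parse error: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: document must be a mapping")
    return validate_config(raw)


def validate_config(raw: dict[str, Any]) -> ModelConfig:
    """Validate a raw mapping into a :class:`ModelConfig`."""
    try:
        cfg = ModelConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc
    # cross-field invariants beyond the schema
    params = to_baseline_parameters(cfg)
    report = validate_parameters(params)
    if not report:
        raise ConfigError("transitions: " + "; ".join(report.messages))
    report = validate_values(to_state_values(cfg))
    if not report:
        raise ConfigError("values: " + "; ".join(report.messages))
    to_initial_distribution(cfg)
    for name in cfg.strategies:
        to_strategy(cfg, name)
    return cfg


def dump_config(cfg: ModelConfig, path: str | Path | None = None) -> str:
    """Serialize to canonical JSON (stable key order, 2-space indent)."""
    text = json.dumps(cfg.model_dump(mode="json"), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# conversion to runtime objects
# ---------------------------------------------------------------------------

def to_baseline_parameters(cfg: ModelConfig) -> BaselineParameters:
    t = cfg.transitions
    p_progress = np.array([t.p_progress.mild_to_moderate,
                           t.p_progress.moderate_to_severe])
    p_care = np.zeros((3, 3, 3))
    for sev_label, rows in t.p_care.items():
        s = _SEVERITY_BY_LABEL[sev_label]
        for from_label, dests in rows.items():
            c_from = _CARE_BY_LABEL[from_label]
            for to_label, p in dests.items():
                p_care[s, c_from, _CARE_BY_LABEL[to_label]] = p
    p_death = np.zeros((3, 3))
    for sev_label, row in t.p_death.items():
        s = _SEVERITY_BY_LABEL[sev_label]
        for care_label, p in row.items():
            p_death[s, _CARE_BY_LABEL[care_label]] = p
    return BaselineParameters(
        p_progress=p_progress,
        p_care=p_care,
        p_death=p_death,
        cycle_length=cfg.model.cycle_length_years,
        allow_care_reversal=cfg.model.allow_care_reversal,
    )


def to_state_values(cfg: ModelConfig) -> StateValues:
    n = len(LIVING_STATE_NAMES)
    arrays = {k: np.zeros(n) for k in
              ("patient_utility", "caregiver_utility_delta",
               "formal_cost", "informal_hours")}
    for name, entry in cfg.values.states.items():
        i = STATE_INDEX_BY_NAME[name]
        for k in arrays:
            arrays[k][i] = getattr(entry, k)
    return StateValues(unit_wage=cfg.values.unit_wage,
                       currency=cfg.model.currency, **arrays)


def to_initial_distribution(cfg: ModelConfig) -> np.ndarray:
    from .engine import initial_distribution

    return initial_distribution(cfg.initial_distribution)


def parse_care_transition(text: str) -> CareTransition:
    """Parse "home_care->institutional_care" or "...->...|mild"."""
    severity = None
    if "|" in text:
        text, sev_label = text.split("|", 1)
        if sev_label not in _SEVERITY_BY_LABEL:
            raise ConfigError(f"unknown severity {sev_label!r} in target")
        severity = _SEVERITY_BY_LABEL[sev_label]
    parts = text.split("->")
    if len(parts) != 2 or parts[0] not in _CARE_BY_LABEL or parts[1] not in _CARE_BY_LABEL:
        raise ConfigError(f"cannot parse care transition {text!r}")
    return CareTransition(_CARE_BY_LABEL[parts[0]], _CARE_BY_LABEL[parts[1]], severity)


def _to_link(outcome: str, link_cfg: LinkConfig) -> SurrogateLink:
    target = None
    if link_cfg.target is not None:
        target = parse_care_transition(link_cfg.target)
    return SurrogateLink(
        outcome=outcome,
        pathway=link_cfg.pathway,
        coefficient=link_cfg.coefficient,
        target=target,
        citation=link_cfg.citation,
    )


def to_strategy(cfg: ModelConfig, name: str) -> Strategy:
    """Build the runtime strategy: direct effects verbatim, pilot effects
    assembled through the surrogate links with double-counting checks."""
    if name not in cfg.strategies:
        raise ConfigError(f"unknown strategy {name!r}")
    sc = cfg.strategies[name]
    eligibility = frozenset(STATE_INDEX_BY_NAME[n] for n in sc.eligibility)

    effects: list[TransitionEffect | StateValueEffect] = []
    for e in sc.effects:
        if isinstance(e, TransitionEffectConfig):
            effects.append(TransitionEffect(parse_care_transition(e.target), e.rr))
        else:
            states = None
            if e.states is not None:
                states = frozenset(STATE_INDEX_BY_NAME[n] for n in e.states)
            effects.append(StateValueEffect(e.stream, e.delta, states))

    pilot = [
        SurrogateEffect(p.outcome, p.effect, p.se, p.follow_up_weeks)
        for p in sc.pilot_effects
    ]
    links = [_to_link(outcome, lc) for outcome, lc in cfg.surrogate.links.items()]
    link_by_outcome = {lk.outcome: lk for lk in links}
    registry = PathwayRegistry(
        pairs={
            (p.outcome, link_by_outcome[p.outcome].pathway)
            for p in pilot
            if p.outcome in link_by_outcome
        },
        direct_qol_measured=(
            cfg.surrogate.direct_qol_measured
            or any(p.outcome == "utility" for p in pilot)
        ),
    )
    try:
        assembled = assemble_strategy(
            pilot_effects=pilot,
            links=links,
            registry=registry,
            persistence_cycles=sc.persistence_cycles,
            eligibility=eligibility,
            intervention_cost=sc.intervention_cost_per_year,
            name=name,
            waning=sc.waning,
            waning_cycles=sc.waning_cycles,
        )
    except ValueError as exc:
        raise ConfigError(f"strategies.{name}: {exc}") from exc
    try:
        return dataclasses.replace(
            assembled, effects=effects + assembled.effects
        )
    except ValueError as exc:
        raise ConfigError(f"strategies.{name}: {exc}") from exc


# ---------------------------------------------------------------------------
# dotted-path overrides (the sensitivity-analysis addressing scheme)
# ---------------------------------------------------------------------------

def _navigate(doc: Any, segments: list[str], path: str) -> tuple[Any, str | int]:
    node = doc
    for seg in segments[:-1]:
        if isinstance(node, list):
            node = node[int(seg)]
        elif isinstance(node, dict):
            if seg not in node:
                raise ConfigError(f"override path {path!r}: no key {seg!r}")
            node = node[seg]
        else:
            raise ConfigError(f"override path {path!r}: cannot descend into {seg!r}")
    last = segments[-1]
    if isinstance(node, list):
        return node, int(last)
    if not isinstance(node, dict):
        raise ConfigError(f"override path {path!r}: cannot descend to {last!r}")
    return node, last


def get_config_value(cfg: ModelConfig, path: str) -> Any:
    """Read a value at a dotted path in the config document."""
    doc = cfg.model_dump(mode="python")
    node, last = _navigate(doc, path.split("."), path)
    try:
        return node[last]
    except (KeyError, IndexError) as exc:
        raise ConfigError(f"override path {path!r}: no key {last!r}") from exc


def apply_overrides(cfg: ModelConfig, overrides: dict[str, Any]) -> ModelConfig:
    """Return a new validated config with dotted-path overrides applied.

    Overrides are applied to the serialized document and the result is
    re-validated, so an override that breaks an invariant fails with a
    located message and a strategy depending on an overridden link
    coefficient is re-assembled from the new value.
    """
    doc = cfg.model_dump(mode="python")
    for path, value in overrides.items():
        node, last = _navigate(doc, path.split("."), path)
        if isinstance(node, dict) and last not in node:
            raise ConfigError(f"override path {path!r}: no key {last!r}")
        node[last] = value
    return validate_config(doc)
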