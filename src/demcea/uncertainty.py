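"""Uncertainty analysis: PSA with CEAC, tornado diagrams, and scenarios.

Probabilistic sensitivity analysis draws parameter sets from standard
health-economic prior families (beta for probabilities, gamma for
non-negative quantities, lognormal for positive ratios, Dirichlet for
multinomial transition rows), re-runs control and intervention on the SAME
drawn baseline (common random baseline, which removes between-strategy
sampling noise from the increments), and summarizes the draws as a
cost-effectiveness acceptability curve.  Deterministic sensitivity is
covered by one-way (tornado) ranges and named scenario bundles; both use
the config document's dotted paths as the parameter-addressing scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import (
    ConfigError,
    ModelConfig,
    PriorConfig,
    apply_overrides,
    get_config_value,
)
from .model import run_cea

__all__ = [
    "ParameterPrior",
    "PSAResult",
    "TornadoBar",
    "sample_parameters",
    "run_psa",
    "ceac",
    "tornado",
    "run_scenarios",
]


@dataclass(frozen=True)
class ParameterPrior:
    """A sampling distribution for one named model input.

    ``path`` addresses the input in the config document.  Families follow
    health-economic convention: beta for [0, 1] probabilities/utilities
    (moment-matched to mean and SE), gamma for non-negative costs/hours,
    lognormal for positive ratios, and dirichlet for a whole care-transition
    row (``counts`` with the implicit stay destination first, then ``keys``).
    """

    path: str
    family: str
    mean: float | None = None
    se: float | None = None
    counts: tuple[float, ...] | None = None
    keys: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "lognormal", "dirichlet"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "dirichlet":
            if not self.counts or self.keys is None:
                raise ValueError("dirichlet prior needs counts and destination keys")
            if len(self.counts) != len(self.keys) + 1:
                raise ValueError(
                    "dirichlet counts must have one entry per destination key "
                    "plus the leading stay count"
                )
            if any(c <= 0 for c in self.counts):
                raise ValueError("dirichlet counts must be positive")
        else:
            if self.mean is None or self.se is None:
                raise ValueError(f"{self.family} prior needs mean and se")

    @classmethod
    def from_config(cls, pc: PriorConfig) -> "ParameterPrior":
        return cls(
            path=pc.path,
            family=pc.family,
            mean=pc.mean,
            se=pc.se,
            counts=tuple(pc.counts) if pc.counts else None,
            keys=tuple(pc.keys) if pc.keys is not None else None,
        )


def _beta_draws(rng: np.random.Generator, m: float, se: float, n: int) -> np.ndarray:
    if se == 0.0:
        return np.full(n, m)
    if not 0.0 < m < 1.0:
        raise ValueError(f"beta prior mean {m} must be in (0, 1)")
    v = se * se
    nu = m * (1.0 - m) / v - 1.0
    if nu <= 0:
        raise ValueError(
            f"infeasible moment-matching: SE {se} too large for beta support "
            f"at mean {m}"
        )
    return rng.beta(m * nu, (1.0 - m) * nu, size=n)


def _gamma_draws(rng: np.random.Generator, m: float, se: float, n: int) -> np.ndarray:
    if se == 0.0:
        return np.full(n, m)
    if m <= 0:
        raise ValueError(f"gamma prior mean {m} must be > 0 when SE > 0")
    shape = (m / se) ** 2
    scale = se * se / m
    return rng.gamma(shape, scale, size=n)


def _lognormal_draws(
    rng: np.random.Generator, m: float, se: float, n: int
) -> np.ndarray:
    if se == 0.0:
        return np.full(n, m)
    if m <= 0:
        raise ValueError(f"lognormal prior mean {m} must be > 0")
    sigma2 = np.log1p((se / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def sample_parameters(
    priors: list[ParameterPrior], seed: int, n: int
) -> list[dict[str, Any]]:
    """Draw ``n`` override sets, deterministically given ``seed``.

    Each draw maps a config path to a sampled value (a scalar, or for a
    Dirichlet row a destination->probability mapping with the stay
    probability left implicit as the residual).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    columns: list[tuple[str, Any]] = []
    for prior in priors:
        if prior.family == "beta":
            columns.append((prior.path, _beta_draws(rng, prior.mean, prior.se, n)))
        elif prior.family == "gamma":
            columns.append((prior.path, _gamma_draws(rng, prior.mean, prior.se, n)))
        elif prior.family == "lognormal":
            columns.append(
                (prior.path, _lognormal_draws(rng, prior.mean, prior.se, n))
            )
        else:  # dirichlet over [stay, *keys]
            rows = rng.dirichlet(np.asarray(prior.counts, dtype=float), size=n)
            columns.append((prior.path, rows))
    draws: list[dict[str, Any]] = []
    for i in range(n):
        d: dict[str, Any] = {}
        for (path, col), prior in zip(columns, priors):
            if prior.family == "dirichlet":
                d[path] = {k: float(col[i, j + 1]) for j, k in enumerate(prior.keys)}
            else:
                d[path] = float(col[i])
        draws.append(d)
    return draws


@dataclass
class PSAResult:
    """Per-draw incremental results of a probabilistic sensitivity analysis."""

    n: int
    seed: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    wtp_grid: np.ndarray
    ceac: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ceac = ceac(self, self.wtp_grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def run_psa(
    cfg: ModelConfig,
    strategy_name: str,
    seed: int | None = None,
    n: int | None = None,
    priors: list[ParameterPrior] | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty to (dC, dQ).

    Defaults for seed, n and priors come from the config's ``psa`` and
    ``analysis`` sections.  Every draw re-runs both strategies on the same
    drawn baseline; a draw whose overrides fail validation aborts the
    analysis with the offending draw index.
    """
    if priors is None:
        priors = [
            ParameterPrior.from_config(pc) for pc in (cfg.psa.priors if cfg.psa else [])
        ]
    if n is None:
        n = cfg.psa.n if cfg.psa else 1000
    if seed is None:
        seed = cfg.analysis.seed
    draws = sample_parameters(priors, seed, n)
    delta_cost = np.empty(n)
    delta_qaly = np.empty(n)
    for i, overrides in enumerate(draws):
        try:
            cfg_i = apply_overrides(cfg, overrides) if overrides else cfg
            result, _, _ = run_cea(cfg_i, strategy_name)
        except (ConfigError, ValueError) as exc:
            raise RuntimeError(f"PSA draw {i} failed: {exc}") from exc
        delta_cost[i] = result.delta_cost
        delta_qaly[i] = result.delta_qaly
    return PSAResult(
        n=n,
        seed=seed,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        wtp_grid=np.asarray(cfg.analysis.wtp_grid, dtype=float),
    )


def ceac(psa: PSAResult, wtp_grid: np.ndarray | list[float]) -> np.ndarray:
    """P(net monetary benefit > 0) per willingness-to-pay value.

    Ties (NMB exactly 0) count as not cost-effective.
    """
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if psa.n < 1:
        raise ValueError("empty PSA result")
    nmb = wtp[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    return (nmb > 0).mean(axis=1)


@dataclass(frozen=True)
class TornadoBar:
    path: str
    nmb_low: float
    nmb_high: float

    @property
    def width(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def tornado(
    cfg: ModelConfig,
    strategy_name: str,
    ranges: list[tuple[str, float, float]] | None = None,
    wtp: float | None = None,
) -> list[TornadoBar]:
    """One-way sensitivity: vary each parameter alone at a fixed WTP.

    Returns one bar per parameter — net monetary benefit at the range's low
    and high value — sorted by bar width descending.
    """
    if ranges is None:
        ranges = [
            (r.path, r.low, r.high) for r in (cfg.tornado.ranges if cfg.tornado else [])
        ]
    if wtp is None:
        wtp = cfg.tornado.wtp if cfg.tornado else cfg.analysis.wtp_reference

    bars = []
    for path, low, high in ranges:
        base = get_config_value(cfg, path)
        if not (low <= base <= high):
            raise ValueError(
                f"tornado range for {path!r} must satisfy low <= base <= high "
                f"(got low={low}, base={base}, high={high})"
            )
        nmbs = []
        for value in (low, high):
            result, _, _ = run_cea(apply_overrides(cfg, {path: value}), strategy_name)
            nmbs.append(wtp * result.delta_qaly - result.delta_cost)
        bars.append(TornadoBar(path, nmbs[0], nmbs[1]))
    bars.sort(key=lambda b: b.width, reverse=True)
    return bars


def run_scenarios(
    cfg: ModelConfig,
    strategy_name: str,
    scenarios: dict[str, dict[str, Any]] | None = None,
    wtp: float | None = None,
) -> pd.DataFrame:
    """Run named override bundles (plus the base case) and tabulate CEA rows.

    Each scenario is a mapping of config paths to values (overrides applied
    before validation); the table reports incremental QALYs, costs, the ICER
    and the net monetary benefit at the reference willingness-to-pay.
    """
    if scenarios is None:
        scenarios = cfg.scenarios
    if wtp is None:
        wtp = cfg.analysis.wtp_reference

    rows = []
    for name, overrides in [("base_case", {})] + sorted(scenarios.items()):
        cfg_s = apply_overrides(cfg, overrides) if overrides else cfg
        result, _, _ = run_cea(cfg_s, strategy_name)
        rows.append(
            {
                "scenario": name,
                "delta_qaly": result.delta_qaly,
                "delta_cost": result.delta_cost,
                "icer": result.icer,
                "nmb": wtp * result.delta_qaly - result.delta_cost,
            }
        )
    return pd.DataFrame(rows)
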