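"""Model parameters, sampling-distribution moment matching, and configuration files.

A cost-utility model is specified by per-state cost and utility estimates
(with second-order uncertainty), the arm/state structure of the two
treatment strategies, and analysis settings (cycle length, horizon,
discount rate, PSA size).  Costs carry gamma uncertainty; utility weights
and probabilities carry beta uncertainty; both families are parameterised
from (mean, sd) by the method of moments, the standard construction for
probabilistic sensitivity analysis when only summary estimates are
published.

Monetary values are 2018 Canadian dollars as published; no inflation
adjustment happens inside the package.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

log = logging.getLogger(__name__)

FAMILIES = ("gamma", "beta", "fixed")


class ConfigError(ValueError):
    """A parameter or configuration file violates the schema."""


@dataclass(frozen=True)
class ParameterEstimate:
    """A point estimate with second-order uncertainty.

    ``mean`` is in CAD for costs, a utility weight on [0, 1] for
    utilities, or a probability for transition/event parameters; ``sd``
    is on the same scale.  ``family`` names the PSA sampling
    distribution; ``sd == 0`` if and only if the family is ``fixed``.
    ``key`` identifies the parameter for shared sampling: two estimates
    with the same non-empty key receive the same draw in each PSA
    iteration.
    """

    mean: float
    sd: float = 0.0
    family: str = "fixed"
    key: str = ""

    def __post_init__(self) -> None:
        where = self.key or "parameter"
        if self.family not in FAMILIES:
            raise ConfigError(f"{where}: unknown family {self.family!r}")
        if self.mean < 0:
            raise ConfigError(f"{where}: mean must be non-negative, got {self.mean}")
        if self.sd < 0:
            raise ConfigError(f"{where}: sd must be non-negative, got {self.sd}")
        if (self.sd == 0) != (self.family == "fixed"):
            raise ConfigError(f"{where}: sd == 0 exactly when family == 'fixed'")
        if self.family == "beta":
            if not 0.0 < self.mean < 1.0:
                raise ConfigError(f"{where}: beta mean must lie in (0, 1), got {self.mean}")
            if self.sd**2 >= self.mean * (1.0 - self.mean):
                raise ConfigError(
                    f"{where}: infeasible beta variance sd^2={self.sd**2:.6g} "
                    f">= mean(1-mean)={self.mean * (1 - self.mean):.6g}"
                )
        if self.family == "gamma" and self.mean <= 0:
            raise ConfigError(f"{where}: gamma mean must be positive, got {self.mean}")


FIXED_ZERO = ParameterEstimate(0.0)


def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Match a beta distribution to (mean, sd): returns (alpha, beta).

    Solves E[X] = a/(a+b) and Var[X] = ab/((a+b)^2 (a+b+1)).
    """
    if not 0.0 < mean < 1.0:
        raise ConfigError(f"beta mean must lie in (0, 1), got {mean}")
    var = sd * sd
    if not 0.0 < var < mean * (1.0 - mean):
        raise ConfigError(
            f"infeasible beta variance {var:.6g} for mean {mean:.6g} "
            f"(must lie in (0, {mean * (1 - mean):.6g}))"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Match a gamma distribution to (mean, sd): returns (shape, rate)."""
    if mean <= 0 or sd <= 0:
        raise ConfigError(f"gamma moments must be positive, got mean={mean}, sd={sd}")
    return mean * mean / (sd * sd), mean / (sd * sd)


def default_uncertainty(
    estimate: ParameterEstimate,
    kind: str,
    cost_cv: float = 0.25,
    util_prob_cv: float = 0.10,
) -> ParameterEstimate:
    """Attach the default coefficient of variation to a bare point estimate.

    Costs get a gamma with sd = cost_cv * mean (default 25%); utilities
    and probabilities a beta with sd = util_prob_cv * mean (default 10%).
    A zero mean, or a utility/probability outside (0, 1), stays fixed.
    Where the CV rule would make the beta infeasible the sd is capped at
    0.99 * sqrt(mean(1-mean)) with a log entry, so literature utilities
    near 0 or 1 remain usable.
    """
    if kind not in ("cost", "utility", "probability"):
        raise ConfigError(f"unknown parameter kind {kind!r}")
    mean = estimate.mean
    if mean == 0:
        return ParameterEstimate(0.0, 0.0, "fixed", estimate.key)
    if kind == "cost":
        return ParameterEstimate(mean, cost_cv * mean, "gamma", estimate.key)
    if not 0.0 < mean < 1.0:
        log.warning("%s: mean %.4g outside (0,1); kept fixed", estimate.key or kind, mean)
        return ParameterEstimate(mean, 0.0, "fixed", estimate.key)
    sd = util_prob_cv * mean
    cap = 0.99 * math.sqrt(mean * (1.0 - mean))
    if sd >= cap:
        log.warning(
            "%s: CV rule sd=%.4g infeasible for beta mean %.4g; capped at %.4g",
            estimate.key or kind, sd, mean, cap,
        )
        sd = cap
    return ParameterEstimate(mean, sd, "beta", estimate.key)


def sample_estimate(estimate: ParameterEstimate, rng: np.random.Generator) -> float:
    """Draw one value from the estimate's PSA distribution."""
    if estimate.family == "fixed":
        return estimate.mean
    if estimate.family == "gamma":
        shape, rate = gamma_params_from_moments(estimate.mean, estimate.sd)
        return float(rng.gamma(shape, 1.0 / rate))
    alpha, beta = beta_params_from_moments(estimate.mean, estimate.sd)
    return float(rng.beta(alpha, beta))


# ---------------------------------------------------------------------------
# Structural types


@dataclass(frozen=True)
class EventVariant:
    """A within-cycle event tier (e.g. a toxicity grade) of a health state.

    The tier modifies that cycle's cost and utility; if ``destination``
    is set, the event also routes the affected fraction of the residual
    row mass to another state at the end of the cycle.
    """

    label: str
    probability: ParameterEstimate
    cost: ParameterEstimate
    utility: ParameterEstimate
    destination: str | None = None


@dataclass(frozen=True)
class HealthState:
    """A model health state with per-cycle cost/utility and optional events.

    ``transient`` marks a single-cycle treatment state: all surviving
    mass exits via the event destinations at the end of the entry cycle.
    ``progression_from_pfs`` marks states whose occupants face the
    PFS-minus-OS progression hazard.  ``transitions`` are fixed
    per-cycle probabilities to other states (e.g. Progression to
    Supportive Care).
    """

    name: str
    absorbing: bool = False
    cost: ParameterEstimate = FIXED_ZERO
    utility: ParameterEstimate = FIXED_ZERO
    one_time_cost: ParameterEstimate = FIXED_ZERO
    events: tuple[EventVariant, ...] = ()
    transient: bool = False
    progression_from_pfs: bool = False
    transitions: tuple[tuple[str, ParameterEstimate], ...] = ()

    def validate(self) -> None:
        if self.events:
            total = sum(v.probability.mean for v in self.events)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"state {self.name!r}: event probabilities sum to {total:.6g}, not 1"
                )
        if self.absorbing and (self.cost.mean != 0 or self.utility.mean != 0):
            raise ConfigError(f"absorbing state {self.name!r} must have zero cost and utility")
        if self.absorbing and (self.events or self.transitions or self.transient):
            raise ConfigError(f"absorbing state {self.name!r} admits no events or transitions")
        if self.transient:
            if not self.events or any(v.destination is None for v in self.events):
                raise ConfigError(
                    f"transient state {self.name!r}: every event needs a destination"
                )


@dataclass(frozen=True)
class ArmConfig:
    """One treatment strategy: an ordered state list plus its entry state."""

    name: str
    states: tuple[HealthState, ...]
    initial_state: str
    progression_state: str = "Progression"

    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def state(self, name: str) -> HealthState:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def absorbing_state(self) -> str:
        return next(s.name for s in self.states if s.absorbing)

    def validate(self) -> None:
        names = self.state_names()
        if len(set(names)) != len(names):
            raise ConfigError(f"arm {self.name!r}: duplicate state names")
        absorbing = [s.name for s in self.states if s.absorbing]
        if len(absorbing) != 1:
            raise ConfigError(
                f"arm {self.name!r}: exactly one absorbing state ('Death') required, "
                f"found {absorbing or 'none'}"
            )
        if self.initial_state not in names:
            raise ConfigError(f"arm {self.name!r}: unknown initial state {self.initial_state!r}")
        for s in self.states:
            s.validate()
            for v in s.events:
                if v.destination is not None and v.destination not in names:
                    raise ConfigError(
                        f"arm {self.name!r}, state {s.name!r}, event {v.label!r}: "
                        f"unknown destination {v.destination!r}"
                    )
            for to, _p in s.transitions:
                if to not in names:
                    raise ConfigError(
                        f"arm {self.name!r}, state {s.name!r}: unknown transition target {to!r}"
                    )
            if s.progression_from_pfs and self.progression_state not in names:
                raise ConfigError(
                    f"arm {self.name!r}: progression state {self.progression_state!r} missing"
                )


@dataclass(frozen=True)
class Settings:
    """Analysis settings shared by both arms."""

    cycle_length: float = 3.0          # months
    horizon: float = 5.0               # years
    discount_rate: float = 0.015       # annual proportion
    cost_cv: float = 0.25
    util_prob_cv: float = 0.10
    psa_iterations: int = 10_000
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 200_001, 1000))
    seed: int = 2018
    half_cycle_correction: bool = False
    equalize_after_months: float | None = 60.0

    def validate(self) -> None:
        if self.cycle_length <= 0:
            raise ConfigError("cycle_length must be positive")
        n = self.horizon * 12.0 / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(
                f"horizon ({self.horizon} y) must be an integer number of "
                f"{self.cycle_length}-month cycles"
            )
        if self.psa_iterations < 1:
            raise ConfigError("psa_iterations must be >= 1")
        if list(self.wtp_grid) != sorted(self.wtp_grid) or any(w < 0 for w in self.wtp_grid):
            raise ConfigError("wtp_grid must be ascending and non-negative")

    @property
    def n_cycles(self) -> int:
        return round(self.horizon * 12.0 / self.cycle_length)


@dataclass(frozen=True)
class ModelConfig:
    """The full model configuration: two arms, settings, parameter tables."""

    intervention: ArmConfig
    comparator: ArmConfig
    settings: Settings
    cost_table: dict[str, ParameterEstimate] = field(default_factory=dict)
    utility_table: dict[str, ParameterEstimate] = field(default_factory=dict)
    synthetic_trial: dict | None = None

    def validate(self) -> None:
        self.settings.validate()
        self.intervention.validate()
        self.comparator.validate()
        if self.intervention.absorbing_state != self.comparator.absorbing_state:
            raise ConfigError(
                "arms must share the absorbing state name, got "
                f"{self.intervention.absorbing_state!r} vs {self.comparator.absorbing_state!r}"
            )

    def cost(self, row: str) -> float:
        return self.cost_table[row].mean

    def utility(self, row: str) -> float:
        return self.utility_table[row].mean

    def arms(self) -> tuple[ArmConfig, ArmConfig]:
        return self.intervention, self.comparator

    def iter_estimates(self) -> Iterator[ParameterEstimate]:
        """Every ParameterEstimate reachable from the arm structure."""
        for arm in self.arms():
            for s in arm.states:
                yield s.cost
                yield s.utility
                yield s.one_time_cost
                for v in s.events:
                    yield v.probability
                    yield v.cost
                    yield v.utility
                for _to, p in s.transitions:
                    yield p


# ---------------------------------------------------------------------------
# Configuration file loading (YAML dialect)


def _estimate_from_node(
    node, key: str, kind: str, tables: dict[str, dict[str, ParameterEstimate]],
    settings: Settings,
) -> ParameterEstimate:
    """Build an estimate from a YAML node: a table reference, a bare number,
    or an inline {mean, sd} mapping."""
    if isinstance(node, str):  # table reference
        table = tables["cost" if kind == "cost" else "utility"]
        if node not in table:
            raise ConfigError(f"{key}: unknown parameter table row {node!r}")
        return table[node]
    if isinstance(node, (int, float)):
        bare = ParameterEstimate(float(node), 0.0, "fixed", key)
        return default_uncertainty(bare, kind, settings.cost_cv, settings.util_prob_cv)
    if isinstance(node, dict):
        mean = float(node["mean"])
        if "sd" in node:
            sd = float(node["sd"])
            family = node.get("family", "fixed" if sd == 0 else
                              ("gamma" if kind == "cost" else "beta"))
            return ParameterEstimate(mean, sd, family, key)
        bare = ParameterEstimate(mean, 0.0, "fixed", key)
        return default_uncertainty(bare, kind, settings.cost_cv, settings.util_prob_cv)
    raise ConfigError(f"{key}: cannot interpret {node!r} as a parameter estimate")


def _parse_state(
    node: dict, arm: str, tables, settings: Settings
) -> HealthState:
    name = node["name"]
    base = f"{arm}/{name}"

    def est(field_name: str, kind: str, default=None) -> ParameterEstimate:
        ref_key = f"{field_name}_ref"
        if ref_key in node:
            return _estimate_from_node(node[ref_key], f"{base}/{field_name}", kind,
                                       tables, settings)
        if field_name in node:
            return _estimate_from_node(node[field_name], f"{base}/{field_name}", kind,
                                       tables, settings)
        return default if default is not None else FIXED_ZERO

    events = []
    for ev in node.get("events", []):
        label = ev["label"]
        ebase = f"{base}/events/{label}"
        prob = _estimate_from_node(ev["probability"], f"{ebase}/probability",
                                   "probability", tables, settings)
        cost = (_estimate_from_node(ev["cost_ref"], f"{ebase}/cost", "cost", tables, settings)
                if "cost_ref" in ev else
                _estimate_from_node(ev.get("cost", 0.0), f"{ebase}/cost", "cost",
                                    tables, settings))
        util = (_estimate_from_node(ev["utility_ref"], f"{ebase}/utility", "utility",
                                    tables, settings)
                if "utility_ref" in ev else
                _estimate_from_node(ev.get("utility", 0.0), f"{ebase}/utility", "utility",
                                    tables, settings))
        events.append(EventVariant(label, prob, cost, util, ev.get("destination")))

    transitions = []
    for tr in node.get("transitions", []):
        p = _estimate_from_node(tr["probability"], f"{base}/to {tr['to']}/probability",
                                "probability", tables, settings)
        transitions.append((tr["to"], p))

    return HealthState(
        name=name,
        absorbing=bool(node.get("absorbing", False)),
        cost=est("cost", "cost"),
        utility=est("utility", "utility"),
        one_time_cost=est("one_time_cost", "cost"),
        events=tuple(events),
        transient=bool(node.get("transient", False)),
        progression_from_pfs=bool(node.get("progression_from_pfs", False)),
        transitions=tuple(transitions),
    )


def model_config_from_dict(doc: dict) -> ModelConfig:
    """Build and validate a ModelConfig from a parsed configuration mapping."""
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    s = doc.get("settings", {})
    wtp = s.get("wtp_grid", {"start": 0, "stop": 200_000, "step": 1000})
    if isinstance(wtp, dict):
        grid = tuple(float(x) for x in
                     np.arange(wtp["start"], wtp["stop"] + wtp["step"] / 2.0, wtp["step"]))
    else:
        grid = tuple(float(x) for x in wtp)
    eq = s.get("equalize_after_months", 60.0)
    settings = Settings(
        cycle_length=float(s.get("cycle_length_months", 3.0)),
        horizon=float(s.get("horizon_years", 5.0)),
        discount_rate=float(s.get("discount_rate", 0.015)),
        cost_cv=float(s.get("cost_cv", 0.25)),
        util_prob_cv=float(s.get("utility_probability_cv", 0.10)),
        psa_iterations=int(s.get("psa_iterations", 10_000)),
        wtp_grid=grid,
        seed=int(s.get("seed", 2018)),
        half_cycle_correction=bool(s.get("half_cycle_correction", False)),
        equalize_after_months=None if eq in (None, "none") else float(eq),
    )

    params = doc.get("parameters", {})
    cost_table: dict[str, ParameterEstimate] = {}
    for row, node in params.get("costs", {}).items():
        cost_table[row] = _estimate_from_node(
            node, f"cost:{row}", "cost",
            {"cost": {}, "utility": {}}, settings,
        )
        cost_table[row] = ParameterEstimate(
            cost_table[row].mean, cost_table[row].sd, cost_table[row].family, f"cost:{row}"
        )
    utility_table: dict[str, ParameterEstimate] = {}
    for row, node in params.get("utilities", {}).items():
        est = _estimate_from_node(node, f"utility:{row}", "utility",
                                  {"cost": {}, "utility": {}}, settings)
        utility_table[row] = ParameterEstimate(est.mean, est.sd, est.family, f"utility:{row}")
    tables = {"cost": cost_table, "utility": utility_table}

    arms_doc = doc.get("arms", {})
    built: dict[str, ArmConfig] = {}
    for role in ("intervention", "comparator"):
        if role not in arms_doc:
            raise ConfigError(f"missing arm {role!r}")
        a = arms_doc[role]
        states = tuple(_parse_state(n, a.get("name", role), tables, settings)
                       for n in a["states"])
        built[role] = ArmConfig(
            name=a.get("name", role),
            states=states,
            initial_state=a["initial_state"],
            progression_state=a.get("progression_state", "Progression"),
        )

    config = ModelConfig(
        intervention=built["intervention"],
        comparator=built["comparator"],
        settings=settings,
        cost_table=cost_table,
        utility_table=utility_table,
        synthetic_trial=doc.get("synthetic_trial"),
    )
    config.validate()
    return config


def load_model_config(path: str | Path) -> ModelConfig:
    """Read, parse and validate a YAML model configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - parser detail
            raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    return model_config_from_dict(doc)
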