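"""Probabilistic sensitivity analysis.

Each iteration draws one joint parameter set — gamma for costs, beta for
utilities and probabilities, per-cycle beta draws for the OS/PFS
transition schedules — applies it to BOTH arms (parameters shared
between arms are drawn once, preserving their correlation), runs the
cohort model for each arm, and records discounted cost, QALYs and
life-years.  Summaries are arm means with equal-tailed 2.5/97.5
percentile intervals, the ICER computed from mean increments (ratio of
means), the cost-effectiveness plane scatter, and the CEAC from net
monetary benefit at each willingness-to-pay threshold.

Randomness is organised as per-parameter substreams derived from the
master seed, so adding a parameter does not perturb the draws of the
others.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import accumulate, assemble_transitions, run_cohort
from .params import (
    ModelConfig,
    ParameterEstimate,
    beta_params_from_moments,
    gamma_params_from_moments,
)
from .survival import ProbSchedule

log = logging.getLogger(__name__)

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass
class CEACurve:
    """Probability the intervention is cost-effective vs willingness to pay."""

    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.wtp = np.asarray(self.wtp, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("CEAC probabilities must lie in [0, 1]")

    def at(self, wtp: float) -> float:
        i = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.probability[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "prob_cost_effective": self.probability})


@dataclass
class PSAResult:
    """Per-iteration outcomes of the probabilistic analysis."""

    arm_names: tuple[str, str]              # (intervention, comparator)
    costs: np.ndarray                       # (2, n) CAD, discounted
    qalys: np.ndarray                       # (2, n)
    lys: np.ndarray                         # (2, n)
    seed: int
    n_excluded: int = 0
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.costs = np.atleast_2d(np.asarray(self.costs, dtype=float))
        self.qalys = np.atleast_2d(np.asarray(self.qalys, dtype=float))
        self.lys = np.atleast_2d(np.asarray(self.lys, dtype=float))
        if not self.summary:
            self.summary = self._summarize()

    @property
    def n_iter(self) -> int:
        return self.costs.shape[1]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.costs[0] - self.costs[1]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qalys[0] - self.qalys[1]

    @property
    def delta_ly(self) -> np.ndarray:
        return self.lys[0] - self.lys[1]

    @property
    def icer_point(self):
        return icer(float(self.delta_cost.mean()), float(self.delta_qaly.mean()))

    def _summarize(self) -> dict:
        def block(x: np.ndarray) -> dict:
            lo, hi = np.percentile(x, [2.5, 97.5])
            return {"mean": float(x.mean()), "ci_low": float(lo), "ci_high": float(hi)}

        out: dict = {}
        for i, name in enumerate(self.arm_names):
            out[name] = {"cost": block(self.costs[i]),
                         "qaly": block(self.qalys[i]),
                         "ly": block(self.lys[i])}
        out["incremental"] = {"cost": block(self.delta_cost),
                              "qaly": block(self.delta_qaly),
                              "ly": block(self.delta_ly)}
        out["icer"] = self.icer_point
        return out


def icer(delta_cost: float, delta_effect: float):
    """Incremental cost-effectiveness ratio or a dominance label.

    Returns ``"dominant"`` when the intervention is cheaper and more
    effective, ``"dominated"`` for the reverse, ``"undefined"`` when the
    effect difference is zero, and the ratio otherwise.
    """
    if delta_effect == 0:
        return UNDEFINED
    if delta_cost < 0 and delta_effect > 0:
        return DOMINANT
    if delta_cost > 0 and delta_effect < 0:
        return DOMINATED
    return delta_cost / delta_effect


def ceac(psa: PSAResult, wtp_grid) -> CEACurve:
    """Cost-effectiveness acceptability curve over a WTP grid.

    At each threshold, the fraction of iterations with positive net
    monetary benefit lambda * dE - dC; a zero NMB counts as not
    cost-effective.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    dc = psa.delta_cost
    de = psa.delta_qaly
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    return CEACurve(wtp=grid, probability=(nmb > 0).mean(axis=1))


def ce_plane_export(psa: PSAResult, path: str | Path) -> pd.DataFrame:
    """Write the per-iteration (dQALY, dCost) scatter to CSV."""
    df = pd.DataFrame({"delta_qaly": psa.delta_qaly, "delta_cost": psa.delta_cost})
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Sampling


def _substream(master_seed: int, key: str) -> np.random.Generator:
    """Deterministic per-parameter RNG derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed,
                               spawn_key=(zlib.crc32(key.encode("utf-8")),)))


def _draw_many(est: ParameterEstimate, rng: np.random.Generator, n: int) -> np.ndarray:
    if est.family == "fixed":
        return np.full(n, est.mean)
    if est.family == "gamma":
        shape, rate = gamma_params_from_moments(est.mean, est.sd)
        return rng.gamma(shape, 1.0 / rate, size=n)
    alpha, beta = beta_params_from_moments(est.mean, est.sd)
    return rng.beta(alpha, beta, size=n)


def _schedule_draws(schedule: ProbSchedule, rng: np.random.Generator,
                    n: int) -> np.ndarray:
    """(n, n_cycles) beta draws of the per-cycle transition probability.

    Each time point is sampled from a beta moment-matched to that
    cycle's (mean, sd); infeasible sds are capped just inside the beta
    feasibility bound.  Sampling is per time point, so implied survival
    paths are not constrained to be monotone across cycles (a documented
    property of the approach).
    """
    out = np.empty((n, schedule.n_cycles))
    for k in range(schedule.n_cycles):
        m, sd = schedule.means[k], schedule.sds[k]
        if sd == 0 or m <= 0.0 or m >= 1.0:
            out[:, k] = m
            continue
        cap = 0.99 * np.sqrt(m * (1.0 - m))
        alpha, beta = beta_params_from_moments(m, min(sd, cap))
        out[:, k] = rng.beta(alpha, beta, size=n)
    return np.clip(out, 0.0, 1.0)


def draw_parameter_set(config: ModelConfig, schedules: dict, rng_or_seed) -> dict:
    """Draw one joint parameter set (a single PSA iteration).

    Returns ``{"values": {key: value}, "schedules": {(role, endpoint): array}}``.
    ``schedules`` maps arm role ("intervention"/"comparator") to
    ``{"os": ProbSchedule, "pfs": ProbSchedule}``.  Draws are
    independent across parameters and reproducible under a fixed seed.
    """
    if isinstance(rng_or_seed, np.random.Generator):
        master = int(rng_or_seed.integers(0, 2**31 - 1))
    else:
        master = int(rng_or_seed)
    draws = _draw_structural(config, master, 1)
    sched = _draw_schedules(config, schedules, master, 1)
    return {"values": {k: float(v[0]) for k, v in draws.items()},
            "schedules": {k: v[0] for k, v in sched.items()}}


def _draw_structural(config: ModelConfig, master_seed: int, n: int) -> dict[str, np.ndarray]:
    """(n,) draws per unique parameter key across both arms."""
    out: dict[str, np.ndarray] = {}
    for est in config.iter_estimates():
        if not est.key or est.key in out or est.family == "fixed":
            continue
        out[est.key] = _draw_many(est, _substream(master_seed, est.key), n)
    return out


def _draw_schedules(config: ModelConfig, schedules: dict, master_seed: int,
                    n: int, equalize_from_cycle: int | None = None) -> dict:
    out: dict[tuple[str, str], np.ndarray] = {}
    for role in ("comparator", "intervention"):
        for endpoint in ("os", "pfs"):
            sched = schedules[role][endpoint]
            # keyed by the schedule's own arm label so structurally
            # identical arms receive identical draws
            rng = _substream(master_seed, f"schedule/{sched.arm}/{sched.endpoint}")
            out[(role, endpoint)] = _schedule_draws(sched, rng, n)
    if equalize_from_cycle is not None:
        c = equalize_from_cycle
        for endpoint in ("os", "pfs"):
            out[("intervention", endpoint)][:, c:] = out[("comparator", endpoint)][:, c:]
    return out


def run_psa(
    config: ModelConfig,
    schedules: dict,
    n_iter: int | None = None,
    seed: int | None = None,
    equalize_from_cycle: int | None = None,
) -> PSAResult:
    """Run the probabilistic analysis.

    ``schedules`` maps "intervention"/"comparator" to ``{"os": ProbSchedule,
    "pfs": ProbSchedule}``.  Each iteration applies one shared parameter
    set to both arms.  ``equalize_from_cycle`` copies the comparator's
    per-cycle schedule draws onto the intervention arm from that cycle
    on (the non-durable-effect assumption for long horizons).
    Reproducible under a fixed seed.
    """
    n_iter = config.settings.psa_iterations if n_iter is None else int(n_iter)
    seed = config.settings.seed if seed is None else int(seed)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    settings = config.settings
    n_cycles = schedules["intervention"]["os"].n_cycles

    values = _draw_structural(config, seed, n_iter)
    sched_draws = _draw_schedules(config, schedules, seed, n_iter, equalize_from_cycle)

    roles = {"intervention": config.intervention, "comparator": config.comparator}
    costs = np.empty((2, n_iter))
    qalys = np.empty((2, n_iter))
    lys = np.empty((2, n_iter))
    for it in range(n_iter):
        draws = {k: v[it] for k, v in values.items()}
        for a, (role, arm) in enumerate(roles.items()):
            trans = assemble_transitions(
                arm,
                schedules[role]["os"], schedules[role]["pfs"],
                draws=draws,
                os_probs=sched_draws[(role, "os")][it],
                pfs_probs=sched_draws[(role, "pfs")][it],
            )
            trace = run_cohort(trans, arm.initial_state, n_cycles,
                               cycle_length=settings.cycle_length)
            res = accumulate(trace, arm.states, settings.discount_rate, draws=draws,
                             half_cycle_correction=settings.half_cycle_correction,
                             transitions=trans)
            costs[a, it] = res.total_cost
            qalys[a, it] = res.total_qaly
            lys[a, it] = res.total_ly

    finite = np.isfinite(costs).all(axis=0) & np.isfinite(qalys).all(axis=0)
    n_excluded = int((~finite).sum())
    if n_excluded:
        log.warning("run_psa: excluded %d iteration(s) with non-finite outcomes",
                    n_excluded)
        costs, qalys, lys = costs[:, finite], qalys[:, finite], lys[:, finite]

    return PSAResult(
        arm_names=(config.intervention.name, config.comparator.name),
        costs=costs, qalys=qalys, lys=lys, seed=seed, n_excluded=n_excluded,
    )
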