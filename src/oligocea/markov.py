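"""Time-inhomogeneous Markov cohort engine.

One arm of the model is a cohort distributed over mutually exclusive
health states, advanced in discrete cycles by per-cycle row-stochastic
transition matrices.  The matrices are assembled from the OS-driven
death probability (applied from every alive state), the PFS-minus-OS
progression probability (applied from states flagged as facing the
progression hazard), fixed configured transitions, and event-conditional
destinations; residual mass stays in state.  Costs, life-years and QALYs
are accumulated over the trace with annual discounting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ArmConfig, HealthState, ParameterEstimate
from .survival import ProbSchedule

log = logging.getLogger(__name__)


@dataclass
class TransitionSchedule:
    """Per-cycle transition matrices over an ordered state set."""

    states: list[str]
    matrices: np.ndarray            # (n_cycles, S, S)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        S = len(self.states)
        if self.matrices.ndim != 3 or self.matrices.shape[1:] != (S, S):
            raise ValueError("matrices must have shape (n_cycles, S, S)")
        rows = self.matrices.sum(axis=2)
        if not np.allclose(rows, 1.0, atol=1e-12):
            bad = np.argwhere(np.abs(rows - 1.0) > 1e-12)[0]
            raise ValueError(
                f"non-stochastic row: cycle {bad[0]}, state {self.states[bad[1]]!r} "
                f"(sum {rows[tuple(bad)]:.12g})")
        if np.any(self.matrices < -1e-15):
            raise ValueError("transition probabilities must be non-negative")

    @property
    def n_cycles(self) -> int:
        return self.matrices.shape[0]


@dataclass
class MarkovTrace:
    """Cohort occupancy by cycle; row k is the distribution after k cycles."""

    states: list[str]
    occupancy: np.ndarray           # (n_cycles + 1, S)
    cycle_length: float             # months

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if not np.allclose(self.occupancy.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each occupancy row must sum to 1")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=self.states)
        df.insert(0, "cycle", np.arange(len(df)))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CohortResult:
    """Discounted and undiscounted totals for one cohort run."""

    total_cost: float
    total_qaly: float
    total_ly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    undiscounted_ly: float


def discount_factor(annual_rate: float, t_years) -> np.ndarray | float:
    """Present-value factor (1 + r)^(-t) at time t in years."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    t_arr = np.asarray(t_years, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.power(1.0 + annual_rate, -t_arr)
    return float(out) if t_arr.ndim == 0 else out


def _resolve(est: ParameterEstimate, draws: Mapping[str, float] | None) -> float:
    if draws is not None and est.key and est.key in draws:
        return draws[est.key]
    return est.mean


def state_cycle_cost(state: HealthState, draws: Mapping[str, float] | None = None) -> float:
    """Expected per-cycle cost of a state over its event tiers."""
    if not state.events:
        return _resolve(state.cost, draws)
    probs = np.array([_resolve(v.probability, draws) for v in state.events])
    probs = probs / probs.sum()
    costs = np.array([_resolve(v.cost, draws) for v in state.events])
    return float(probs @ costs)


def state_cycle_utility(state: HealthState, draws: Mapping[str, float] | None = None) -> float:
    """Expected utility weight of a state over its event tiers."""
    if not state.events:
        return _resolve(state.utility, draws)
    probs = np.array([_resolve(v.probability, draws) for v in state.events])
    probs = probs / probs.sum()
    utils = np.array([_resolve(v.utility, draws) for v in state.events])
    return float(probs @ utils)


def assemble_transitions(
    arm: ArmConfig,
    os_schedule: ProbSchedule,
    pfs_schedule: ProbSchedule,
    draws: Mapping[str, float] | None = None,
    os_probs: np.ndarray | None = None,
    pfs_probs: np.ndarray | None = None,
) -> TransitionSchedule:
    """Build per-cycle transition matrices for one arm.

    Per cycle: the OS death probability applies from every alive state;
    states flagged ``progression_from_pfs`` additionally move to the
    progression state with max(0, p_PFS - p_death) (additive-hazard
    split of the composite PFS event, clamped at zero when the digitized
    curves cross).  These survival-curve-driven probabilities are never
    rescaled; an error names the cycle and state if they exceed 1.
    Configured fixed transitions and event tiers with a destination are
    conditional on the residual mass (alive, not progressed) and route
    their share of it; what is left stays in state.  A transient
    treatment state exits entirely through its event destinations, so it
    is occupied for its entry cycle only.

    ``os_probs`` / ``pfs_probs`` override the schedule means (used by
    the PSA with per-cycle sampled probabilities); ``draws`` overrides
    event and fixed-transition probabilities by parameter key.
    """
    if (os_schedule.cycle_length != pfs_schedule.cycle_length
            or os_schedule.n_cycles != pfs_schedule.n_cycles):
        raise ValueError("OS and PFS schedules must share the cycle grid")
    p_death = np.asarray(os_schedule.means if os_probs is None else os_probs, float)
    p_pfs = np.asarray(pfs_schedule.means if pfs_probs is None else pfs_probs, float)
    n_cycles = os_schedule.n_cycles
    names = arm.state_names()
    idx = {n: i for i, n in enumerate(names)}
    S = len(names)
    death_i = idx[arm.absorbing_state]
    prog_i = idx.get(arm.progression_state)

    if np.any(p_pfs + 1e-12 < p_death):
        log.info("arm %s: PFS event probability below OS death probability in "
                 "%d cycle(s); progression clamped to 0",
                 arm.name, int(np.sum(p_pfs < p_death)))
    p_prog = np.clip(p_pfs - p_death, 0.0, None)

    M = np.zeros((n_cycles, S, S))
    for s in arm.states:
        i = idx[s.name]
        if s.absorbing:
            M[:, i, i] = 1.0
            continue
        row = np.zeros((n_cycles, S))
        row[:, death_i] = p_death
        specified = p_death.copy()
        if s.progression_from_pfs:
            row[:, prog_i] += p_prog
            specified += p_prog
        over = specified > 1.0 + 1e-12
        if np.any(over):
            k = int(np.argmax(over))
            raise ValueError(
                f"arm {arm.name!r}: specified probabilities exceed 1 at cycle {k}, "
                f"state {s.name!r} (total {specified[k]:.6g})")
        residual = 1.0 - specified
        if s.events:
            probs = np.array([_resolve(v.probability, draws) for v in s.events])
            probs = probs / probs.sum()   # sampled tiers renormalised to a partition
        else:
            probs = np.zeros(0)
        routed = 0.0
        for to, p_est in s.transitions:
            p = _resolve(p_est, draws)
            row[:, idx[to]] += residual * p
            routed += p
        if s.transient:
            for v, p in zip(s.events, probs):
                row[:, idx[v.destination]] += residual * (1.0 - routed) * p
            routed = 1.0
        else:
            for v, p in zip(s.events, probs):
                if v.destination is not None:
                    row[:, idx[v.destination]] += residual * p
                    routed += p
        if routed > 1.0 + 1e-12:
            raise ValueError(
                f"arm {arm.name!r}, state {s.name!r}: conditional transition and "
                f"event-destination probabilities total {routed:.6g} > 1")
        row[:, i] += residual * (1.0 - routed)
        M[:, i, :] = row
    return TransitionSchedule(states=names, matrices=M)


def run_cohort(transitions: TransitionSchedule, initial_state: str,
               n_cycles: int, cycle_length: float = 3.0) -> MarkovTrace:
    """Propagate a unit cohort: occupancy(k+1) = occupancy(k) @ M(k)."""
    if n_cycles > transitions.n_cycles:
        raise ValueError(
            f"n_cycles {n_cycles} exceeds available matrices {transitions.n_cycles}")
    if initial_state not in transitions.states:
        raise ValueError(f"unknown initial state {initial_state!r}")
    S = len(transitions.states)
    occ = np.zeros((n_cycles + 1, S))
    occ[0, transitions.states.index(initial_state)] = 1.0
    for k in range(n_cycles):
        occ[k + 1] = occ[k] @ transitions.matrices[k]
    return MarkovTrace(states=transitions.states, occupancy=occ,
                       cycle_length=cycle_length)


def accumulate(
    trace: MarkovTrace,
    states: Sequence[HealthState],
    rate: float,
    draws: Mapping[str, float] | None = None,
    half_cycle_correction: bool = False,
    transitions: TransitionSchedule | None = None,
) -> CohortResult:
    """Discounted costs, life-years and QALYs over a cohort trace.

    Cycle k accrues occupancy(k) times the state's expected per-cycle
    cost and utility (utility scaled by cycle length in years),
    discounted at the cycle-start time; by default there is no
    half-cycle correction.  With ``half_cycle_correction`` the accrual
    uses the average of start- and end-of-cycle occupancy.  One-time
    entry costs are charged on the flow into the state at each cycle
    (the initial distribution counts as inflow at cycle 0).
    """
    by_name = {s.name: s for s in states}
    if set(trace.states) != set(by_name):
        raise ValueError("trace states do not match the provided state list")
    n_cycles = trace.n_cycles
    c_years = trace.cycle_length / 12.0
    t = np.arange(n_cycles) * c_years
    disc = discount_factor(rate, t)

    cost_vec = np.array([state_cycle_cost(by_name[n], draws) for n in trace.states])
    util_vec = np.array([state_cycle_utility(by_name[n], draws) for n in trace.states])
    alive_vec = np.array([0.0 if by_name[n].absorbing else 1.0 for n in trace.states])

    occ = trace.occupancy[:-1]
    if half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])

    cost_flow = occ @ cost_vec                       # per-cycle CAD
    qaly_flow = (occ @ util_vec) * c_years
    ly_flow = (occ @ alive_vec) * c_years

    # one-time entry costs: inflow at cycle 0 is the initial distribution;
    # afterwards, mass arriving from a *different* state
    otc_vec = np.array([_resolve(by_name[n].one_time_cost, draws) for n in trace.states])
    otc_disc = 0.0
    otc_undisc = 0.0
    if np.any(otc_vec > 0):
        inflow = np.zeros((n_cycles, len(trace.states)))
        inflow[0] = trace.occupancy[0]
        if transitions is not None:
            for k in range(1, n_cycles):
                Mk = transitions.matrices[k - 1].copy()
                np.fill_diagonal(Mk, 0.0)
                inflow[k] = trace.occupancy[k - 1] @ Mk
        entry = inflow @ otc_vec
        otc_disc = float(entry @ disc)
        otc_undisc = float(entry.sum())

    return CohortResult(
        total_cost=float(cost_flow @ disc) + otc_disc,
        total_qaly=float(qaly_flow @ disc),
        total_ly=float(ly_flow @ disc),
        undiscounted_cost=float(cost_flow.sum()) + otc_undisc,
        undiscounted_qaly=float(qaly_flow.sum()),
        undiscounted_ly=float(ly_flow.sum()),
    )
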