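"""End-to-end reference-case runs, reports and run manifests.

Ties the stages together: fit Weibull models to the per-arm OS/PFS
curves, build per-cycle transition-probability schedules over the model
horizon (equalizing the arms beyond the durability cutoff on long
horizons), run the probabilistic analysis, and emit a results table
(per-arm mean cost/QALY with 95% percentile intervals, increments,
ICER), the CE-plane scatter, the CEAC, and a manifest that makes the run
reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .markov import accumulate, assemble_transitions, run_cohort
from .params import ModelConfig
from .psa import DOMINANT, DOMINATED, UNDEFINED, PSAResult, ce_plane_export, ceac, run_psa
from .survival import ProbSchedule, SurvivalCurve, build_schedule, equalize_after, fit_weibull

log = logging.getLogger(__name__)


def format_icer(value) -> str:
    """Currency-rounded display string, dominance labels passed through."""
    if value == DOMINANT:
        return "dominant (less costly, more effective)"
    if value == DOMINATED:
        return "dominated (more costly, less effective)"
    if value == UNDEFINED:
        return "ICER undefined (ΔE = 0)"
    return f"CAD {value:,.0f}"


def build_arm_schedules(
    config: ModelConfig,
    curves: dict[tuple[str, str], SurvivalCurve],
    horizon: float | None = None,
) -> dict[str, dict[str, ProbSchedule]]:
    """Fit each arm's OS/PFS curve and build per-cycle schedules.

    ``curves`` is keyed by (arm name, endpoint).  The observed window of
    each schedule ends at the curve's last coordinate; later cycles are
    projected.  On horizons past the durability cutoff the intervention
    schedules are equalized with the comparator's.
    """
    settings = config.settings
    horizon = settings.horizon if horizon is None else float(horizon)
    out: dict[str, dict[str, ProbSchedule]] = {}
    for role, arm in (("intervention", config.intervention),
                      ("comparator", config.comparator)):
        out[role] = {}
        for endpoint in ("OS", "PFS"):
            curve = curves[(arm.name, endpoint)]
            fit = fit_weibull(curve)
            observed = min(float(curve.times.max()), horizon * 12.0)
            out[role][endpoint.lower()] = build_schedule(
                fit, horizon, settings.cycle_length, observed,
                endpoint=endpoint, arm=arm.name)
    cutoff = settings.equalize_after_months
    if cutoff is not None and horizon * 12.0 > cutoff:
        for endpoint in ("os", "pfs"):
            out["intervention"][endpoint] = equalize_after(
                out["intervention"][endpoint], out["comparator"][endpoint], cutoff)
    return out


def equalize_cycle(config: ModelConfig, horizon: float) -> int | None:
    """PSA draw-equalization cycle for the given horizon, if any."""
    cutoff = config.settings.equalize_after_months
    if cutoff is None or horizon * 12.0 <= cutoff:
        return None
    return int(round(cutoff / config.settings.cycle_length))


def deterministic_run(config: ModelConfig, schedules, horizon: float) -> dict:
    """Point-estimate cohort run of both arms (no sampling)."""
    n_cycles = round(horizon * 12.0 / config.settings.cycle_length)
    out = {}
    for role, arm in (("intervention", config.intervention),
                      ("comparator", config.comparator)):
        trans = assemble_transitions(arm, schedules[role]["os"], schedules[role]["pfs"])
        trace = run_cohort(trans, arm.initial_state, n_cycles,
                           cycle_length=config.settings.cycle_length)
        res = accumulate(trace, arm.states, config.settings.discount_rate,
                         half_cycle_correction=config.settings.half_cycle_correction,
                         transitions=trans)
        out[arm.name] = {"trace": trace, "result": res}
    return out


def _config_hash(config: ModelConfig) -> str:
    doc = {
        "settings": vars(config.settings) | {"wtp_grid": list(config.settings.wtp_grid)},
        "costs": {k: (v.mean, v.sd, v.family) for k, v in config.cost_table.items()},
        "utilities": {k: (v.mean, v.sd, v.family) for k, v in config.utility_table.items()},
        "arms": [config.intervention.name, config.comparator.name],
    }
    blob = yaml.safe_dump(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_reference_case(
    config: ModelConfig,
    curves: dict[tuple[str, str], SurvivalCurve],
    horizon: float | None = None,
    out_dir: str | Path | None = None,
    n_iter: int | None = None,
    seed: int | None = None,
) -> dict:
    """Full analysis for one horizon; optionally writes all outputs.

    Returns a report dict shaped like the published results tables
    (per-arm cost/QALY means with 95% percentile intervals, increments,
    ICER) plus the PSAResult and CEAC under ``"psa"`` and ``"ceac"``.
    """
    settings = config.settings
    horizon = settings.horizon if horizon is None else float(horizon)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    schedules = build_arm_schedules(config, curves, horizon)
    timings["fit_and_schedules_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    psa = run_psa(config, schedules, n_iter=n_iter, seed=seed,
                  equalize_from_cycle=equalize_cycle(config, horizon))
    timings["psa_s"] = round(time.perf_counter() - t0, 3)

    curve = ceac(psa, settings.wtp_grid)
    n_cycles = round(horizon * 12.0 / settings.cycle_length)
    label = "reference case" if horizon == settings.horizon else f"{horizon:g}-year horizon"
    report = {
        "label": label,
        "horizon_years": horizon,
        "n_cycles": n_cycles,
        "iterations": psa.n_iter,
        "seed": psa.seed,
        "summary": psa.summary,
        "icer_display": format_icer(psa.icer_point),
        "psa": psa,
        "ceac": curve,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        ce_plane_export(psa, out_dir / "ce_plane.csv")
        curve.to_frame().to_csv(out_dir / "ceac.csv", index=False)
        for role, sched in schedules.items():
            for endpoint, s in sched.items():
                s.to_csv(out_dir / f"schedule_{role}_{endpoint}.csv")
        det = deterministic_run(config, schedules, horizon)
        for name, d in det.items():
            d["trace"].to_csv(out_dir / f"trace_{name.replace(' ', '_')}.csv")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump({k: v for k, v in report.items() if k not in ("psa", "ceac")},
                      fh, indent=2)
        timings["write_s"] = round(time.perf_counter() - t0, 3)
        manifest = {
            "package": "oligocea",
            "version": __version__,
            "config_hash": _config_hash(config),
            "seed": psa.seed,
            "iterations": psa.n_iter,
            "horizon_years": horizon,
            "timings": timings,
            "outputs": sorted(p.name for p in out_dir.iterdir() if p.name != "manifest.json"),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        report["manifest"] = manifest
    return report
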