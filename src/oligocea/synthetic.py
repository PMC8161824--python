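"""Synthetic two-arm trial generator.

The published trial's patient-level data and digitized curve coordinates
are not distributable, so every pipeline stage is exercised on synthetic
data with the same statistical structure: Weibull OS and PFS event times
in two arms under proportional hazards (treatment scale = control scale
* HR^(-1/shape)), PFS coupled to OS so progression cannot follow death,
exponential dropout plus administrative censoring, and Kaplan–Meier step
curves of the kind a digitizer would extract from a published figure.

Defaults emulate the evidence the model rests on: control median OS of
28 months with a treatment hazard ratio of 0.57 (about a 13-month median
gain at the default shape), PFS doubled under treatment, and a 2:1
allocation of 99 patients.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .params import ModelConfig, load_model_config
from .survival import SurvivalCurve

import yaml

TREATMENT, CONTROL = "SABR", "SoC"


def _scale_for_median(shape: float, median: float) -> float:
    return median / math.log(2.0) ** (1.0 / shape)


@dataclass(frozen=True)
class TrialSpec:
    """Generating parameters of the synthetic trial.

    ``n_per_arm`` is (treatment, control).  Scales are months.  The
    hazard ratio acts through the Weibull scale, treatment scale =
    control scale * hr^(-1/shape).  ``censor_rate`` is the exponential
    dropout rate per month; ``max_followup`` the administrative cutoff.
    """

    n_per_arm: tuple[int, int] = (66, 33)
    os_control: tuple[float, float] = (1.47, _scale_for_median(1.47, 28.0))
    hr_os: float = 0.57
    pfs_control: tuple[float, float] = (1.0, _scale_for_median(1.0, 6.0))
    pfs_multiplier: float = 2.0
    censor_rate: float = 0.005
    max_followup: float = 60.0
    seed: int = 20180513

    def __post_init__(self) -> None:
        if min(self.n_per_arm) < 1:
            raise ValueError("each arm needs at least one subject")
        for shape, scale in (self.os_control, self.pfs_control):
            if shape <= 0 or scale <= 0:
                raise ValueError("Weibull shape and scale must be positive")
        if self.hr_os <= 0 or self.pfs_multiplier <= 0:
            raise ValueError("hr_os and pfs_multiplier must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")

    def os_params(self, arm: str) -> tuple[float, float]:
        shape, scale = self.os_control
        if arm == TREATMENT:
            scale *= self.hr_os ** (-1.0 / shape)
        return shape, scale

    def pfs_params(self, arm: str) -> tuple[float, float]:
        shape, scale = self.pfs_control
        if arm == TREATMENT:
            scale *= self.pfs_multiplier
        return shape, scale

    @classmethod
    def from_dict(cls, doc: dict) -> "TrialSpec":
        def pair(node: dict) -> tuple[float, float]:
            shape = float(node["shape"])
            if "median_months" in node:
                return shape, _scale_for_median(shape, float(node["median_months"]))
            return shape, float(node["scale"])

        mf = doc.get("max_followup_months", 60.0)
        return cls(
            n_per_arm=(int(doc.get("n_treatment", 66)), int(doc.get("n_control", 33))),
            os_control=pair(doc["os_control"]),
            hr_os=float(doc.get("hr_os", 0.57)),
            pfs_control=pair(doc["pfs_control"]),
            pfs_multiplier=float(doc.get("pfs_multiplier", 2.0)),
            censor_rate=float(doc.get("censor_rate_per_month", 0.005)),
            max_followup=math.inf if mf in (None, "inf") else float(mf),
            seed=int(doc.get("seed", 20180513)),
        )


def simulate_trial(spec: TrialSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-subject OS/PFS times and event indicators for both arms.

    OS and PFS event times share one uniform per subject (a common
    frailty draw), which couples the endpoints; PFS is additionally
    clamped at OS so progression never follows death.  Censoring is the
    minimum of an exponential dropout time and the administrative
    cutoff, applied to both endpoints.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    frames = []
    for arm, n in zip((TREATMENT, CONTROL), spec.n_per_arm):
        k_os, lam_os = spec.os_params(arm)
        k_pfs, lam_pfs = spec.pfs_params(arm)
        u = rng.uniform(size=n)
        neglog = -np.log(u)
        t_os = lam_os * neglog ** (1.0 / k_os)
        t_pfs = np.minimum(lam_pfs * neglog ** (1.0 / k_pfs), t_os)
        if spec.censor_rate > 0:
            dropout = rng.exponential(1.0 / spec.censor_rate, size=n)
        else:
            dropout = np.full(n, np.inf)
        censor = np.minimum(dropout, spec.max_followup)
        frames.append(pd.DataFrame({
            "arm": arm,
            "os_time": np.minimum(t_os, censor),
            "os_event": (t_os <= censor).astype(int),
            "pfs_time": np.minimum(t_pfs, censor),
            "pfs_event": (t_pfs <= censor).astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


def km_curve(times, events, endpoint: str = "OS", arm: str = "arm") -> SurvivalCurve:
    """Kaplan–Meier product-limit step curve with at-risk counts.

    Coordinates are emitted at event times only (the steps a digitizer
    would capture); risk-set sizes just before each event time come
    along for use as fitting weights.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if not events.any():
        import warnings

        warnings.warn("all observations censored; survival curve is flat at 1.0")
        return SurvivalCurve(endpoint, arm, np.array([times.max()]), np.array([1.0]),
                             at_risk=np.array([float(len(times))]))
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    at_event = table[table["observed"] > 0]
    event_times = at_event.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    n_risk = at_event["at_risk"].to_numpy(dtype=float)
    return SurvivalCurve(endpoint, arm, event_times, surv, at_risk=n_risk)


def trial_curves(df: pd.DataFrame) -> dict[tuple[str, str], SurvivalCurve]:
    """KM curves for every (arm, endpoint) in a simulated trial table."""
    out: dict[tuple[str, str], SurvivalCurve] = {}
    for arm, sub in df.groupby("arm"):
        out[(arm, "OS")] = km_curve(sub["os_time"], sub["os_event"], "OS", arm)
        out[(arm, "PFS")] = km_curve(sub["pfs_time"], sub["pfs_event"], "PFS", arm)
    return out


def reference_config_path():
    """Packaged reference configuration (published parameter table fixture)."""
    return resources.files("oligocea.data") / "table1_reference.yaml"


def make_reference_config() -> tuple[ModelConfig, dict[tuple[str, str], SurvivalCurve]]:
    """Load the packaged reference model and generate its survival curves.

    Returns the validated ModelConfig built from the published parameter
    table plus KM curves from the synthetic trial specified inside the
    configuration (seeded, hence reproducible).
    """
    with resources.as_file(reference_config_path()) as p:
        config = load_model_config(p)
    spec = TrialSpec.from_dict(config.synthetic_trial or {})
    df = simulate_trial(spec)
    return config, trial_curves(df)


def load_reference_bia():
    """BIA inputs from the packaged reference configuration."""
    from .budget import BIAInputs

    with resources.as_file(reference_config_path()) as p:
        with open(p) as fh:
            doc = yaml.safe_load(fh)
    return BIAInputs.from_dict(doc["budget_impact"])
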