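"""Weibull extrapolation of digitized survival curves.

Published Kaplan–Meier curves (digitized to (time, survival) step
coordinates) are fitted with a two-parameter Weibull model,

    S(t) = exp(-(t / scale)^shape),

by weighted least squares on the complementary log-log scale, where the
model is linear: log(-log S(t)) = shape * log t - shape * log scale.
Weights are the numbers at risk when available.  The fit is extrapolated
beyond follow-up, converted to per-cycle transition probabilities

    p_k = 1 - S(t_k + c) / S(t_k),

and given per-cycle standard deviations: the delta method on the
(log shape, log scale) covariance inside the observed window, inflated
by the regression's residual variance (a standard error of prediction)
beyond it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Digitized step-curve coordinates for one endpoint in one arm.

    ``times`` are months, strictly increasing; ``survival`` proportions,
    non-increasing in [0, 1].  ``at_risk`` optionally holds risk-set
    sizes at the same times, used as regression weights.
    """

    endpoint: str                       # "OS" or "PFS"
    arm: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.at_risk is not None:
            self.at_risk = np.asarray(self.at_risk, dtype=float)
        if self.endpoint not in ("OS", "PFS"):
            raise ValueError(f"endpoint must be OS or PFS, got {self.endpoint!r}")
        if self.times.ndim != 1 or self.times.shape != self.survival.shape:
            raise ValueError("times and survival must be 1-d arrays of equal length")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival must lie in [0, 1]")
        if self.at_risk is not None and self.at_risk.shape != self.times.shape:
            raise ValueError("at_risk must align with times")

    @classmethod
    def from_csv(cls, path: str | Path, endpoint: str, arm: str) -> "SurvivalCurve":
        """Read columns time_months, survival, optional n_risk."""
        df = pd.read_csv(path)
        required = {"time_months", "survival"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
        at_risk = df["n_risk"].to_numpy(float) if "n_risk" in df.columns else None
        return cls(endpoint, arm, df["time_months"].to_numpy(float),
                   df["survival"].to_numpy(float), at_risk)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_months": self.times, "survival": self.survival})
        if self.at_risk is not None:
            df["n_risk"] = self.at_risk
        df.to_csv(path, index=False)


@dataclass
class WeibullFit:
    """Fitted Weibull parameters with log-scale covariance.

    ``log_param_cov`` is the 2x2 covariance of (log shape, log scale)
    from the local quadratic approximation at the optimum; ``resid_var``
    is the residual variance of the complementary log-log regression,
    the extra component of the standard error of prediction outside the
    observed window.
    """

    shape: float
    scale: float
    log_param_cov: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2)))
    resid_var: float = 0.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")
        self.log_param_cov = np.asarray(self.log_param_cov, dtype=float)
        if self.log_param_cov.shape != (2, 2):
            raise ValueError("log_param_cov must be 2x2")
        if not np.allclose(self.log_param_cov, self.log_param_cov.T, atol=1e-10):
            raise ValueError("log_param_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(self.log_param_cov) < -1e-10):
            raise ValueError("log_param_cov must be positive semidefinite")


@dataclass
class ProbSchedule:
    """Per-cycle transition probabilities (mean, sd) for one endpoint/arm.

    Cycle k covers [k*c, (k+1)*c) months; ``observed_horizon`` separates
    cycles informed by the digitized window from projected ones.
    """

    endpoint: str
    arm: str
    cycle_length: float
    means: np.ndarray
    sds: np.ndarray
    observed_horizon: float

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape or self.means.ndim != 1:
            raise ValueError("means and sds must be aligned 1-d arrays")
        if np.any((self.means < 0) | (self.means > 1)):
            raise ValueError("schedule means must lie in [0, 1]")
        if np.any(self.sds < 0):
            raise ValueError("schedule sds must be non-negative")

    @property
    def n_cycles(self) -> int:
        return len(self.means)

    def regions(self) -> np.ndarray:
        ends = (np.arange(self.n_cycles) + 1) * self.cycle_length
        return np.where(ends <= self.observed_horizon + 1e-9, "observed", "projected")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(self.n_cycles),
            "mean": self.means,
            "sd": self.sds,
            "region": self.regions(),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def fit_weibull(curve: SurvivalCurve) -> WeibullFit:
    """Fit S(t) = exp(-(t/scale)^shape) to digitized coordinates.

    Weighted least squares of log(-log S) on log t.  When at-risk counts
    are present, weights are the inverse Greenwood variance of each
    point on the complementary log-log scale (early coordinates, where
    |log S| is tiny and the transform wildly amplifies noise, are
    appropriately down-weighted); otherwise uniform.  Points with
    survival of exactly 0 or 1 (or time 0) are outside the transform's
    domain and are dropped with a log entry.  The (log shape, log scale)
    covariance comes from the WLS covariance of the regression
    coefficients via the delta method; it is exactly zero when the
    points lie on a true Weibull (zero residual).
    """
    usable = (curve.survival > 0) & (curve.survival < 1) & (curve.times > 0)
    dropped = int((~usable).sum())
    if dropped:
        log.info("fit_weibull(%s/%s): dropped %d point(s) with S in {0,1} or t=0",
                 curve.arm, curve.endpoint, dropped)
    t = curve.times[usable]
    s = curve.survival[usable]
    if len(t) < 3:
        raise ValueError(
            f"need at least 3 points with survival strictly in (0, 1); got {len(t)}")
    if curve.at_risk is None:
        w = np.ones_like(t)
    else:
        n_risk = curve.at_risk[usable]
        if np.any(n_risk <= 0):
            raise ValueError("at_risk counts must be positive")
        # deaths at each step from the KM ratio; Greenwood's cumulative sum
        # gives Var(S)/S^2, mapped to the cloglog scale by 1/(log S)^2
        s_prev = np.concatenate([[1.0], s[:-1]])
        d = n_risk * (1.0 - s / s_prev)
        greenwood = np.cumsum(d / (n_risk * np.clip(n_risk - d, 1e-12, None)))
        var_y = np.clip(greenwood / np.log(s) ** 2, 1e-12, None)
        w = 1.0 / var_y
        edge_var_y = float(var_y[-1])

    x = np.log(t)
    y = np.log(-np.log(s))
    X = np.column_stack([x, np.ones_like(x)])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    beta = np.linalg.solve(xtwx, WX.T @ y)
    slope, intercept = beta
    if slope <= 0:
        raise ValueError("fitted shape is non-positive; curve is not decreasing in time")
    shape = slope
    scale = float(np.exp(-intercept / slope))

    resid = y - X @ beta
    dof = len(t) - 2
    rss = float(np.sum(w * resid**2))
    sigma2 = rss / dof if dof > 0 else 0.0
    if sigma2 < 1e-20:
        sigma2 = 0.0
    cov_beta = sigma2 * np.linalg.inv(xtwx)
    # residual variance on the cloglog scale for prediction beyond the
    # data: with inverse-variance weights sigma2 is a dimensionless
    # scale factor, so anchor it to the Greenwood variance at the last
    # observed coordinate; with uniform weights it is already on scale
    resid_var = sigma2 * edge_var_y if curve.at_risk is not None else sigma2
    # (log shape, log scale) = (log slope, -intercept/slope)
    J = np.array([[1.0 / slope, 0.0],
                  [intercept / slope**2, -1.0 / slope]])
    cov_log = J @ cov_beta @ J.T
    cov_log = (cov_log + cov_log.T) / 2.0
    return WeibullFit(shape=float(shape), scale=scale,
                      log_param_cov=cov_log, resid_var=resid_var)


def survival_at(fit: WeibullFit, t) -> np.ndarray | float:
    """Weibull survival function S(t) = exp(-(t/scale)^shape)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-np.power(t_arr / fit.scale, fit.shape))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def cycle_transition_prob(fit: WeibullFit, cycle_start: float,
                          cycle_length: float) -> float:
    """Conditional event probability over one cycle, 1 - S(t+c)/S(t)."""
    if cycle_start < 0:
        raise ValueError("cycle_start must be non-negative")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    s0 = survival_at(fit, cycle_start)
    if s0 == 0.0:
        log.info("cycle_transition_prob: S(%.4g)=0; probability defined as 1", cycle_start)
        return 1.0
    s1 = survival_at(fit, cycle_start + cycle_length)
    return float(min(1.0, max(0.0, 1.0 - s1 / s0)))


def _prob_gradient(fit: WeibullFit, start: float, length: float,
                   eps: float = 1e-6) -> np.ndarray:
    """Gradient of the cycle probability w.r.t. (log shape, log scale)."""
    grad = np.empty(2)
    for i, (dk, dl) in enumerate([(eps, 0.0), (0.0, eps)]):
        hi = WeibullFit(fit.shape * np.exp(dk), fit.scale * np.exp(dl))
        lo = WeibullFit(fit.shape * np.exp(-dk), fit.scale * np.exp(-dl))
        grad[i] = (cycle_transition_prob(hi, start, length)
                   - cycle_transition_prob(lo, start, length)) / (2 * eps)
    return grad


def build_schedule(fit: WeibullFit, horizon: float, cycle_length: float,
                   observed_horizon: float, endpoint: str = "OS",
                   arm: str = "arm") -> ProbSchedule:
    """Per-cycle (mean, sd) transition probabilities over the model horizon.

    Means are the conditional per-cycle event probabilities from the
    fitted model.  Sds use the delta method on the (log shape, log
    scale) covariance inside ``observed_horizon`` and a standard error
    of prediction — the delta-method variance inflated by the residual
    variance propagated through the complementary log-log link — beyond
    it; projected sds are floored at the last observed cycle's sd.
    """
    if horizon * 12.0 < observed_horizon - 1e-9:
        raise ValueError("observed_horizon cannot exceed the model horizon")
    n_cycles = round(horizon * 12.0 / cycle_length)
    means = np.empty(n_cycles)
    sds = np.empty(n_cycles)
    boundary_sd = 0.0
    for k in range(n_cycles):
        start = k * cycle_length
        end = start + cycle_length
        p = cycle_transition_prob(fit, start, cycle_length)
        means[k] = p
        g = _prob_gradient(fit, start, cycle_length)
        var = float(g @ fit.log_param_cov @ g)
        if end <= observed_horizon + 1e-9:
            sds[k] = np.sqrt(max(var, 0.0))
            boundary_sd = sds[k]
        else:
            # prediction error is a level shift of the log cumulative
            # hazard: p = 1 - exp(-dH * e^eps), so dp/deps =
            # (S1/S0) * log(S0/S1), bounded by 1/e
            s0 = survival_at(fit, start)
            s1 = survival_at(fit, end)
            if s0 > 0 and s1 > 0 and s1 < s0:
                ratio = s1 / s0
                dp_deps = ratio * np.log(1.0 / ratio)
            else:
                dp_deps = 0.0
            var += dp_deps**2 * fit.resid_var
            sds[k] = max(np.sqrt(max(var, 0.0)), boundary_sd)
    return ProbSchedule(endpoint=endpoint, arm=arm, cycle_length=cycle_length,
                        means=means, sds=sds, observed_horizon=observed_horizon)


def equalize_after(intervention: ProbSchedule, comparator: ProbSchedule,
                   cutoff: float) -> ProbSchedule:
    """Replace the intervention schedule with the comparator's from ``cutoff``.

    Encodes a non-durable treatment effect: beyond the cutoff (months,
    at a cycle boundary) projected transition probabilities — means and
    sds — are taken from the comparator arm.
    """
    if (intervention.cycle_length != comparator.cycle_length
            or intervention.n_cycles != comparator.n_cycles):
        raise ValueError("schedules must share cycle length and horizon")
    ratio = cutoff / intervention.cycle_length
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"cutoff {cutoff} months is not a cycle boundary")
    k = int(round(ratio))
    k = min(max(k, 0), intervention.n_cycles)
    means = intervention.means.copy()
    sds = intervention.sds.copy()
    means[k:] = comparator.means[k:]
    sds[k:] = comparator.sds[k:]
    return ProbSchedule(endpoint=intervention.endpoint, arm=intervention.arm,
                        cycle_length=intervention.cycle_length, means=means, sds=sds,
                        observed_horizon=intervention.observed_horizon)
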