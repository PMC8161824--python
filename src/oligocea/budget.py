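"""Budget impact of adopting SABR at a centre with no existing equipment.

Year-by-year, undiscounted accounting: capital and human-resource costs
in the year incurred, plus the annual cohort's recurring cost difference
(SABR minus standard of care).  A large positive year-1 impact from
capital outlay can be offset over time by avoided systemic-therapy
costs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BIAInputs:
    """Inputs to the budget impact analysis.

    ``capital_costs`` is a list of (label, amount CAD, year incurred),
    years counted from 1.  Recurring costs are per patient per year.
    """

    capital_costs: tuple[tuple[str, float, int], ...]
    sabr_recurring_per_patient: float
    soc_recurring_per_patient: float
    patients_per_year: float
    horizon: int = 5

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 year")
        if self.patients_per_year < 0:
            raise ValueError("patients_per_year must be non-negative")
        for label, amount, year in self.capital_costs:
            if amount < 0:
                raise ValueError(f"capital cost {label!r} must be non-negative")
            if year < 1:
                raise ValueError(f"capital cost {label!r}: year must be >= 1")
        if self.sabr_recurring_per_patient < 0 or self.soc_recurring_per_patient < 0:
            raise ValueError("recurring costs must be non-negative")

    @classmethod
    def from_dict(cls, doc: dict) -> "BIAInputs":
        caps = tuple((c["label"], float(c["amount"]), int(c.get("year", 1)))
                     for c in doc.get("capital_costs", []))
        return cls(
            capital_costs=caps,
            sabr_recurring_per_patient=float(doc["sabr_recurring_per_patient"]),
            soc_recurring_per_patient=float(doc["soc_recurring_per_patient"]),
            patients_per_year=float(doc.get("patients_per_year", 0)),
            horizon=int(doc.get("horizon_years", 5)),
        )


@dataclass
class BIAResult:
    """Annual and cumulative net budget impact (CAD, undiscounted)."""

    years: np.ndarray
    net_impact: np.ndarray
    cumulative: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "net_impact": self.net_impact,
                             "cumulative": self.cumulative})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_bia(inputs: BIAInputs) -> BIAResult:
    """Net impact(y) = capital incurred in y + cohort recurring difference."""
    years = np.arange(1, inputs.horizon + 1)
    impact = np.zeros(inputs.horizon, dtype=float)
    for _label, amount, year in inputs.capital_costs:
        if year <= inputs.horizon:
            impact[year - 1] += amount
    recurring = inputs.patients_per_year * (
        inputs.sabr_recurring_per_patient - inputs.soc_recurring_per_patient)
    impact += recurring
    return BIAResult(years=years, net_impact=impact, cumulative=np.cumsum(impact))
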