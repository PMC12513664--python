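"""Device-cost amortization and the per-patient / national savings model.

A correctly reclassified patient moves one stage down in terms of direct
care costs (with effectiveness factor ``f``), moves one stage *up* in
medication costs, and incurs the annual device cost ``c``:

    per-patient saving = f * (DC_high - DC_low) - (MC_high - MC_low) - c

with (low, high) = (mild, moderate) for the ``moderate_detected``
scenario and (moderate, advanced) for ``advanced_detected``.  The
national total multiplies by the *unrounded* adopted cohort from the
detection cascade; euro rounding happens only at display.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

from ._util import PortfolioError, round_half_away
from .detection_cascade import run_cascade
from .parameters_io import (
    SCENARIO_STAGE_PAIR,
    CountryCostTable,
    DeviceParams,
    Portfolio,
    Scenario,
)


def annual_device_cost(device: DeviceParams) -> float:
    """Annual per-patient device cost in euros.

    A unit is shared across ``uses_per_device_year`` one-week recordings,
    and each patient is prescribed ``prescriptions_per_patient_year`` of
    them: ``unit_price / uses * prescriptions``.  The default
    ``floor_integer`` mode truncates to whole euros (2500/30*2 -> 166).
    """
    exact = device.unit_price / device.uses_per_device_year * device.prescriptions_per_patient_year
    if device.cost_rounding == "floor_integer":
        return float(int(exact))
    return exact


class SavingsComponents(BaseModel):
    """The terms of the per-patient saving, for audit and break-even."""

    model_config = ConfigDict(frozen=True)

    direct_cost_gap: float
    medication_cost_gap: float
    device_cost: float
    effectiveness_factor: float

    def recombine(self) -> float:
        return (
            self.effectiveness_factor * self.direct_cost_gap
            - self.medication_cost_gap
            - self.device_cost
        )


class SavingsResult(BaseModel):
    """Savings for one country x scenario."""

    model_config = ConfigDict(frozen=True)

    country: str
    scenario: Scenario
    n_patients_unrounded: float
    per_patient_saving: float
    total_saving: float
    components: SavingsComponents

    @model_validator(mode="after")
    def _check_consistency(self) -> "SavingsResult":
        if self.total_saving != self.per_patient_saving * self.n_patients_unrounded:
            raise PortfolioError(f"{self.country}/{self.scenario}: total != per-patient x n")
        if self.components.recombine() != self.per_patient_saving:
            raise PortfolioError(f"{self.country}/{self.scenario}: components do not recombine")
        return self

    @property
    def total_saving_display(self) -> int:
        return round_half_away(self.total_saving)


def _cost_gaps(costs: CountryCostTable, scenario: Scenario) -> tuple[float, float]:
    low, high = SCENARIO_STAGE_PAIR[scenario]
    dc = costs.costs[high].direct_cost - costs.costs[low].direct_cost
    mc = costs.costs[high].medication_cost - costs.costs[low].medication_cost
    return dc, mc


def per_patient_saving(
    costs: CountryCostTable,
    scenario: Scenario,
    effectiveness_factor: float,
    device_cost: float,
) -> float:
    """Annual saving per correctly reclassified patient; may be negative."""
    if not 0 < effectiveness_factor <= 1:
        raise PortfolioError(f"effectiveness factor {effectiveness_factor} outside (0, 1]")
    dc_gap, mc_gap = _cost_gaps(costs, scenario)
    return effectiveness_factor * dc_gap - mc_gap - device_cost


def total_savings(per_patient: float, n_patients_unrounded: float) -> float:
    """National annual saving: per-patient saving times the reached cohort."""
    if n_patients_unrounded < 0:
        raise PortfolioError(f"negative cohort size {n_patients_unrounded}")
    return per_patient * n_patients_unrounded


def run_full_model(portfolio: Portfolio) -> list[SavingsResult]:
    """Cascade plus savings for every country x configured scenario.

    Ordering is deterministic: portfolio country order, then scenario
    order as configured.
    """
    device_cost = annual_device_cost(portfolio.device)
    f = portfolio.config.effectiveness_factor
    cascades = {sc: {c.country: c for c in run_cascade(portfolio, sc)} for sc in portfolio.config.scenarios}
    results = []
    for rec in portfolio.countries:
        for scenario in portfolio.config.scenarios:
            n = cascades[scenario][rec.code].adopted_unrounded
            dc_gap, mc_gap = _cost_gaps(rec.costs, scenario)
            components = SavingsComponents(
                direct_cost_gap=dc_gap,
                medication_cost_gap=mc_gap,
                device_cost=device_cost,
                effectiveness_factor=f,
            )
            per_patient = components.recombine()
            results.append(
                SavingsResult(
                    country=rec.code,
                    scenario=scenario,
                    n_patients_unrounded=n,
                    per_patient_saving=per_patient,
                    total_saving=total_savings(per_patient, n),
                    components=components,
                )
            )
    return results
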