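"""Per-country detection cascade.

For each country and scenario the reachable cohort is a chain of
multiplicative shrinkages of a stage pool:

    stage pool      = national total x stage share
    underdiagnosed  = pool x underdiagnosis rate
    detectable      = underdiagnosed x device sensitivity
    adopted         = detectable x market penetration

In the ``moderate_detected`` scenario the pool is the *mild* stage
(patients recorded as mild whose motor fluctuations went unnoticed); in
``advanced_detected`` it is the *moderate* stage (patients whose advanced
disease went unnoticed).  Unrounded counts are carried downstream; the
display integers exist only for presentation.
"""

from __future__ import annotations

from typing import Mapping

from pydantic import BaseModel, ConfigDict, model_validator

from ._util import ConfigurationError, PortfolioError, round_half_away
from .parameters_io import Portfolio, Scenario, Stage

#: stage whose pool feeds the cascade, per scenario
SCENARIO_POOL_STAGE: Mapping[Scenario, Stage] = {
    "moderate_detected": "mild",
    "advanced_detected": "moderate",
}


class CascadeResult(BaseModel):
    """One country x scenario cascade, unrounded and display views."""

    model_config = ConfigDict(frozen=True)

    country: str
    scenario: Scenario
    stage_pool_unrounded: float
    underdiagnosed_unrounded: float
    detectable_unrounded: float
    adopted_unrounded: float

    @model_validator(mode="after")
    def _check_monotone(self) -> "CascadeResult":
        chain = (
            self.adopted_unrounded,
            self.detectable_unrounded,
            self.underdiagnosed_unrounded,
            self.stage_pool_unrounded,
        )
        if not (0 <= chain[0] <= chain[1] <= chain[2] <= chain[3]):
            raise PortfolioError(f"{self.country}/{self.scenario}: cascade counts must shrink monotonically")
        return self

    @property
    def stage_pool_display(self) -> int:
        return round_half_away(self.stage_pool_unrounded)

    @property
    def underdiagnosed_display(self) -> int:
        return round_half_away(self.underdiagnosed_unrounded)

    @property
    def detectable_display(self) -> int:
        return round_half_away(self.detectable_unrounded)

    @property
    def adopted_display(self) -> int:
        return round_half_away(self.adopted_unrounded)


def underdiagnosed_count(stage_pool: float, rate: float) -> float:
    """Patients in the pool whose true state is not recognised."""
    if stage_pool < 0 or not 0 <= rate <= 1:
        raise PortfolioError(f"invalid underdiagnosis inputs pool={stage_pool}, rate={rate}")
    return stage_pool * rate


def detectable_count(n: float, sensitivity: float) -> float:
    """Underdiagnosed patients the device would correctly flag."""
    if n < 0 or not 0 <= sensitivity <= 1:
        raise PortfolioError(f"invalid detection inputs n={n}, sensitivity={sensitivity}")
    return n * sensitivity


def adopted_count(n: float, penetration: float) -> float:
    """Detectable patients in care settings that actually deploy the device."""
    if n < 0 or not 0 <= penetration <= 1:
        raise PortfolioError(f"invalid adoption inputs n={n}, penetration={penetration}")
    return n * penetration


def run_cascade(portfolio: Portfolio, scenario: Scenario) -> list[CascadeResult]:
    """Run the cascade for every country in the portfolio."""
    if scenario not in SCENARIO_POOL_STAGE:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    pool_stage = SCENARIO_POOL_STAGE[scenario]
    rate = (
        portfolio.cascade.underdiagnosis_rate_mild
        if pool_stage == "mild"
        else portfolio.cascade.underdiagnosis_rate_moderate
    )
    results = []
    for rec in portfolio.countries:
        epi = rec.epidemiology
        if portfolio.config.cascade_total_source == "hy":
            if epi.total_diagnosed_hy is None:
                raise ConfigurationError(
                    f"{rec.code}: cascade_total_source='hy' but no H&Y counts are available"
                )
            total = epi.total_diagnosed_hy
        else:
            total = epi.total_diagnosed_text
        pool = total * portfolio.stage_distribution.share(pool_stage)
        under = underdiagnosed_count(pool, rate)
        detect = detectable_count(under, portfolio.cascade.detection_sensitivity)
        adopt = adopted_count(detect, portfolio.cascade.market_penetration)
        results.append(
            CascadeResult(
                country=rec.code,
                scenario=scenario,
                stage_pool_unrounded=pool,
                underdiagnosed_unrounded=under,
                detectable_unrounded=detect,
                adopted_unrounded=adopt,
            )
        )
    return results
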