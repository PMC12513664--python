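"""Synthetic country portfolios with the structure the model assumes.

Generated countries mimic the bundled European parameter sets: direct
costs that rise with disease stage (drawn as a mild-stage base times
stage multipliers >= 1, which guarantees the monotone cost structure the
savings equations exploit), medication costs as a fixed per-country
fraction of direct costs, plausible national totals, and an H&Y stage
histogram consistent with the total.  They exist to exercise every code
path and property without the bundled data — they make no claim to
represent the joint distribution of real national health costs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._util import PortfolioError, round_half_away
from .parameters_io import (
    BUNDLED_STAGE_DISTRIBUTION,
    HY_STAGES,
    STAGES,
    CascadeParams,
    CountryCostTable,
    CountryEpidemiology,
    CountryRecord,
    DeviceParams,
    ModelConfig,
    Portfolio,
    StageCosts,
    StageDistribution,
)

#: mild/moderate/advanced-compatible H&Y stage weights used as the mean
#: histogram shape (roughly the pooled bundled prevalence table)
_HY_SHAPE = {"I": 0.12, "II": 0.30, "III": 0.35, "IV": 0.17, "V": 0.06}


class SynthConfig(BaseModel):
    """Ranges for the synthetic generator.

    Defaults bracket the bundled five-country values: national totals
    20k-180k, mild-stage direct costs 2000-6500 euros, moderate costs
    1.2-4.6x mild, advanced 1.1-7.5x moderate, medication 30-75% of the
    same stage's direct cost.  ``cascade_jitter`` is a relative spread
    applied multiplicatively to the default cascade rates (0 keeps them
    exact).
    """

    model_config = ConfigDict(frozen=True)

    n_countries: int = Field(default=5, ge=1)
    total_range: tuple[int, int] = (20_000, 180_000)
    base_direct_cost_range: tuple[float, float] = (2_000.0, 6_500.0)
    moderate_multiplier_range: tuple[float, float] = (1.2, 4.6)
    advanced_multiplier_range: tuple[float, float] = (1.1, 7.5)
    medication_fraction_range: tuple[float, float] = (0.30, 0.75)
    cascade_jitter: float = Field(default=0.0, ge=0, le=0.5)
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self) -> "SynthConfig":
        for name in ("total_range", "base_direct_cost_range", "moderate_multiplier_range",
                     "advanced_multiplier_range", "medication_fraction_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise PortfolioError(f"{name}: low {lo} > high {hi}")
        for name in ("moderate_multiplier_range", "advanced_multiplier_range"):
            if getattr(self, name)[0] < 1:
                raise PortfolioError(f"{name}: multipliers must be >= 1")
        lo, hi = self.medication_fraction_range
        if not (0 < lo and hi < 1):
            raise PortfolioError("medication_fraction_range must lie in (0, 1)")
        if self.total_range[0] < 0:
            raise PortfolioError("total_range must be non-negative")
        return self


def _country_rng(config: SynthConfig, index: int) -> np.random.Generator:
    # per-country stream keyed by (seed, index): independent of n_countries
    return np.random.default_rng([config.seed, index])


def generate_country(config: SynthConfig, index: int) -> tuple[CountryCostTable, CountryEpidemiology]:
    """One synthetic country, deterministic given ``(config.seed, index)``."""
    rng = _country_rng(config, index)
    code = f"SY{index:03d}"

    total = int(rng.integers(config.total_range[0], config.total_range[1] + 1))
    base = float(rng.uniform(*config.base_direct_cost_range))
    m_mult = float(rng.uniform(*config.moderate_multiplier_range))
    a_mult = float(rng.uniform(*config.advanced_multiplier_range))
    med_frac = float(rng.uniform(*config.medication_fraction_range))

    direct = {"mild": base, "moderate": base * m_mult, "advanced": base * m_mult * a_mult}
    costs = {
        s: StageCosts(direct_cost=direct[s], medication_cost=med_frac * direct[s]) for s in STAGES
    }

    dist = BUNDLED_STAGE_DISTRIBUTION
    counts = {s: round_half_away(total * dist.share(s)) for s in STAGES}

    # H&Y histogram: Dirichlet around the pooled shape, then integerised
    # so the five stages sum exactly to the national total.
    shape = np.array([_HY_SHAPE[s] for s in HY_STAGES])
    props = rng.dirichlet(shape * 50.0)
    hy = {s: int(np.floor(total * p)) for s, p in zip(HY_STAGES, props)}
    hy["III"] += total - sum(hy.values())

    table = CountryCostTable(
        code=code,
        name=f"Synthetic country {index}",
        costs=costs,
        stage_patient_counts=counts,
    )
    epi = CountryEpidemiology(code=code, hy_counts=hy, total_diagnosed_text=total)
    return table, epi


def _jittered_cascade(config: SynthConfig, rng: np.random.Generator) -> CascadeParams:
    base = CascadeParams()
    if config.cascade_jitter == 0:
        return base
    j = config.cascade_jitter

    def wobble(x: float) -> float:
        return float(np.clip(x * rng.uniform(1 - j, 1 + j), 0.0, 1.0))

    return CascadeParams(
        underdiagnosis_rate_mild=wobble(base.underdiagnosis_rate_mild),
        underdiagnosis_rate_moderate=wobble(base.underdiagnosis_rate_moderate),
        detection_sensitivity=wobble(base.detection_sensitivity),
        market_penetration=wobble(base.market_penetration),
    )


def generate_portfolio(
    config: SynthConfig,
    device: Optional[DeviceParams] = None,
    model_config_override: Optional[ModelConfig] = None,
) -> Portfolio:
    """A fully validated synthetic portfolio of ``config.n_countries``."""
    countries = []
    for i in range(config.n_countries):
        table, epi = generate_country(config, i)
        countries.append(CountryRecord(costs=table, epidemiology=epi))
    cascade_rng = np.random.default_rng([config.seed, 1_000_003])
    return Portfolio(
        countries=tuple(countries),
        stage_distribution=StageDistribution(mild=0.45, moderate=0.35, advanced=0.20),
        cascade=_jittered_cascade(config, cascade_rng),
        device=device or DeviceParams(),
        config=model_config_override or ModelConfig(),
    )
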