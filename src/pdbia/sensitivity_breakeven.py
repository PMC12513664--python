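"""One-way sweeps, tornado ranking, Monte-Carlo propagation, break-even.

Parameters are addressed by dotted paths into the portfolio, e.g.
``cascade.market_penetration``, ``device.unit_price`` or
``config.effectiveness_factor``.  Every perturbed evaluation rebuilds a
validated copy of the portfolio, so domain constraints (rates in [0,1],
non-negative prices, ...) apply to swept and sampled values exactly as
they do to configured ones.
"""

from __future__ import annotations

from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._util import ConfigurationError, PortfolioError
from .detection_cascade import run_cascade
from .parameters_io import CountryCostTable, Portfolio, Scenario
from .savings_model import _cost_gaps, annual_device_cost, per_patient_saving, total_savings


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True)


# ---------------------------------------------------------------------------
# Dotted-path access
# ---------------------------------------------------------------------------

def get_param(portfolio: Portfolio, path: str) -> float:
    """Read a scalar parameter by dotted path."""
    obj = portfolio
    for part in path.split("."):
        if not isinstance(obj, BaseModel) or part not in type(obj).model_fields:
            raise ConfigurationError(f"unknown parameter path {path!r} (at {part!r})")
        obj = getattr(obj, part)
    if not isinstance(obj, (int, float)) or isinstance(obj, bool):
        raise ConfigurationError(f"parameter path {path!r} does not address a scalar")
    return float(obj)


def _updated(model: BaseModel, parts: Sequence[str], value: float) -> BaseModel:
    head = parts[0]
    if head not in type(model).model_fields:
        raise ConfigurationError(f"unknown parameter path component {head!r}")
    if len(parts) == 1:
        new = value
    else:
        sub = getattr(model, head)
        if not isinstance(sub, BaseModel):
            raise ConfigurationError(f"path component {head!r} is not a parameter group")
        new = _updated(sub, parts[1:], value)
    return type(model).model_validate({**model.__dict__, head: new})


def with_param(portfolio: Portfolio, path: str, value: float) -> Portfolio:
    """A validated copy of the portfolio with one scalar replaced."""
    get_param(portfolio, path)  # fail early on bad paths
    return _updated(portfolio, path.split("."), value)


def evaluate_total(portfolio: Portfolio, country: str, scenario: Scenario) -> float:
    """Total annual saving for one country x scenario (exact, unrounded)."""
    try:
        rec = portfolio.country(country)
    except KeyError:
        raise ConfigurationError(f"unknown country {country!r}") from None
    cascade = next(c for c in run_cascade(portfolio, scenario) if c.country == country)
    pp = per_patient_saving(
        rec.costs, scenario, portfolio.config.effectiveness_factor, annual_device_cost(portfolio.device)
    )
    return total_savings(pp, cascade.adopted_unrounded)


# ---------------------------------------------------------------------------
# One-way sweep and tornado
# ---------------------------------------------------------------------------

def one_way_sweep(
    portfolio: Portfolio,
    parameter: str,
    grid: Sequence[float],
    country: str,
    scenario: Scenario,
) -> list[tuple[float, float]]:
    """Evaluate the total saving at each grid value of one parameter."""
    return [(float(v), evaluate_total(with_param(portfolio, parameter, v), country, scenario)) for v in grid]


class ParamRange(_Frozen):
    """A low/base/high range for one scalar parameter."""

    parameter: str
    low: float
    base: float
    high: float

    @model_validator(mode="after")
    def _check_order(self) -> "ParamRange":
        if not self.low <= self.base <= self.high:
            raise PortfolioError(f"{self.parameter}: require low <= base <= high")
        return self


#: Illustrative default ranges: adoption and sensitivity bands, the quoted
#: +/-500-euro device price band, and +/-25% relative on the
#: underdiagnosis rates.
def default_tornado_ranges() -> list[ParamRange]:
    return [
        ParamRange(parameter="cascade.market_penetration", low=0.1, base=0.2, high=0.3),
        ParamRange(parameter="cascade.detection_sensitivity", low=0.8, base=0.9, high=1.0),
        ParamRange(parameter="device.unit_price", low=2000, base=2500, high=3000),
        ParamRange(parameter="cascade.underdiagnosis_rate_mild", low=0.135, base=0.18, high=0.225),
        ParamRange(parameter="cascade.underdiagnosis_rate_moderate", low=0.27, base=0.36, high=0.45),
    ]


class TornadoRow(_Frozen):
    parameter: str
    saving_at_low: float
    saving_at_high: float
    span: float


def tornado(
    portfolio: Portfolio,
    ranges: Sequence[ParamRange],
    country: str,
    scenario: Scenario,
) -> list[TornadoRow]:
    """One-at-a-time low/high evaluations, ranked by output span.

    Ties are broken by parameter path, lexicographically.
    """
    if not ranges:
        raise PortfolioError("tornado needs at least one parameter range")
    rows = []
    for r in ranges:
        lo = evaluate_total(with_param(portfolio, r.parameter, r.low), country, scenario)
        hi = evaluate_total(with_param(portfolio, r.parameter, r.high), country, scenario)
        rows.append(TornadoRow(parameter=r.parameter, saving_at_low=lo, saving_at_high=hi, span=abs(hi - lo)))
    return sorted(rows, key=lambda row: (-row.span, row.parameter))


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

class Distribution(_Frozen):
    """A sampling distribution for one parameter.

    ``point`` needs ``value``; ``uniform`` needs ``low``/``high``;
    ``triangular`` needs ``low``/``mode``/``high``.
    """

    kind: Literal["point", "uniform", "triangular"]
    value: Optional[float] = None
    low: Optional[float] = None
    mode: Optional[float] = None
    high: Optional[float] = None

    @model_validator(mode="after")
    def _check_fields(self) -> "Distribution":
        if self.kind == "point":
            if self.value is None:
                raise PortfolioError("point distribution needs 'value'")
        elif self.kind == "uniform":
            if self.low is None or self.high is None or self.low > self.high:
                raise PortfolioError("uniform distribution needs low <= high")
        else:
            if None in (self.low, self.mode, self.high) or not self.low <= self.mode <= self.high:
                raise PortfolioError("triangular distribution needs low <= mode <= high")
        return self

    def support(self) -> tuple[float, ...]:
        if self.kind == "point":
            return (self.value,)
        return (self.low, self.high)

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return self.value
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(rng.triangular(self.low, self.mode, self.high))


class McSpec(_Frozen):
    """Monte-Carlo specification: independent parameter distributions."""

    distributions: Mapping[str, Distribution]
    n_draws: int = Field(ge=1)
    seed: int


class McSummary(_Frozen):
    mean: float
    sd: float
    p2_5: float
    median: float
    p97_5: float
    n_draws: int
    draws: Optional[tuple[float, ...]] = None


def monte_carlo(
    portfolio: Portfolio,
    spec: McSpec,
    country: str,
    scenario: Scenario,
    keep_draws: bool = False,
) -> McSummary:
    """Propagate parameter uncertainty through the model.

    Parameters are drawn independently from one seeded generator; the
    summary is reproducible given ``spec.seed``.  Support endpoints are
    validated against parameter domains before any sampling.
    """
    paths = sorted(spec.distributions)
    for path in paths:  # fail fast on out-of-domain supports
        for endpoint in spec.distributions[path].support():
            with_param(portfolio, path, endpoint)

    rng = np.random.default_rng(spec.seed)
    draws = np.empty(spec.n_draws)
    for i in range(spec.n_draws):
        p = portfolio
        for path in paths:
            p = with_param(p, path, spec.distributions[path].draw(rng))
        draws[i] = evaluate_total(p, country, scenario)

    return McSummary(
        mean=float(draws.mean()),
        sd=float(draws.std(ddof=1)) if spec.n_draws > 1 else 0.0,
        p2_5=float(np.percentile(draws, 2.5)),
        median=float(np.percentile(draws, 50)),
        p97_5=float(np.percentile(draws, 97.5)),
        n_draws=spec.n_draws,
        draws=tuple(float(x) for x in draws) if keep_draws else None,
    )


# ---------------------------------------------------------------------------
# Break-even
# ---------------------------------------------------------------------------

def break_even_device_cost(
    costs: CountryCostTable,
    scenario: Scenario,
    effectiveness_factor: float = 1.0,
) -> float:
    """Annual per-patient device cost at which the saving is exactly zero.

    Algebraic inversion of the savings equation:
    ``f * (DC_high - DC_low) - (MC_high - MC_low)``.  Display rounding is
    deliberately ignored: a root of a rounded step function is
    ill-defined.
    """
    if not 0 < effectiveness_factor <= 1:
        raise PortfolioError(f"effectiveness factor {effectiveness_factor} outside (0, 1]")
    dc_gap, mc_gap = _cost_gaps(costs, scenario)
    return effectiveness_factor * dc_gap - mc_gap
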