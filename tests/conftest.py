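import pytest

from pdbia.detection_cascade import SCENARIO_POOL_STAGE
from pdbia.parameters_io import SCENARIO_STAGE_PAIR, load_portfolio
from pdbia.savings_model import annual_device_cost


@pytest.fixture(scope="session")
def bundled():
    return load_portfolio("bundled:paper")


def closed_form_total(portfolio, code, scenario):
    """Independent single-expression oracle for one country x scenario:

    T x share x underdiagnosis x sensitivity x penetration
      x (f * dDC - dMC - device_cost)
    """
    rec = portfolio.country(code)
    pool_stage = SCENARIO_POOL_STAGE[scenario]
    low, high = SCENARIO_STAGE_PAIR[scenario]
    casc = portfolio.cascade
    rate = casc.underdiagnosis_rate_mild if pool_stage == "mild" else casc.underdiagnosis_rate_moderate
    if portfolio.config.cascade_total_source == "hy":
        total = rec.epidemiology.total_diagnosed_hy
    else:
        total = rec.epidemiology.total_diagnosed_text
    f = portfolio.config.effectiveness_factor
    dc = rec.costs.costs[high].direct_cost - rec.costs.costs[low].direct_cost
    mc = rec.costs.costs[high].medication_cost - rec.costs.costs[low].medication_cost
    c = annual_device_cost(portfolio.device)
    return (
        total
        * portfolio.stage_distribution.share(pool_stage)
        * rate
        * casc.detection_sensitivity
        * casc.market_penetration
        * (f * dc - mc - c)
    )
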