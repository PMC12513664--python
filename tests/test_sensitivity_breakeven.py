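import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from pdbia._util import ConfigurationError, PortfolioError
from pdbia.savings_model import per_patient_saving
from pdbia.sensitivity_breakeven import (
    Distribution,
    McSpec,
    ParamRange,
    break_even_device_cost,
    evaluate_total,
    get_param,
    monte_carlo,
    one_way_sweep,
    tornado,
    with_param,
)
from pdbia.synthetic_data import SynthConfig, generate_country


def test_get_and_set_param(bundled):
    assert get_param(bundled, "cascade.market_penetration") == 0.2
    p2 = with_param(bundled, "device.unit_price", 3000.0)
    assert get_param(p2, "device.unit_price") == 3000.0
    assert get_param(bundled, "device.unit_price") == 2500.0  # base unmodified


@pytest.mark.parametrize("path", ["cascade.nope", "nope.x", "countries", "config.display_rounding"])
def test_bad_paths_rejected(bundled, path):
    with pytest.raises(ConfigurationError):
        get_param(bundled, path)


def test_set_out_of_domain_rejected(bundled):
    with pytest.raises(ValidationError):
        with_param(bundled, "cascade.market_penetration", 1.5)


def test_sweep_zero_penetration(bundled):
    [(_, total)] = one_way_sweep(bundled, "cascade.market_penetration", [0.0], "ES", "moderate_detected")
    assert total == 0.0


def test_sweep_linearity_in_penetration(bundled):
    """Savings are linear in penetration: grid 0.1/0.2/0.4 gives ratios 1:2:4."""
    curve = one_way_sweep(bundled, "cascade.market_penetration", [0.1, 0.2, 0.4], "SE", "advanced_detected")
    (_, a), (_, b), (_, c) = curve
    assert b == pytest.approx(2 * a, rel=1e-12)
    assert c == pytest.approx(4 * a, rel=1e-12)


def test_sweep_price_strictly_decreasing(bundled):
    curve = one_way_sweep(bundled, "device.unit_price", [2000, 2500, 3000], "DE", "advanced_detected")
    totals = [t for _, t in curve]
    assert totals[0] > totals[1] > totals[2]


def test_tornado_single_and_degenerate(bundled):
    (row,) = tornado(
        bundled, [ParamRange(parameter="device.unit_price", low=2000, base=2500, high=3000)],
        "DE", "advanced_detected",
    )
    assert row.span > 0
    rows = tornado(
        bundled,
        [
            ParamRange(parameter="device.unit_price", low=2000, base=2500, high=3000),
            ParamRange(parameter="cascade.detection_sensitivity", low=0.9, base=0.9, high=0.9),
        ],
        "DE", "advanced_detected",
    )
    assert rows[-1].parameter == "cascade.detection_sensitivity"
    assert rows[-1].span == 0.0


def test_tornado_penetration_dominates_price(bundled):
    """A +/-50% adoption band moves German advanced-scenario savings far more
    than the +/-500-euro device price band."""
    rows = tornado(
        bundled,
        [
            ParamRange(parameter="cascade.market_penetration", low=0.1, base=0.2, high=0.3),
            ParamRange(parameter="device.unit_price", low=2000, base=2500, high=3000),
        ],
        "DE", "advanced_detected",
    )
    assert rows[0].parameter == "cascade.market_penetration"
    assert rows[0].span > rows[1].span


def test_tornado_linear_span_equals_slope_times_width(bundled):
    """For a linear parameter, span = |slope| x (high - low)."""
    lo, hi = 0.05, 0.35
    (row,) = tornado(
        bundled, [ParamRange(parameter="cascade.market_penetration", low=lo, base=0.2, high=hi)],
        "UK", "moderate_detected",
    )
    per_unit = evaluate_total(with_param(bundled, "cascade.market_penetration", 1.0), "UK", "moderate_detected")
    assert row.span == pytest.approx(per_unit * (hi - lo), rel=1e-12)


def test_tornado_empty_ranges(bundled):
    with pytest.raises(PortfolioError):
        tornado(bundled, [], "DE", "advanced_detected")


def test_tornado_tie_break_lexicographic(bundled):
    rows = tornado(
        bundled,
        [
            ParamRange(parameter="device.unit_price", low=2500, base=2500, high=2500),
            ParamRange(parameter="cascade.detection_sensitivity", low=0.9, base=0.9, high=0.9),
        ],
        "DE", "advanced_detected",
    )
    assert [r.parameter for r in rows] == ["cascade.detection_sensitivity", "device.unit_price"]


def test_param_range_ordering_enforced():
    with pytest.raises(PortfolioError):
        ParamRange(parameter="x", low=1.0, base=0.5, high=2.0)


def test_mc_point_mass_equals_deterministic(bundled):
    """Point-mass distributions collapse the Monte Carlo onto the
    deterministic pipeline, bit for bit."""
    spec = McSpec(
        distributions={
            "cascade.market_penetration": Distribution(kind="point", value=0.2),
            "device.unit_price": Distribution(kind="point", value=2500.0),
        },
        n_draws=25,
        seed=42,
    )
    s = monte_carlo(bundled, spec, "DE", "advanced_detected", keep_draws=True)
    det = evaluate_total(bundled, "DE", "advanced_detected")
    assert s.sd == 0.0
    assert all(d == det for d in s.draws)
    assert s.mean == det


def test_mc_seed_reproducibility(bundled):
    spec = McSpec(
        distributions={"cascade.market_penetration": Distribution(kind="uniform", low=0.1, high=0.3)},
        n_draws=200,
        seed=7,
    )
    a = monte_carlo(bundled, spec, "SE", "advanced_detected")
    b = monte_carlo(bundled, spec, "SE", "advanced_detected")
    assert a == b


def test_mc_uniform_mean_matches_linear_expectation(bundled):
    """Penetration enters linearly, so a symmetric uniform band is centred on
    the deterministic value; the sample mean lands within 3 standard errors."""
    spec = McSpec(
        distributions={"cascade.market_penetration": Distribution(kind="uniform", low=0.1, high=0.3)},
        n_draws=10_000,
        seed=123,
    )
    s = monte_carlo(bundled, spec, "DE", "advanced_detected")
    det = evaluate_total(bundled, "DE", "advanced_detected")
    se = s.sd / spec.n_draws**0.5
    assert abs(s.mean - det) < 3 * se


def test_mc_out_of_domain_distribution_rejected(bundled):
    spec = McSpec(
        distributions={"cascade.market_penetration": Distribution(kind="uniform", low=0.5, high=1.5)},
        n_draws=10,
        seed=0,
    )
    with pytest.raises(ValidationError):
        monte_carlo(bundled, spec, "DE", "advanced_detected")


@pytest.mark.parametrize("bad", [
    dict(kind="point"),
    dict(kind="uniform", low=2.0, high=1.0),
    dict(kind="triangular", low=0.0, mode=2.0, high=1.0),
])
def test_malformed_distributions_rejected(bad):
    with pytest.raises(PortfolioError):
        Distribution(**bad)


@pytest.mark.parametrize("code, scenario, f, expected", [
    ("SE", "moderate_detected", 1.0, 4953 - 1509),    # 3444
    ("DE", "advanced_detected", 1.0, 44901 - 10976),  # 33925
])
def test_break_even_hand_values(bundled, code, scenario, f, expected):
    assert break_even_device_cost(bundled.country(code).costs, scenario, f) == expected


def test_break_even_zero_gaps(bundled):
    flat = bundled.country("SE").costs.model_copy(
        update={"costs": {s: bundled.country("SE").costs.costs["mild"] for s in ("mild", "moderate", "advanced")}}
    )
    assert break_even_device_cost(flat, "moderate_detected", 1.0) == 0.0


@settings(max_examples=300, derandomize=True)
@given(
    seed=st.integers(min_value=0, max_value=2**31 - 1),
    index=st.integers(min_value=0, max_value=50),
    f=st.floats(min_value=0.05, max_value=1.0),
    scenario=st.sampled_from(["moderate_detected", "advanced_detected"]),
)
def test_break_even_round_trip_is_exact_zero(seed, index, f, scenario):
    """Charging exactly the break-even device cost nulls the per-patient
    saving, with no floating-point residue, on arbitrary synthetic countries."""
    table, _ = generate_country(SynthConfig(seed=seed), index)
    c = break_even_device_cost(table, scenario, f)
    assert per_patient_saving(table, scenario, f, c) == 0.0
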