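"""Domain types, validation, bundled parameter sets, and file I/O.

The model is driven by a :class:`Portfolio`: a set of countries (each a
per-stage cost table plus an epidemiology record), a stage distribution,
cascade parameters, device economics, and model configuration.  A
portfolio can be loaded from the bundled literature-derived parameter set
(``"bundled:paper"``) or from a directory written by
:func:`write_portfolio` (a YAML config plus a CSV cost table, both
hand-editable and round-trip exact).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._util import ConfigurationError, PortfolioError, SchemaError, round_half_away

Stage = Literal["mild", "moderate", "advanced"]
STAGES: tuple[Stage, ...] = ("mild", "moderate", "advanced")

Scenario = Literal["moderate_detected", "advanced_detected"]
SCENARIOS: tuple[Scenario, ...] = ("moderate_detected", "advanced_detected")

#: (lower stage, higher stage) whose cost gap drives the saving in each scenario.
SCENARIO_STAGE_PAIR: dict[Scenario, tuple[Stage, Stage]] = {
    "moderate_detected": ("mild", "moderate"),
    "advanced_detected": ("moderate", "advanced"),
}

#: effectiveness-factor presets for the direct-cost reduction.  The savings
#: equations are written with a 0.8 factor ("equation" preset) but the
#: published national totals are only consistent with 1.0 ("published").
EFFECTIVENESS_PRESETS: dict[str, float] = {"published": 1.0, "equation": 0.8}

HY_STAGES: tuple[str, ...] = ("I", "II", "III", "IV", "V")


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True)


class StageCosts(_Frozen):
    """Annual per-patient costs at one disease stage, in euros.

    ``direct_cost`` covers hospitalisations, consultations, nursing and
    formal care, excluding medication; ``medication_cost`` is the
    pharmacological treatment cost.
    """

    direct_cost: float = Field(ge=0, allow_inf_nan=False)
    medication_cost: float = Field(ge=0, allow_inf_nan=False)


class CountryCostTable(_Frozen):
    """Per-stage costs and diagnosed patient counts for one country."""

    code: str
    name: str
    costs: Mapping[Stage, StageCosts]
    stage_patient_counts: Mapping[Stage, int]

    @model_validator(mode="after")
    def _check_stages(self) -> "CountryCostTable":
        for field_name, mapping in (("costs", self.costs), ("stage_patient_counts", self.stage_patient_counts)):
            missing = set(STAGES) - set(mapping)
            if missing:
                raise SchemaError(f"{self.code}: {field_name} missing stage(s) {sorted(missing)}")
            extra = set(mapping) - set(STAGES)
            if extra:
                raise SchemaError(f"{self.code}: {field_name} has unknown stage(s) {sorted(extra)}")
        for stage, n in self.stage_patient_counts.items():
            if n < 0:
                raise PortfolioError(f"{self.code}: negative patient count for {stage}")
        return self


class CountryEpidemiology(_Frozen):
    """Diagnosed-population totals for one country.

    Two totals coexist because the literature sources disagree: the sum of
    the Hoehn & Yahr prevalence table (``total_diagnosed_hy``) and the
    round national figures quoted in the narrative
    (``total_diagnosed_text``).  The cascade consumes one of them,
    selected by :attr:`ModelConfig.cascade_total_source`.
    """

    code: str
    hy_counts: Optional[Mapping[str, int]] = None
    total_diagnosed_hy: Optional[int] = None
    total_diagnosed_text: int = Field(ge=0)

    @model_validator(mode="after")
    def _check_totals(self) -> "CountryEpidemiology":
        if self.hy_counts is not None:
            if set(self.hy_counts) != set(HY_STAGES):
                raise SchemaError(f"{self.code}: hy_counts must cover stages {HY_STAGES}")
            if any(v < 0 for v in self.hy_counts.values()):
                raise PortfolioError(f"{self.code}: negative H&Y count")
            s = sum(self.hy_counts.values())
            if self.total_diagnosed_hy is None:
                object.__setattr__(self, "total_diagnosed_hy", s)
            elif self.total_diagnosed_hy != s:
                raise PortfolioError(
                    f"{self.code}: total_diagnosed_hy={self.total_diagnosed_hy} != sum(hy_counts)={s}"
                )
        if self.total_diagnosed_hy is not None and self.total_diagnosed_hy < 0:
            raise PortfolioError(f"{self.code}: negative total_diagnosed_hy")
        return self


class StageDistribution(_Frozen):
    """Population shares of the three-stage model; must sum to 1."""

    mild: float = Field(ge=0, le=1)
    moderate: float = Field(ge=0, le=1)
    advanced: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _check_sum(self) -> "StageDistribution":
        total = self.mild + self.moderate + self.advanced
        if abs(total - 1.0) > 1e-9:
            raise PortfolioError(f"stage shares sum to {total!r}, expected 1")
        return self

    def share(self, stage: Stage) -> float:
        return getattr(self, stage)


class CascadeParams(_Frozen):
    """Rates of the underdiagnosis -> detection -> adoption cascade.

    Defaults: 18% of mild-pool patients have unrecognised motor
    fluctuations and 36% of moderate-pool patients unrecognised advanced
    disease (observational under-diagnosis studies); the device detects
    with 0.9 sensitivity; 20% of care settings adopt it.
    """

    underdiagnosis_rate_mild: float = Field(default=0.18, ge=0, le=1)
    underdiagnosis_rate_moderate: float = Field(default=0.36, ge=0, le=1)
    detection_sensitivity: float = Field(default=0.9, ge=0, le=1)
    market_penetration: float = Field(default=0.2, ge=0, le=1)


class DeviceParams(_Frozen):
    """Device economics: a 2500-euro unit reused ~30 one-week recordings a
    year, prescribed twice per patient-year, gives 166 euros/patient-year
    (floored to whole euros by default)."""

    unit_price: float = Field(default=2500.0, ge=0)
    uses_per_device_year: int = Field(default=30, gt=0)
    prescriptions_per_patient_year: int = Field(default=2, gt=0)
    cost_rounding: Literal["floor_integer", "exact"] = "floor_integer"


class ModelConfig(_Frozen):
    """Run-level switches.

    ``effectiveness_factor`` scales the direct-cost gap (fraction of
    reclassified patients whose care costs actually drop a stage).  The
    savings equations carry 0.8, but the published totals require 1.0;
    both are exposed as presets and "published" is the default.
    """

    effectiveness_factor: float = Field(default=1.0, gt=0, le=1)
    display_rounding: Literal["nearest_integer"] = "nearest_integer"
    scenarios: tuple[Scenario, ...] = SCENARIOS
    cascade_total_source: Literal["narrative", "hy"] = "narrative"

    @classmethod
    def from_preset(cls, preset: str, **overrides) -> "ModelConfig":
        try:
            factor = EFFECTIVENESS_PRESETS[preset]
        except KeyError:
            raise ConfigurationError(
                f"unknown effectiveness preset {preset!r}; expected one of {sorted(EFFECTIVENESS_PRESETS)}"
            ) from None
        return cls(effectiveness_factor=factor, **overrides)


class CountryRecord(_Frozen):
    """A cost table paired with its epidemiology record."""

    costs: CountryCostTable
    epidemiology: CountryEpidemiology

    @model_validator(mode="after")
    def _check_codes(self) -> "CountryRecord":
        if self.costs.code != self.epidemiology.code:
            raise PortfolioError(
                f"country code mismatch: costs={self.costs.code!r} vs epidemiology={self.epidemiology.code!r}"
            )
        return self

    @property
    def code(self) -> str:
        return self.costs.code


class Portfolio(_Frozen):
    """Everything one model run needs."""

    countries: tuple[CountryRecord, ...]
    stage_distribution: StageDistribution
    cascade: CascadeParams = CascadeParams()
    device: DeviceParams = DeviceParams()
    config: ModelConfig = ModelConfig()

    @model_validator(mode="after")
    def _check_unique(self) -> "Portfolio":
        codes = [c.code for c in self.countries]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise PortfolioError(f"duplicate country identifiers: {dupes}")
        return self

    def country(self, code: str) -> CountryRecord:
        for rec in self.countries:
            if rec.code == code:
                return rec
        raise KeyError(code)


# ---------------------------------------------------------------------------
# Bundled literature-derived parameter set
# ---------------------------------------------------------------------------

#: Per-stage annual costs in euros (direct excl. drugs, medication) and the
#: published stage-stratified diagnosed counts, five European countries.
_BUNDLED_COSTS: dict[str, tuple[str, dict[Stage, tuple[float, float]], dict[Stage, int]]] = {
    "ES": (
        "Spain",
        {"mild": (5600, 1904), "moderate": (8680, 2951), "advanced": (10800, 3672)},
        {"mild": 47914, "moderate": 37266, "advanced": 21295},
    ),
    "SE": (
        "Sweden",
        {"mild": (2180, 1308), "moderate": (7133, 2817), "advanced": (52300, 5830)},
        {"mild": 9000, "moderate": 7000, "advanced": 4000},
    ),
    "DE": (
        "Germany",
        {"mild": (2000, 1500), "moderate": (9105, 5000), "advanced": (54006, 15976)},
        {"mild": 172350, "moderate": 134050, "advanced": 76600},
    ),
    "IT": (
        "Italy",
        {"mild": (6460, 2040), "moderate": (8677, 2740), "advanced": (9943, 3140)},
        {"mild": 54000, "moderate": 42000, "advanced": 24000},
    ),
    "UK": (
        "United Kingdom",
        {"mild": (6039, 1907), "moderate": (12376, 3908), "advanced": (28522, 9007)},
        {"mild": 46776, "moderate": 36381, "advanced": 20789},
    ),
}

#: Round national diagnosed-population figures quoted in the narrative;
#: these feed the detection cascade by default.
_BUNDLED_NARRATIVE_TOTALS: dict[str, int] = {
    "ES": 150_000,
    "SE": 20_000,
    "DE": 180_000,
    "IT": 120_000,
    "UK": 127_000,
}

#: 2016 diagnosed prevalence by Hoehn & Yahr stage (GlobalData market
#: analysis), all regions it reports.  Sweden is absent from the source.
BUNDLED_HY_COUNTS: dict[str, dict[str, int]] = {
    "US": {"I": 108_832, "II": 251_150, "III": 293_008, "IV": 139_013, "V": 32_709},
    "JP": {"I": 15_828, "II": 68_580, "III": 183_175, "IV": 121_674, "V": 53_094},
    "UK": {"I": 13_649, "II": 31_499, "III": 36_749, "IV": 17_849, "V": 4_200},
    "ES": {"I": 11_819, "II": 52_599, "III": 15_758, "IV": 21_082, "V": 5_217},
    "FR": {"I": 38_729, "II": 89_375, "III": 104_271, "IV": 50_646, "V": 11_917},
    "DE": {"I": 50_293, "II": 116_061, "III": 135_404, "IV": 65_768, "V": 15_475},
    "IT": {"I": 16_338, "II": 37_702, "III": 43_986, "IV": 21_365, "V": 5_027},
}

#: Fixed three-stage shares used for all published stage counts.
BUNDLED_STAGE_DISTRIBUTION = StageDistribution(mild=0.45, moderate=0.35, advanced=0.20)

BUNDLED_TOKEN = "bundled:paper"


def bundled_portfolio() -> Portfolio:
    """The five-country literature parameter set with default constants."""
    countries = []
    for code, (name, costs, counts) in _BUNDLED_COSTS.items():
        table = CountryCostTable(
            code=code,
            name=name,
            costs={s: StageCosts(direct_cost=dc, medication_cost=mc) for s, (dc, mc) in costs.items()},
            stage_patient_counts=dict(counts),
        )
        epi = CountryEpidemiology(
            code=code,
            hy_counts=BUNDLED_HY_COUNTS.get(code),
            total_diagnosed_text=_BUNDLED_NARRATIVE_TOTALS[code],
        )
        countries.append(CountryRecord(costs=table, epidemiology=epi))
    return Portfolio(countries=tuple(countries), stage_distribution=BUNDLED_STAGE_DISTRIBUTION)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_COST_CSV = "cost_tables.csv"
_CONFIG_YAML = "portfolio.yaml"
_COST_COLUMNS = ("country", "stage", "direct_cost", "medication_cost", "n_patients")


def write_portfolio(portfolio: Portfolio, path: str | Path) -> Path:
    """Write a portfolio to ``path`` (a directory) as a YAML config plus a
    flat CSV cost table; :func:`load_portfolio` restores it bit-exactly."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / _COST_CSV, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COST_COLUMNS)
        for rec in portfolio.countries:
            for stage in STAGES:
                sc = rec.costs.costs[stage]
                w.writerow(
                    [rec.code, stage, repr(sc.direct_cost), repr(sc.medication_cost),
                     rec.costs.stage_patient_counts[stage]]
                )

    doc = {
        "stage_distribution": portfolio.stage_distribution.model_dump(),
        "cascade": portfolio.cascade.model_dump(),
        "device": portfolio.device.model_dump(),
        "config": {**portfolio.config.model_dump(), "scenarios": list(portfolio.config.scenarios)},
        "countries": {
            rec.code: {
                "name": rec.costs.name,
                "total_diagnosed_text": rec.epidemiology.total_diagnosed_text,
                "hy_counts": dict(rec.epidemiology.hy_counts) if rec.epidemiology.hy_counts else None,
            }
            for rec in portfolio.countries
        },
        "country_order": [rec.code for rec in portfolio.countries],
    }
    with open(out / _CONFIG_YAML, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return out


def load_portfolio(path: str | Path) -> Portfolio:
    """Load a portfolio from a directory written by :func:`write_portfolio`,
    or the bundled parameter set for the token ``"bundled:paper"``."""
    if str(path) == BUNDLED_TOKEN:
        return bundled_portfolio()
    root = Path(path)
    cfg_path, csv_path = root / _CONFIG_YAML, root / _COST_CSV
    if not root.is_dir() or not cfg_path.exists() or not csv_path.exists():
        raise SchemaError(f"{root} is not a portfolio directory (need {_CONFIG_YAML} and {_COST_CSV})")

    with open(cfg_path) as fh:
        doc = yaml.safe_load(fh)

    rows: dict[str, dict[Stage, tuple[float, float, int]]] = {}
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != _COST_COLUMNS:
            raise SchemaError(f"{csv_path}: expected columns {_COST_COLUMNS}, got {reader.fieldnames}")
        for row in reader:
            stage = row["stage"]
            if stage not in STAGES:
                raise SchemaError(f"{csv_path}: unknown stage {stage!r} for country {row['country']!r}")
            rows.setdefault(row["country"], {})[stage] = (
                float(row["direct_cost"]),
                float(row["medication_cost"]),
                int(row["n_patients"]),
            )

    countries = []
    for code in doc.get("country_order", sorted(rows)):
        meta = doc["countries"][code]
        stage_rows = rows.get(code, {})
        missing = set(STAGES) - set(stage_rows)
        if missing:
            raise SchemaError(f"country {code!r}: cost table missing stage(s) {sorted(missing)}")
        table = CountryCostTable(
            code=code,
            name=meta["name"],
            costs={s: StageCosts(direct_cost=dc, medication_cost=mc) for s, (dc, mc, _) in stage_rows.items()},
            stage_patient_counts={s: n for s, (_, _, n) in stage_rows.items()},
        )
        epi = CountryEpidemiology(
            code=code,
            hy_counts=meta.get("hy_counts"),
            total_diagnosed_text=meta["total_diagnosed_text"],
        )
        countries.append(CountryRecord(costs=table, epidemiology=epi))

    return Portfolio(
        countries=tuple(countries),
        stage_distribution=StageDistribution(**doc["stage_distribution"]),
        cascade=CascadeParams(**doc["cascade"]),
        device=DeviceParams(**doc["device"]),
        config=ModelConfig(**{**doc["config"], "scenarios": tuple(doc["config"]["scenarios"])}),
    )


_RESULT_COLUMNS = (
    "country",
    "scenario",
    "n_patients_unrounded",
    "n_patients_display",
    "per_patient_saving",
    "total_saving",
    "components",
)


def write_results(results: Sequence, path: str | Path, format: str = "csv") -> Path:
    """Write savings results as CSV or JSON with a fixed column order.

    ``results`` is a non-empty sequence of objects exposing the result
    fields (e.g. :class:`~pdbia.savings_model.SavingsResult`).  The
    ``components`` breakdown is a JSON object in both formats.
    """
    if not results:
        raise PortfolioError("no results to write")
    if format not in ("csv", "json"):
        raise ConfigurationError(f"unknown results format {format!r}; expected 'csv' or 'json'")

    records = []
    for r in results:
        comp = r.components
        records.append(
            {
                "country": r.country,
                "scenario": r.scenario,
                "n_patients_unrounded": r.n_patients_unrounded,
                "n_patients_display": round_half_away(r.n_patients_unrounded),
                "per_patient_saving": r.per_patient_saving,
                "total_saving": r.total_saving,
                "components": {
                    "direct_cost_gap": comp.direct_cost_gap,
                    "medication_cost_gap": comp.medication_cost_gap,
                    "device_cost": comp.device_cost,
                    "effectiveness_factor": comp.effectiveness_factor,
                },
            }
        )

    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        with open(out, "w") as fh:
            json.dump(records, fh, indent=2)
    else:
        with open(out, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_RESULT_COLUMNS)
            w.writeheader()
            for rec in records:
                w.writerow({**rec, "components": json.dumps(rec["components"])})
    return out
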