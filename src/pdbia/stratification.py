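"""Map five Hoehn & Yahr stages onto the three-stage model.

Mild = H&Y I-II, moderate = H&Y III, advanced = H&Y IV-V.  Stage-V
patients are non-ambulatory and cannot wear the gait sensor, so the
monitorable fraction of a population is 1 minus its stage-V share.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from ._util import PortfolioError, round_half_away
from .parameters_io import (
    BUNDLED_HY_COUNTS,
    HY_STAGES,
    STAGES,
    Stage,
    StageDistribution,
)


class HYTable(BaseModel):
    """Diagnosed patient counts by Hoehn & Yahr stage for one region."""

    model_config = ConfigDict(frozen=True)

    region: str
    counts: Mapping[str, int]

    @model_validator(mode="after")
    def _check(self) -> "HYTable":
        if set(self.counts) != set(HY_STAGES):
            raise PortfolioError(f"{self.region}: counts must cover exactly stages {HY_STAGES}")
        if any(v < 0 for v in self.counts.values()):
            raise PortfolioError(f"{self.region}: negative stage count")
        return self

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def bundled_hy_tables() -> list[HYTable]:
    """The bundled 2016 prevalence table, one entry per reported region."""
    return [HYTable(region=r, counts=c) for r, c in BUNDLED_HY_COUNTS.items()]


def stage_proportions_from_hy(hy: HYTable) -> StageDistribution:
    """Collapse a five-stage table into mild/moderate/advanced shares."""
    total = hy.total
    if total <= 0:
        raise PortfolioError(f"{hy.region}: cannot derive a stage distribution from zero patients")
    return StageDistribution(
        mild=(hy.counts["I"] + hy.counts["II"]) / total,
        moderate=hy.counts["III"] / total,
        advanced=(hy.counts["IV"] + hy.counts["V"]) / total,
    )


def monitorable_fraction(tables: Sequence[HYTable]) -> float:
    """Fraction of patients the device can monitor, pooled over regions.

    Only H&Y V patients (non-ambulatory) are excluded:
    ``1 - sum(stage V) / sum(all stages)``.
    """
    if not tables:
        raise PortfolioError("monitorable_fraction needs at least one H&Y table")
    grand = sum(t.total for t in tables)
    if grand <= 0:
        raise PortfolioError("pooled patient total is zero")
    stage_v = sum(t.counts["V"] for t in tables)
    return 1.0 - stage_v / grand


class StratifiedCounts(BaseModel):
    """Per-stage patient counts: exact real values plus display integers."""

    model_config = ConfigDict(frozen=True)

    unrounded: Mapping[Stage, float]
    display: Mapping[Stage, int]


def stratify_total(total: float, dist: StageDistribution) -> StratifiedCounts:
    """Split a national total into per-stage counts.

    Mild and moderate counts are ``total x share``; the advanced count is
    the residual so the three unrounded values sum to the input total
    exactly.  Display values are rounded half-away-from-zero.
    """
    if total < 0:
        raise PortfolioError(f"negative population total {total}")
    mild = total * dist.mild
    moderate = total * dist.moderate
    advanced = total - (mild + moderate)  # residual: the three sum to total
    unrounded: dict[Stage, float] = {"mild": mild, "moderate": moderate, "advanced": advanced}
    return StratifiedCounts(
        unrounded=unrounded,
        display={s: round_half_away(unrounded[s]) for s in STAGES},
    )


def read_hy_tables_csv(path: str | Path) -> list[HYTable]:
    """Read H&Y tables from a CSV with columns region,I,II,III,IV,V."""
    tables = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"region", *HY_STAGES}
        if set(reader.fieldnames or ()) != expected:
            raise PortfolioError(f"{path}: expected columns {sorted(expected)}, got {reader.fieldnames}")
        for row in reader:
            tables.append(
                HYTable(region=row["region"], counts={s: int(row[s]) for s in HY_STAGES})
            )
    return tables
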