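"""Estimated daily intakes, margin of exposure and concern tiers.

Exposure enters as population-specific estimated daily intakes (EDI,
ng/kg-bw/day) of each chemical via dust ingestion, taken as point medians
per (region, age group).  The margin of exposure compares a health-based
guidance dose with the exposure dose:

    MOE = HED / EDI          (HED converted mg → ng before dividing)

and is classified into three concern tiers: high (MOE ≤ 1), moderate
(1 < MOE < 100) and low (MOE ≥ 100).  Because the HED is a population
distribution while the EDI is a point value, the assessment is
probabilistic: MOE percentiles inherit the HED percentile ranks, and the
three conventional interval bands (P2.5–P97.5, P1–P99, P0.1–P99.9) are
reported with per-rank tiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .ivive import HEDDistribution

logger = logging.getLogger(__name__)

EDI_COLUMNS = ["region", "age_group", "chemical_id", "edi_ng_kg_day", "reference"]

MG_TO_NG = 1e6

TIERS = ("high", "moderate", "low")

#: the three interval bands reported per assessment, as (low rank, high rank)
INTERVAL_BANDS = {
    "P2.5-P97.5": (2.5, 97.5),
    "P1-P99": (1.0, 99.0),
    "P0.1-P99.9": (0.1, 99.9),
}


class ExposureError(ValueError):
    """Malformed EDI table or mismatched assessment inputs."""


@dataclass(frozen=True)
class EDIRecord:
    """Median estimated daily intake for one (region, age group, chemical)."""

    region: str
    age_group: str
    chemical_id: str
    edi_median: float  # ng/kg-bw/day
    reference: str = ""

    def __post_init__(self) -> None:
        if not self.edi_median > 0:
            raise ExposureError(
                f"EDI must be positive, got {self.edi_median!r} "
                f"({self.region}, {self.age_group}, {self.chemical_id})"
            )


@dataclass(frozen=True)
class MOEAssessment:
    """Percentile MOEs, tiers and interval bands for one population × chemical."""

    region: str
    age_group: str
    chemical_id: str
    edi_median: float
    moe_percentiles: Mapping[float, float]
    tier_per_percentile: Mapping[float, str]
    intervals: Mapping[str, tuple[float, float]]


def read_edi_table(path: str | Path) -> list[EDIRecord]:
    """Read a long-format EDI CSV (columns :data:`EDI_COLUMNS`).

    Cells recorded as "-" (intake not reported for that group) are skipped
    with a log note.  Duplicate (region, age_group, chemical) keys are an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EDI_COLUMNS if c not in df.columns]
    if missing:
        raise ExposureError(f"{path}: missing column(s) {missing}")
    records: list[EDIRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = row.edi_ng_kg_day.strip()
        if raw in {"-", ""}:
            logger.info(
                "skipping row %d: EDI not reported for (%s, %s, %s)",
                i, row.region, row.age_group, row.chemical_id,
            )
            continue
        try:
            edi = float(raw)
        except ValueError:
            raise ExposureError(
                f"{path}: non-numeric EDI {raw!r} in row {i}"
            ) from None
        key = (row.region, row.age_group, row.chemical_id)
        if key in seen:
            raise ExposureError(f"{path}: duplicate EDI record for {key} (row {i})")
        seen.add(key)
        records.append(
            EDIRecord(
                region=row.region,
                age_group=row.age_group,
                chemical_id=row.chemical_id,
                edi_median=edi,
                reference=row.reference,
            )
        )
    return records


def moe_point(hed: float, edi: float) -> float:
    """Margin of exposure for a point HED (mg/kg/day) and EDI (ng/kg/day)."""
    if not hed > 0:
        raise ExposureError(f"HED must be positive, got {hed}")
    if not edi > 0:
        raise ExposureError(f"EDI must be positive, got {edi}")
    return hed * MG_TO_NG / edi


def classify_moe(moe: float) -> str:
    """Concern tier: high (MOE ≤ 1), moderate (1 < MOE < 100), low (MOE ≥ 100)."""
    if not moe > 0:
        raise ExposureError(f"MOE must be positive, got {moe}")
    if moe <= 1.0:
        return "high"
    if moe < 100.0:
        return "moderate"
    return "low"


def probabilistic_assessment(hed: HEDDistribution, edi: EDIRecord) -> MOEAssessment:
    """Percentile-wise MOE for one HED distribution against one EDI median.

    The MOE at rank p is ``moe_point(HED percentile p, EDI)``: low HED
    percentiles map to low MOE percentiles, so the MOE percentiles are
    monotone nondecreasing in rank.  Interval bands are assembled from the
    available ranks (a band is omitted when its ranks were not computed).
    """
    if hed.chemical_id != edi.chemical_id or hed.age_group != edi.age_group:
        raise ExposureError(
            f"mismatched assessment inputs: HED ({hed.chemical_id}, {hed.age_group}) "
            f"vs EDI ({edi.chemical_id}, {edi.age_group})"
        )
    moe_percentiles = {
        rank: moe_point(value, edi.edi_median)
        for rank, value in sorted(hed.percentiles.items())
    }
    tiers = {rank: classify_moe(moe) for rank, moe in moe_percentiles.items()}
    intervals = {
        name: (moe_percentiles[lo], moe_percentiles[hi])
        for name, (lo, hi) in INTERVAL_BANDS.items()
        if lo in moe_percentiles and hi in moe_percentiles
    }
    return MOEAssessment(
        region=edi.region,
        age_group=edi.age_group,
        chemical_id=edi.chemical_id,
        edi_median=edi.edi_median,
        moe_percentiles=moe_percentiles,
        tier_per_percentile=tiers,
        intervals=intervals,
    )
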