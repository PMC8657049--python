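"""In vitro hepatocyte assay records and cytotoxicity filtering.

High-throughput screening programmes report, for each assay, the activity
concentration causing 50% of the maximum response (AC50, in μM) together
with a chemical-specific cytotoxicity limit.  Assays whose AC50 lies at or
above the cytotoxicity limit may reflect cell death rather than the nominal
biological target, so risk assessment keeps only assays with AC50 strictly
below the limit.

Animal points of departure (NOAEL/LOAEL, mg/kg/day) with their dosimetric
adjustment factors are read here as well; they feed the animal-based human
equivalent dose for comparison with the in vitro route.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

ASSAY_COLUMNS = [
    "assay_name",
    "chemical_id",
    "ac50_uM",
    "cytotox_limit_uM",
    "biological_target",
]

POD_COLUMNS = [
    "chemical_id",
    "pod_mg_per_kg_day",
    "pod_type",
    "daf",
    "effect_label",
]

POD_TYPES = frozenset({"NOAEL", "LOAEL"})


class AssayTableError(ValueError):
    """Malformed assay or point-of-departure table."""


@dataclass(frozen=True)
class AssayRecord:
    """One in vitro assay: AC50 and cytotoxicity limit in μM."""

    assay_name: str
    chemical_id: str
    ac50: float
    cytotox_limit: float
    biological_target: str = ""

    def __post_init__(self) -> None:
        if not self.assay_name:
            raise AssayTableError("assay_name must be nonempty")
        if not self.chemical_id:
            raise AssayTableError("chemical_id must be nonempty")
        if not self.ac50 > 0:
            raise AssayTableError(
                f"AC50 must be positive, got {self.ac50!r} for {self.assay_name}"
            )
        if not self.cytotox_limit > 0:
            raise AssayTableError(
                f"cytotoxicity limit must be positive, got {self.cytotox_limit!r} "
                f"for {self.assay_name}"
            )


@dataclass(frozen=True)
class AnimalPOD:
    """Animal point of departure (mg/kg/day) with dosimetric adjustment factor.

    The dosimetric adjustment factor (DAF) is the dimensionless allometric
    factor that converts an animal dose to a human-equivalent dose.
    """

    chemical_id: str
    pod_value: float
    pod_type: str
    daf: float
    effect_label: str = ""

    def __post_init__(self) -> None:
        if not self.pod_value > 0:
            raise AssayTableError(f"POD must be positive, got {self.pod_value!r}")
        if self.pod_type not in POD_TYPES:
            raise AssayTableError(
                f"pod_type must be one of {sorted(POD_TYPES)}, got {self.pod_type!r}"
            )
        if not 0 < self.daf <= 1:
            raise AssayTableError(f"DAF must lie in (0, 1], got {self.daf!r}")


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise AssayTableError(f"{path}: missing column(s) {missing}")


def _parse_positive_float(value, row: int, column: str, path: Path) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise AssayTableError(
            f"{path}: non-numeric value {value!r} in row {row}, column {column!r}"
        ) from None
    if out != out:  # NaN (empty cell)
        raise AssayTableError(
            f"{path}: non-numeric value {value!r} in row {row}, column {column!r}"
        )
    return out


def read_assay_table(path: str | Path) -> list[AssayRecord]:
    """Read a CSV of assay records (columns :data:`ASSAY_COLUMNS`).

    Row numbers in error messages are 1-based over data rows (the header
    is row 0).  Assay names must be unique within each chemical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ASSAY_COLUMNS, path)
    records: list[AssayRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        ac50 = _parse_positive_float(row.ac50_uM, i, "ac50_uM", path)
        limit = _parse_positive_float(row.cytotox_limit_uM, i, "cytotox_limit_uM", path)
        rec = AssayRecord(
            assay_name=row.assay_name,
            chemical_id=row.chemical_id,
            ac50=ac50,
            cytotox_limit=limit,
            biological_target=row.biological_target,
        )
        key = (rec.chemical_id, rec.assay_name)
        if key in seen:
            raise AssayTableError(
                f"{path}: duplicate assay {rec.assay_name!r} for chemical "
                f"{rec.chemical_id!r} (row {i})"
            )
        seen.add(key)
        records.append(rec)
    return records


def read_pod_table(path: str | Path) -> list[AnimalPOD]:
    """Read a CSV of animal points of departure (columns :data:`POD_COLUMNS`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, POD_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pod = _parse_positive_float(row.pod_mg_per_kg_day, i, "pod_mg_per_kg_day", path)
        daf = _parse_positive_float(row.daf, i, "daf", path)
        records.append(
            AnimalPOD(
                chemical_id=row.chemical_id,
                pod_value=pod,
                pod_type=row.pod_type,
                daf=daf,
                effect_label=row.effect_label,
            )
        )
    return records


def filter_by_cytotoxicity(records: list[AssayRecord]) -> list[AssayRecord]:
    """Keep assays whose AC50 is strictly below the cytotoxicity limit.

    Ties (AC50 == limit) are dropped: an assay responding only at the
    concentration that kills the cells carries no target-specific signal.
    Order is preserved; records are returned unmodified.
    """
    return [r for r in records if r.ac50 < r.cytotox_limit]
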