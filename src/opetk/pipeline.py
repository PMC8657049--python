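"""End-to-end orchestration: assays → population → Css → HED → MOE.

One run covers every (chemical × age group) with a single Monte Carlo
population per pair: all per-assay HEDs, the pooled overall HED and every
regional MOE assessment for that pair derive from the same Css draw, so
the percentile tables are statistically consistent with each other.

Outputs: an assay-by-assay HED percentile table (assay rows plus an
"overall" row per chemical and age group), a long-format MOE table (one
row per region × age group × chemical × percentile rank), a JSON summary
and a log recording the seed, population size and every fixture constant's
provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .assays import AnimalPOD, AssayRecord, filter_by_cytotoxicity, read_assay_table, read_pod_table
from .exposure import EDIRecord, MOEAssessment, probabilistic_assessment, read_edi_table
from .ivive import HED_RANKS, HEDDistribution, OVERALL_LABEL, animal_hed, hed_from_assay, merge_assays
from .pbtk import Chemical, CssDistribution, population_css
from .population import PopulationSpec, apply_chemical, sample_population, spec_from_config

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage of the analysis failed; the message names the stage."""


@dataclass
class RunConfig:
    """File-level configuration of one full analysis run."""

    assay_table: Path
    pod_table: Path
    edi_table: Path
    chemical_configs: Sequence[Path]
    population_configs: Mapping[str, Path]
    out_dir: Path
    n: int = 1000
    seed: int = 0
    dose_ref: float = 1.0  # mg/kg/day reference dose for Css prediction
    ranks: Sequence[float] = HED_RANKS

    def __post_init__(self) -> None:
        ranks = sorted(float(r) for r in self.ranks)
        if ranks != list(self.ranks) or any(not 0 < r < 100 for r in ranks):
            raise PipelineError("percentile ranks must be sorted and within (0, 100)")
        for path in [self.assay_table, self.pod_table, self.edi_table,
                     *self.chemical_configs, *self.population_configs.values()]:
            if not Path(path).exists():
                raise PipelineError(f"configured input does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            p = Path(p)
            return p if p.is_absolute() else base / p

        return cls(
            assay_table=resolve(raw["assay_table"]),
            pod_table=resolve(raw["pod_table"]),
            edi_table=resolve(raw["edi_table"]),
            chemical_configs=[resolve(p) for p in raw["chemical_configs"]],
            population_configs={k: resolve(p) for k, p in raw["population_configs"].items()},
            out_dir=resolve(raw.get("out_dir", "results")),
            n=int(raw.get("n", 1000)),
            seed=int(raw.get("seed", 0)),
            dose_ref=float(raw.get("dose_ref", 1.0)),
            ranks=tuple(raw.get("ranks", HED_RANKS)),
        )


@dataclass
class PipelineResult:
    """In-memory results of one run, keyed by (chemical_id, age_group)."""

    css: dict[tuple[str, str], CssDistribution]
    heds: dict[tuple[str, str], dict[str, HEDDistribution]]
    animal_heds: dict[str, float]
    assessments: list[MOEAssessment]
    seed: int
    n: int
    hed_table: pd.DataFrame = field(default=None)
    moe_table: pd.DataFrame = field(default=None)


def _derived_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


def run_analysis(
    chemicals: Mapping[str, Chemical],
    population_specs: Mapping[str, PopulationSpec],
    assay_table: Sequence[AssayRecord],
    pod_table: Sequence[AnimalPOD],
    edi_table: Sequence[EDIRecord],
    n: int = 1000,
    seed: int = 0,
    dose_ref: float = 1.0,
    ranks: Sequence[float] = HED_RANKS,
) -> PipelineResult:
    """Run the full in-memory analysis (no file I/O)."""
    surviving = filter_by_cytotoxicity(list(assay_table))
    logger.info(
        "cytotoxicity filter: %d of %d assays retained", len(surviving), len(assay_table)
    )
    css: dict[tuple[str, str], CssDistribution] = {}
    heds: dict[tuple[str, str], dict[str, HEDDistribution]] = {}
    combos = [
        (chem_id, age)
        for chem_id in sorted(chemicals)
        for age in sorted(population_specs)
    ]
    for idx, (chem_id, age) in enumerate(combos):
        chemical = chemicals[chem_id]
        spec = replace(
            apply_chemical(population_specs[age], chemical),
            n=n,
            seed=_derived_seed(seed, idx),
        )
        try:
            population = sample_population(spec)
            dist = population_css(
                population, chemical, dose=dose_ref, age_group=age, ranks=ranks
            )
        except Exception as err:
            raise PipelineError(
                f"Css stage failed for chemical={chem_id}, age_group={age}: {err}"
            ) from err
        css[(chem_id, age)] = dist
        per_assay: dict[str, HEDDistribution] = {}
        for assay in surviving:
            if assay.chemical_id != chem_id:
                continue
            per_assay[assay.assay_name] = hed_from_assay(assay, dist, ranks=ranks)
        if not per_assay:
            raise PipelineError(f"no surviving assays for chemical={chem_id}")
        per_assay[OVERALL_LABEL] = merge_assays(list(per_assay.values()), ranks=ranks)
        heds[(chem_id, age)] = per_assay
        logger.info(
            "chemical=%s age_group=%s: median Css %.4g uM, overall median HED %.4g mg/kg/day",
            chem_id, age, dist.median, per_assay[OVERALL_LABEL].median,
        )

    animal = {}
    for pod in pod_table:
        animal[pod.chemical_id] = animal_hed(pod)
        logger.info("animal-based HED for %s: %.4g mg/kg/day", pod.chemical_id, animal[pod.chemical_id])

    assessments = []
    for edi in edi_table:
        key = (edi.chemical_id, edi.age_group)
        if key not in heds:
            logger.info("no HED distribution for EDI record %s; skipped", edi)
            continue
        try:
            assessments.append(
                probabilistic_assessment(heds[key][OVERALL_LABEL], edi)
            )
        except Exception as err:
            raise PipelineError(
                f"MOE stage failed for region={edi.region}, chemical={edi.chemical_id}, "
                f"age_group={edi.age_group}: {err}"
            ) from err

    result = PipelineResult(
        css=css, heds=heds, animal_heds=animal, assessments=assessments,
        seed=seed, n=n,
    )
    result.hed_table = _hed_table(result)
    result.moe_table = _moe_table(result)
    return result


def _fmt_interval(dist: HEDDistribution) -> str:
    return f"{dist.percentiles[50.0]:.3f}({dist.percentiles[2.5]:.3f}~{dist.percentiles[97.5]:.3f})"


def _hed_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for (chem_id, age), per_assay in sorted(result.heds.items()):
        for assay_name, dist in per_assay.items():
            rows.append(
                {
                    "chemical_id": chem_id,
                    "age_group": age,
                    "assay_name": assay_name,
                    "hed_median": dist.percentiles[50.0],
                    "hed_p2.5": dist.percentiles[2.5],
                    "hed_p97.5": dist.percentiles[97.5],
                    "summary": _fmt_interval(dist),
                }
            )
    return pd.DataFrame(rows)


def _moe_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for a in result.assessments:
        for rank, moe in a.moe_percentiles.items():
            rows.append(
                {
                    "region": a.region,
                    "age_group": a.age_group,
                    "chemical_id": a.chemical_id,
                    "edi_ng_kg_day": a.edi_median,
                    "rank": rank,
                    "moe": moe,
                    "tier": a.tier_per_percentile[rank],
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-driven run: read inputs, execute, write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("opetk")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("seed=%d n=%d dose_ref=%g mg/kg/day", config.seed, config.n, config.dose_ref)
        for item, source in fixtures.PROVENANCE.items():
            logger.info("constant group %s: provenance=%s", item, source)
        assay_table = read_assay_table(config.assay_table)
        pod_table = read_pod_table(config.pod_table)
        edi_table = read_edi_table(config.edi_table)
        chemicals = {}
        for path in config.chemical_configs:
            chem = fixtures.read_chemical(path)
            chemicals[chem.chemical_id] = chem
        population_specs = {}
        for age, path in config.population_configs.items():
            with open(path) as fh:
                population_specs[age] = spec_from_config(yaml.safe_load(fh))
        result = run_analysis(
            chemicals,
            population_specs,
            assay_table,
            pod_table,
            edi_table,
            n=config.n,
            seed=config.seed,
            dose_ref=config.dose_ref,
            ranks=config.ranks,
        )
        result.hed_table.to_csv(out_dir / "hed_table.csv", index=False)
        result.moe_table.to_csv(out_dir / "moe_assessments.csv", index=False)
        summary = {
            "seed": config.seed,
            "n": config.n,
            "dose_ref_mg_kg_day": config.dose_ref,
            "css_median_uM": {
                f"{chem}/{age}": dist.median for (chem, age), dist in result.css.items()
            },
            "overall_hed_percentiles_mg_kg_day": {
                f"{chem}/{age}": per_assay[OVERALL_LABEL].percentiles
                for (chem, age), per_assay in result.heds.items()
            },
            "animal_hed_mg_kg_day": result.animal_heds,
            "n_assessments": len(result.assessments),
        }
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        logger.info("wrote hed_table.csv, moe_assessments.csv, summary.json")
        return result
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def run_from_fixtures(
    seed: int = 0,
    n: int = 1000,
    calibrate: bool = True,
    ranks: Sequence[float] = HED_RANKS,
) -> PipelineResult:
    """Convenience: build the fixture bundle and run the analysis in memory."""
    bundle = fixtures.make_fixture_bundle(seed=seed, calibrate=calibrate, n=n)
    return run_analysis(
        bundle.chemicals,
        bundle.population_specs,
        bundle.assay_table,
        bundle.pod_table,
        bundle.edi_table,
        n=n,
        seed=seed,
        ranks=ranks,
    )
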