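"""Reverse dosimetry: AC50 → human equivalent dose (HED) distributions.

With a population of liver steady-state concentrations Css (μM) predicted
at a unit reference dose (1 mg/kg/day), the external dose expected to put
the liver at an in vitro point of departure AC50 is, by linearity of the
toxicokinetic model,

    HED (mg/kg/day) = AC50 (μM) × dose_ref (mg/kg/day) / Css (μM).

Applying this per Monte Carlo sample yields a population HED distribution;
the p-th HED percentile corresponds to the (100 − p)-th Css percentile
through the reciprocal transform.  HEDs across several assays are merged
by pooling their samples into one "overall" distribution.  An animal-based
HED, for comparison, is the animal point of departure scaled by the
dosimetric adjustment factor: HED = POD × DAF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assays import AnimalPOD, AssayRecord
from .pbtk import CssDistribution

#: default percentile ranks for HED summaries
HED_RANKS = (0.1, 1.0, 2.5, 25.0, 50.0, 75.0, 97.5, 99.0, 99.9)

#: below this sample count the extreme tail ranks (P0.1 / P99.9) depend
#: strongly on the percentile estimator
_TAIL_RANK_MIN_N = 5000

OVERALL_LABEL = "overall"


class IVIVEError(ValueError):
    """Mismatched inputs in the reverse-dosimetry step."""


@dataclass
class HEDDistribution:
    """Population HED samples (mg/kg/day) for one assay or the pooled set."""

    chemical_id: str
    age_group: str
    assay_name: str
    samples: np.ndarray
    percentiles: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise IVIVEError("HEDDistribution requires at least one sample")
        if not np.all(self.samples > 0):
            raise IVIVEError("HED samples must all be positive")
        if not self.percentiles:
            self.percentiles = self.percentile_summary(HED_RANKS)

    def percentile_summary(self, ranks: Sequence[float]) -> dict[float, float]:
        if self.samples.size < _TAIL_RANK_MIN_N and any(
            r < 1.0 or r > 99.0 for r in ranks
        ):
            warnings.warn(
                f"extreme percentile ranks requested with only "
                f"{self.samples.size} samples; P0.1/P99.9 are estimator-sensitive",
                stacklevel=2,
            )
        values = np.percentile(self.samples, ranks)  # linear interpolation
        return {float(r): float(v) for r, v in zip(ranks, values)}

    @property
    def median(self) -> float:
        return float(np.median(self.samples))


def hed_from_assay(
    assay: AssayRecord,
    css: CssDistribution,
    ranks: Sequence[float] = HED_RANKS,
) -> HEDDistribution:
    """Per-sample reverse dosimetry for one assay.

    ``HED_i = AC50 × dose_ref / Css_i`` over the population's Css samples.
    """
    if assay.chemical_id != css.chemical_id:
        raise IVIVEError(
            f"chemical mismatch: assay {assay.chemical_id!r} vs Css {css.chemical_id!r}"
        )
    samples = assay.ac50 * css.dose_ref / css.samples
    dist = HEDDistribution(
        chemical_id=assay.chemical_id,
        age_group=css.age_group,
        assay_name=assay.assay_name,
        samples=samples,
    )
    dist.percentiles = dist.percentile_summary(ranks)
    return dist


def hed_from_css_percentiles(
    ac50: float,
    css_percentiles: Mapping[float, float],
    dose_ref: float = 1.0,
) -> dict[float, float]:
    """HED percentiles from a printed Css percentile summary.

    Convenience pathway when only summary Css percentiles are available:
    the HED at rank p is ``AC50 × dose_ref / Css(100 − p)`` (the
    reciprocal transform reverses rank order).  Requires the summary to
    contain the complementary rank for every requested one.
    """
    if not ac50 > 0 or not dose_ref > 0:
        raise IVIVEError("ac50 and dose_ref must be positive")
    out: dict[float, float] = {}
    for rank, _ in css_percentiles.items():
        complement = 100.0 - rank
        if complement not in css_percentiles:
            raise IVIVEError(f"Css summary lacks complementary rank {complement} for {rank}")
        out[float(complement)] = ac50 * dose_ref / float(css_percentiles[rank])
    return out


def merge_assays(
    heds: Sequence[HEDDistribution],
    ranks: Sequence[float] = HED_RANKS,
    method: str = "pool",
) -> HEDDistribution:
    """Combine per-assay HED distributions into one "overall" distribution.

    Default method pools all samples with equal weight per assay (equal
    sample counts are enforced), so the overall median can fall between
    the per-assay medians.  ``method="median_of_ranks"`` instead takes,
    at every rank, the median across assays of that rank's percentile
    (a summary-level alternative, not the default).
    """
    if len(heds) == 0:
        raise IVIVEError("merge_assays requires at least one distribution")
    first = heds[0]
    for h in heds[1:]:
        if h.chemical_id != first.chemical_id or h.age_group != first.age_group:
            raise IVIVEError(
                "cannot merge distributions across chemicals or age groups: "
                f"({h.chemical_id}, {h.age_group}) vs ({first.chemical_id}, {first.age_group})"
            )
        if h.samples.size != first.samples.size:
            raise IVIVEError(
                "pooled merge requires equal sample counts per assay "
                f"({h.samples.size} vs {first.samples.size})"
            )
    if method == "pool":
        pooled = np.concatenate([h.samples for h in heds])
        dist = HEDDistribution(
            chemical_id=first.chemical_id,
            age_group=first.age_group,
            assay_name=OVERALL_LABEL,
            samples=pooled,
        )
        dist.percentiles = dist.percentile_summary(ranks)
        return dist
    if method == "median_of_ranks":
        pooled = np.concatenate([h.samples for h in heds])
        dist = HEDDistribution(
            chemical_id=first.chemical_id,
            age_group=first.age_group,
            assay_name=OVERALL_LABEL,
            samples=pooled,
        )
        dist.percentiles = {
            float(r): float(np.median([np.percentile(h.samples, r) for h in heds]))
            for r in ranks
        }
        return dist
    raise IVIVEError(f"unknown merge method {method!r}")


def animal_hed(pod: AnimalPOD) -> float:
    """Animal-based human equivalent dose: POD × DAF (mg/kg/day)."""
    return pod.pod_value * pod.daf
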