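"""Monte Carlo virtual populations of children and adults.

The toxicokinetic model is driven by per-individual physiology: body
weight, liver mass, hepatocyte density, blood flows, glomerular filtration
rate, plus the two chemical-specific disposition parameters — fraction
unbound in plasma (fub) and intrinsic hepatic clearance (Clint).  A
:class:`PopulationSpec` describes each parameter with a small parametric
distribution; :func:`sample_population` draws a reproducible population
from it.

This sampler is a documented parametric stand-in for survey-based
population generators: sizes are lognormal, flows and glomerular
filtration scale allometrically with body weight (BW^0.75), liver mass
scales linearly with body weight, and the rest-of-body blood flow is the
residual of cardiac output so that flows balance by construction.

Children (0–18 y) and adults (18–79 y) are modelled as two groups.  The
children's defaults carry a relatively larger liver and a higher intrinsic
metabolic rate per hepatocyte mass, giving the higher per-kilogram
clearance (and hence lower steady-state liver concentrations at a
per-kilogram dose) expected for the young.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .pbtk import Chemical

DISTRIBUTION_FAMILIES = ("lognormal", "normal", "fixed")

#: Parameters every spec must describe.  ``body_weight`` kg; ``liver_fraction``
#: kg liver per kg body weight; ``hepatocellularity`` 10^6 cells per g liver;
#: ``cardiac_output_ref`` L/h at the allometric reference body weight;
#: ``gfr_ref`` L/h at the reference body weight; ``fub`` dimensionless (0, 1];
#: ``clint`` μL/min per 10^6 hepatocytes.
REQUIRED_PARAMETERS = (
    "body_weight",
    "liver_fraction",
    "hepatocellularity",
    "cardiac_output_ref",
    "gfr_ref",
    "fub",
    "clint",
)

AGE_GROUPS = ("children", "adults")

#: Upper validity bound per parameter (lower bound is 0, exclusive, for all).
_UPPER_BOUNDS = {"fub": 1.0, "liver_fraction": 0.2}

_MAX_REDRAWS = 100


class PopulationSpecError(ValueError):
    """Invalid population specification or sampling failure."""


@dataclass(frozen=True)
class Distribution:
    """One-parameter-family descriptor.

    lognormal: location = geometric mean, scale = sigma of ln(x).
    normal:    location = mean, scale = s.d.; draws truncated to validity
               bounds by redraw.
    fixed:     location, scale must be 0.
    """

    family: str
    location: float
    scale: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in DISTRIBUTION_FAMILIES:
            raise PopulationSpecError(f"unknown distribution family {self.family!r}")
        if self.scale < 0:
            raise PopulationSpecError(f"scale must be ≥ 0, got {self.scale}")
        if self.family == "fixed" and self.scale != 0:
            raise PopulationSpecError("fixed distributions must have scale = 0")
        if not self.location > 0:
            raise PopulationSpecError(f"location must be positive, got {self.location}")


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one age group's virtual population."""

    age_group: str
    n: int
    seed: int
    distributions: Mapping[str, Distribution]
    #: fractions of cardiac output perfusing each sampled compartment; the
    #: rest-of-body flow is the residual 1 - sum(fractions).
    flow_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"hepatic_artery": 0.065, "gut": 0.19, "kidney": 0.19}
    )
    #: allometric reference body weight (kg) for flows and GFR.
    bw_ref: float = 70.0
    #: multiplier applied to a chemical's default Clint when a spec is
    #: re-targeted to that chemical (children > 1: faster metabolism).
    metabolic_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise PopulationSpecError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}"
            )
        if self.n < 1:
            raise PopulationSpecError(f"n must be ≥ 1, got {self.n}")
        missing = [p for p in REQUIRED_PARAMETERS if p not in self.distributions]
        if missing:
            raise PopulationSpecError(f"missing distribution(s) for {missing}")
        frac_sum = sum(self.flow_fractions.values())
        if not 0 < frac_sum < 1:
            raise PopulationSpecError(
                f"flow fractions must sum to (0, 1); got {frac_sum}"
            )
        if not self.bw_ref > 0 or not self.metabolic_multiplier > 0:
            raise PopulationSpecError("bw_ref and metabolic_multiplier must be positive")


@dataclass(frozen=True)
class Individual:
    """One sampled set of physiological + chemical disposition parameters.

    ``blood_flows`` holds L/h for hepatic_artery, gut (portal), kidney,
    lung (= cardiac output) and rest; liver inflow is hepatic_artery + gut.
    """

    body_weight: float  # kg
    liver_mass: float  # kg
    hepatocellularity: float  # 10^6 cells / g liver
    blood_flows: Mapping[str, float]  # L/h
    gfr: float  # L/h
    fub: float  # (0, 1]
    clint: float  # μL/min/10^6 cells

    def __post_init__(self) -> None:
        for name, v in (
            ("body_weight", self.body_weight),
            ("liver_mass", self.liver_mass),
            ("hepatocellularity", self.hepatocellularity),
            ("gfr", self.gfr),
            ("fub", self.fub),
            ("clint", self.clint),
        ):
            if not v > 0:
                raise PopulationSpecError(f"{name} must be positive, got {v}")
        if self.fub > 1:
            raise PopulationSpecError(f"fub must be ≤ 1, got {self.fub}")
        q = self.blood_flows
        resid = q["lung"] - (q["hepatic_artery"] + q["gut"] + q["kidney"] + q["rest"])
        if abs(resid) > 1e-9 * q["lung"]:
            raise PopulationSpecError(f"blood flows do not balance (residual {resid})")


def _draw(rng: np.random.Generator, dist: Distribution, n: int, name: str) -> np.ndarray:
    lo, hi = 0.0, _UPPER_BOUNDS.get(name, math.inf)
    if dist.family == "fixed":
        values = np.full(n, dist.location)
        if not (values[0] > lo and values[0] <= hi):
            raise PopulationSpecError(f"fixed value for {name} outside ({lo}, {hi}]")
        return values

    def sample(size: int) -> np.ndarray:
        if dist.family == "lognormal":
            return dist.location * np.exp(rng.normal(0.0, dist.scale, size))
        return rng.normal(dist.location, dist.scale, size)

    values = sample(n)
    for _ in range(_MAX_REDRAWS):
        bad = ~((values > lo) & (values <= hi))
        if not bad.any():
            return values
        values[bad] = sample(int(bad.sum()))
    raise PopulationSpecError(
        f"could not draw valid values for {name} within {_MAX_REDRAWS} redraws "
        f"(family={dist.family}, location={dist.location}, scale={dist.scale})"
    )


def sample_population(spec: PopulationSpec) -> list[Individual]:
    """Draw ``spec.n`` individuals; a pure function of the spec (incl. seed).

    Flows and GFR scale as (BW / bw_ref)^0.75 on top of their sampled
    reference values; liver mass is the sampled liver fraction times body
    weight; rest-of-body flow is the residual of cardiac output.
    """
    rng = np.random.default_rng(spec.seed)
    draws = {
        name: _draw(rng, spec.distributions[name], spec.n, name)
        for name in REQUIRED_PARAMETERS
    }
    bw = draws["body_weight"]
    allo = (bw / spec.bw_ref) ** 0.75
    co = draws["cardiac_output_ref"] * allo
    gfr = draws["gfr_ref"] * allo
    liver_mass = draws["liver_fraction"] * bw
    f = spec.flow_fractions
    individuals = []
    for i in range(spec.n):
        q_ha = f["hepatic_artery"] * co[i]
        q_gut = f["gut"] * co[i]
        q_kid = f["kidney"] * co[i]
        flows = {
            "hepatic_artery": q_ha,
            "gut": q_gut,
            "kidney": q_kid,
            "rest": co[i] - q_ha - q_gut - q_kid,
            "lung": co[i],
        }
        individuals.append(
            Individual(
                body_weight=float(bw[i]),
                liver_mass=float(liver_mass[i]),
                hepatocellularity=float(draws["hepatocellularity"][i]),
                blood_flows={k: float(v) for k, v in flows.items()},
                gfr=float(gfr[i]),
                fub=float(draws["fub"][i]),
                clint=float(draws["clint"][i]),
            )
        )
    return individuals


# Generic (chemical-neutral) disposition defaults used by default_spec();
# apply_chemical() replaces them with a chemical's own values.
_GENERIC_CLINT = 10.0  # μL/min/10^6 cells
_GENERIC_FUB = 0.1

#: Children metabolise these esters faster per unit hepatocyte mass.
_CHILD_METABOLIC_MULTIPLIER = 2.0


def default_spec(age_group: str, n: int = 1000, seed: int = 0) -> PopulationSpec:
    """Shipped fixture spec for one age group.

    Geometric means: adults 70 kg / liver 2.6% of body weight; children
    27 kg / liver 3.4%.  Cardiac output 336 L/h and GFR 7.5 L/h at the
    70 kg reference, hepatocellularity 110×10^6 cells/g for both groups.
    Children's Clint location carries the metabolic multiplier.
    """
    if age_group not in AGE_GROUPS:
        raise PopulationSpecError(
            f"age_group must be one of {AGE_GROUPS}, got {age_group!r}"
        )
    child = age_group == "children"
    mult = _CHILD_METABOLIC_MULTIPLIER if child else 1.0
    ln = lambda gsd: math.log(gsd)  # noqa: E731 - sigma of ln(x) from GSD
    distributions = {
        "body_weight": Distribution("lognormal", 27.0 if child else 70.0,
                                    ln(1.6) if child else ln(1.2)),
        "liver_fraction": Distribution("lognormal", 0.034 if child else 0.026, ln(1.1)),
        "hepatocellularity": Distribution("lognormal", 110.0, ln(1.15)),
        "cardiac_output_ref": Distribution("lognormal", 336.0, ln(1.2)),
        "gfr_ref": Distribution("lognormal", 7.5, ln(1.2)),
        "fub": Distribution("lognormal", _GENERIC_FUB, ln(1.2)),
        "clint": Distribution("lognormal", _GENERIC_CLINT * mult, ln(2.0)),
    }
    return PopulationSpec(
        age_group=age_group,
        n=n,
        seed=seed,
        distributions=distributions,
        metabolic_multiplier=mult,
    )


def apply_chemical(spec: PopulationSpec, chemical: "Chemical") -> PopulationSpec:
    """Re-target a spec's fub/Clint locations to a specific chemical.

    The chemical's default Clint is multiplied by the spec's metabolic
    multiplier (age-group effect); distribution spreads are kept.
    """
    dists = dict(spec.distributions)
    dists["fub"] = replace(dists["fub"], location=chemical.fub_default)
    dists["clint"] = replace(
        dists["clint"], location=chemical.clint_default * spec.metabolic_multiplier
    )
    return replace(spec, distributions=dists)


def spec_to_config(spec: PopulationSpec) -> dict:
    """Plain-dict form of a spec (for YAML round-trips)."""
    return {
        "age_group": spec.age_group,
        "n": spec.n,
        "seed": spec.seed,
        "bw_ref": spec.bw_ref,
        "metabolic_multiplier": spec.metabolic_multiplier,
        "flow_fractions": dict(spec.flow_fractions),
        "distributions": {
            name: {"family": d.family, "location": d.location, "scale": d.scale}
            for name, d in spec.distributions.items()
        },
    }


def spec_from_config(config: Mapping) -> PopulationSpec:
    """Inverse of :func:`spec_to_config`."""
    return PopulationSpec(
        age_group=config["age_group"],
        n=int(config["n"]),
        seed=int(config["seed"]),
        distributions={
            name: Distribution(**d) for name, d in config["distributions"].items()
        },
        flow_fractions=dict(config["flow_fractions"]),
        bw_ref=float(config["bw_ref"]),
        metabolic_multiplier=float(config["metabolic_multiplier"]),
    )
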