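"""Seven-compartment flow-limited toxicokinetic model, oral route.

Compartments: gut, liver, lung, arterial blood, venous blood, kidney and a
lumped "rest of body".  The chemical enters the gut at a constant rate (the
chronic daily dose averaged over 24 h), reaches the liver via the portal
flow, and is eliminated by hepatic metabolism (well-stirred liver) and
renal filtration.  Tissue partitioning is flow-limited: the concentration
leaving a tissue is the tissue concentration divided by its tissue:plasma
partition coefficient.

For a constant input the system is linear, ``dx/dt = A x + b`` in amount
space, and the steady state is the solution of ``A x* = -b``.  An
independent ODE-integration route (:func:`integrate_to_steady_state`)
serves as a numerical cross-check of the analytic solve.

Units: amounts mg, volumes L, flows L/h, clearances L/h, time h.  Liver
steady-state concentration is reported in μM (mg/L × 1000 / MW).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .population import Individual

COMPARTMENTS = ("gut", "liver", "lung", "arteries", "veins", "kidney", "rest")
_IDX = {c: i for i, c in enumerate(COMPARTMENTS)}

#: Tissue volumes as fractions of body weight (body density taken as 1 kg/L);
#: liver volume comes from the individual's sampled liver mass instead, and
#: "rest" absorbs the remainder of the body volume.
VOLUME_FRACTIONS = {
    "gut": 0.017,
    "lung": 0.008,
    "arteries": 0.02,
    "veins": 0.045,
    "kidney": 0.0044,
}

LIVER_DENSITY = 1.05  # kg/L

#: Partition-coefficient keys a Chemical must provide (blood pools are 1).
PERFUSED_TISSUES = ("gut", "liver", "lung", "kidney", "rest")

#: default percentile ranks summarising a population Css distribution
CSS_RANKS = (2.5, 25.0, 50.0, 75.0, 97.5)


class PBTKError(ValueError):
    """Invalid model parameterisation or an unstable/singular system."""


@dataclass(frozen=True)
class Chemical:
    """Chemical-specific model inputs.

    ``clint_default`` (μL/min/10^6 hepatocytes) and ``fub_default`` seed the
    population sampler; per-individual values override them.  Partition
    coefficients are tissue:plasma ratios; ``fabs`` is the oral fraction
    absorbed.
    """

    chemical_id: str
    name: str
    molecular_weight: float  # g/mol
    clint_default: float
    fub_default: float
    partition_coefficients: Mapping[str, float]
    fabs: float = 1.0

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise PBTKError(f"molecular weight must be positive, got {self.molecular_weight}")
        missing = [t for t in PERFUSED_TISSUES if t not in self.partition_coefficients]
        if missing:
            raise PBTKError(f"missing partition coefficient(s) for {missing}")
        for tissue, k in self.partition_coefficients.items():
            if not k > 0:
                raise PBTKError(f"partition coefficient for {tissue} must be positive, got {k}")
        if not 0 < self.fabs <= 1:
            raise PBTKError(f"fabs must lie in (0, 1], got {self.fabs}")
        if not self.clint_default >= 0 or not 0 <= self.fub_default <= 1:
            raise PBTKError("clint_default must be ≥ 0 and fub_default in [0, 1]")


@dataclass(frozen=True)
class PBTKParameters:
    """Fully scaled per-individual, per-chemical model coefficients."""

    individual: Individual
    chemical: Chemical
    volumes: Mapping[str, float]  # L
    flows: Mapping[str, float]  # L/h
    clint_whole_liver: float  # L/h, fub-free intrinsic scale
    cl_hepatic: float  # L/h, well-stirred whole-body hepatic clearance
    cl_renal: float  # L/h, GFR × fub
    dose_rate: float  # mg/h entering the gut (fabs already applied)


@dataclass(frozen=True)
class CssResult:
    css_liver: float  # μM
    css_plasma: float  # μM (venous)
    method: str  # "analytic" | "ode"


@dataclass
class CssDistribution:
    """Population liver steady-state concentrations at a reference dose."""

    chemical_id: str
    age_group: str
    dose_ref: float  # mg/kg/day
    samples: np.ndarray  # μM
    percentiles: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise PBTKError("CssDistribution requires at least one sample")
        if not np.all(self.samples > 0):
            raise PBTKError("Css samples must all be positive")
        if not self.percentiles:
            self.percentiles = self.percentile_summary(CSS_RANKS)

    def percentile_summary(self, ranks: Sequence[float]) -> dict[float, float]:
        values = np.percentile(self.samples, ranks)
        return {float(r): float(v) for r, v in zip(ranks, values)}

    @property
    def median(self) -> float:
        return float(np.median(self.samples))


def scale_clearances(
    individual: Individual, chemical: Chemical, dose: float = 1.0
) -> PBTKParameters:
    """Scale in vitro clearance to the whole body and assemble coefficients.

    Whole-liver intrinsic clearance converts μL/min per 10^6 cells to L/h:
    ``Clint × hepatocellularity (10^6 cells/g) × liver mass (g) × 60e-6``.
    Hepatic clearance follows the well-stirred model
    ``CL_h = Q_h · fub · CLint_whole / (Q_h + fub · CLint_whole)``;
    renal clearance is glomerular filtration of unbound chemical,
    ``CL_r = GFR × fub``.  ``dose`` is mg/kg/day.
    """
    if not individual.liver_mass > 0:
        raise PBTKError("liver mass must be positive")
    q_h = individual.blood_flows["hepatic_artery"] + individual.blood_flows["gut"]
    if not q_h > 0:
        raise PBTKError("hepatic blood flow must be positive")
    if dose < 0:
        raise PBTKError(f"dose must be ≥ 0, got {dose}")

    liver_g = individual.liver_mass * 1000.0
    clint_whole = individual.clint * individual.hepatocellularity * liver_g * 60e-6
    fu_cl = individual.fub * clint_whole
    cl_hepatic = 0.0 if fu_cl == 0 else q_h * fu_cl / (q_h + fu_cl)
    cl_renal = individual.gfr * individual.fub

    bw = individual.body_weight
    volumes = {t: f * bw for t, f in VOLUME_FRACTIONS.items()}
    volumes["liver"] = individual.liver_mass / LIVER_DENSITY
    v_rest = bw - sum(volumes.values())
    if not v_rest > 0:
        raise PBTKError("rest-of-body volume is nonpositive; check liver mass")
    volumes["rest"] = v_rest

    dose_rate = chemical.fabs * dose * bw / 24.0  # mg/h into gut
    return PBTKParameters(
        individual=individual,
        chemical=chemical,
        volumes=volumes,
        flows=dict(individual.blood_flows),
        clint_whole_liver=clint_whole,
        cl_hepatic=cl_hepatic,
        cl_renal=cl_renal,
        dose_rate=dose_rate,
    )


def system_matrix(params: PBTKParameters) -> tuple[np.ndarray, np.ndarray]:
    """Linear system ``dx/dt = A x + b`` in amounts (mg) over COMPARTMENTS.

    Hepatic elimination acts on the liver's plasma-equivalent concentration
    with rate ``fub × CLint_whole`` (this reproduces the well-stirred
    clearance at steady state); renal elimination acts on the kidney's
    plasma-equivalent concentration with ``CL_r = GFR × fub``.
    """
    q = params.flows
    v = params.volumes
    k = params.chemical.partition_coefficients
    fub = params.individual.fub

    # reciprocal of (volume × partition coefficient): amount → plasma-equivalent conc
    r = {t: 1.0 / (v[t] * k[t]) for t in PERFUSED_TISSUES}
    r["arteries"] = 1.0 / v["arteries"]
    r["veins"] = 1.0 / v["veins"]

    q_liv = q["hepatic_artery"] + q["gut"]
    A = np.zeros((7, 7))
    i = _IDX

    # gut: arterial inflow, venous-side outflow to liver (portal)
    A[i["gut"], i["arteries"]] += q["gut"] * r["arteries"]
    A[i["gut"], i["gut"]] -= q["gut"] * r["gut"]
    # liver: hepatic artery + portal inflow, outflow to veins, metabolism
    A[i["liver"], i["arteries"]] += q["hepatic_artery"] * r["arteries"]
    A[i["liver"], i["gut"]] += q["gut"] * r["gut"]
    A[i["liver"], i["liver"]] -= (q_liv + fub * params.clint_whole_liver) * r["liver"]
    # lung: venous inflow at cardiac output, outflow to arteries
    A[i["lung"], i["veins"]] += q["lung"] * r["veins"]
    A[i["lung"], i["lung"]] -= q["lung"] * r["lung"]
    # arteries: from lung, distributed to tissues (sum of flows = cardiac output)
    A[i["arteries"], i["lung"]] += q["lung"] * r["lung"]
    A[i["arteries"], i["arteries"]] -= q["lung"] * r["arteries"]
    # veins: collect liver, kidney, rest; send to lung
    A[i["veins"], i["liver"]] += q_liv * r["liver"]
    A[i["veins"], i["kidney"]] += q["kidney"] * r["kidney"]
    A[i["veins"], i["rest"]] += q["rest"] * r["rest"]
    A[i["veins"], i["veins"]] -= q["lung"] * r["veins"]
    # kidney: arterial inflow, venous outflow, glomerular filtration
    A[i["kidney"], i["arteries"]] += q["kidney"] * r["arteries"]
    A[i["kidney"], i["kidney"]] -= (q["kidney"] + params.cl_renal) * r["kidney"]
    # rest of body
    A[i["rest"], i["arteries"]] += q["rest"] * r["arteries"]
    A[i["rest"], i["rest"]] -= q["rest"] * r["rest"]

    b = np.zeros(7)
    b[i["gut"]] = params.dose_rate
    return A, b


def _check_stable(A: np.ndarray) -> None:
    eig = np.linalg.eigvals(A)
    worst = eig[np.argmax(eig.real)]
    if worst.real >= 0:
        raise PBTKError(f"system matrix is not stable: eigenvalue {worst} has nonnegative real part")


def _to_uM(conc_mg_per_L: float, molecular_weight: float) -> float:
    return conc_mg_per_L * 1000.0 / molecular_weight


def steady_state_css(params: PBTKParameters, check_stability: bool = True) -> CssResult:
    """Analytic steady state of the linear system under constant oral input.

    Returns liver total tissue concentration and venous plasma
    concentration, both in μM.  Css scales linearly with the dose.
    """
    A, b = system_matrix(params)
    if check_stability:
        _check_stable(A)
    try:
        x = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError as err:
        raise PBTKError(f"singular system matrix: {err}") from err
    mw = params.chemical.molecular_weight
    css_liver = _to_uM(x[_IDX["liver"]] / params.volumes["liver"], mw)
    css_plasma = _to_uM(x[_IDX["veins"]] / params.volumes["veins"], mw)
    return CssResult(css_liver=css_liver, css_plasma=css_plasma, method="analytic")


def _rhs(params: PBTKParameters):
    """Explicit per-compartment balance equations (independent of system_matrix)."""
    q = params.flows
    v = params.volumes
    k = params.chemical.partition_coefficients
    fub = params.individual.fub
    q_liv = q["hepatic_artery"] + q["gut"]
    cl_met = fub * params.clint_whole_liver
    cl_ren = params.cl_renal
    rate_in = params.dose_rate
    i = _IDX

    def f(_t, x):
        c_art = x[i["arteries"]] / v["arteries"]
        c_ven = x[i["veins"]] / v["veins"]
        cp_gut = x[i["gut"]] / (v["gut"] * k["gut"])
        cp_liv = x[i["liver"]] / (v["liver"] * k["liver"])
        cp_lung = x[i["lung"]] / (v["lung"] * k["lung"])
        cp_kid = x[i["kidney"]] / (v["kidney"] * k["kidney"])
        cp_rest = x[i["rest"]] / (v["rest"] * k["rest"])
        dx = np.empty(7)
        dx[i["gut"]] = rate_in + q["gut"] * c_art - q["gut"] * cp_gut
        dx[i["liver"]] = (
            q["hepatic_artery"] * c_art + q["gut"] * cp_gut
            - q_liv * cp_liv - cl_met * cp_liv
        )
        dx[i["lung"]] = q["lung"] * c_ven - q["lung"] * cp_lung
        dx[i["arteries"]] = q["lung"] * cp_lung - q["lung"] * c_art
        dx[i["veins"]] = (
            q_liv * cp_liv + q["kidney"] * cp_kid + q["rest"] * cp_rest
            - q["lung"] * c_ven
        )
        dx[i["kidney"]] = q["kidney"] * c_art - (q["kidney"] + cl_ren) * cp_kid
        dx[i["rest"]] = q["rest"] * c_art - q["rest"] * cp_rest
        return dx

    return f


def mass_balance_residual(params: PBTKParameters, x: np.ndarray) -> float:
    """|d(total)/dt − (input − elimination)| relative to the input rate.

    Conservation check: the only source is the gut input, the only sinks
    are hepatic metabolism and renal filtration.
    """
    f = _rhs(params)
    dx = f(0.0, np.asarray(x, float))
    v, k = params.volumes, params.chemical.partition_coefficients
    cp_liv = x[_IDX["liver"]] / (v["liver"] * k["liver"])
    cp_kid = x[_IDX["kidney"]] / (v["kidney"] * k["kidney"])
    eliminated = (
        params.individual.fub * params.clint_whole_liver * cp_liv
        + params.cl_renal * cp_kid
    )
    expected = params.dose_rate - eliminated
    scale = max(abs(params.dose_rate), abs(eliminated), 1e-300)
    return float(abs(dx.sum() - expected) / scale)


def integrate_to_steady_state(
    params: PBTKParameters,
    rel_tol: float = 1e-3,
    max_days: int = 10_000,
) -> CssResult:
    """Integrate from zero amounts until the liver concentration settles.

    Convergence: relative change of liver concentration over one simulated
    day falls below ``rel_tol``.  Raises on failure within ``max_days``.
    """
    if not rel_tol > 0:
        raise PBTKError(f"rel_tol must be positive, got {rel_tol}")
    f = _rhs(params)
    x = np.zeros(7)
    prev = None
    day = 24.0
    t = 0.0
    while t < max_days * 24.0:
        sol = solve_ivp(f, (t, t + day), x, method="Radau", rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise PBTKError(f"ODE integration failed at t={t} h: {sol.message}")
        x = sol.y[:, -1]
        t += day
        c_liver = x[_IDX["liver"]] / params.volumes["liver"]
        if prev is not None:
            if params.dose_rate == 0 or (
                c_liver > 0 and abs(c_liver - prev) / c_liver < rel_tol
            ):
                mw = params.chemical.molecular_weight
                return CssResult(
                    css_liver=_to_uM(c_liver, mw),
                    css_plasma=_to_uM(x[_IDX["veins"]] / params.volumes["veins"], mw),
                    method="ode",
                )
        prev = c_liver
    raise PBTKError(f"no steady state within {max_days} days (liver conc {prev} mg/L)")


def population_css(
    population: Sequence[Individual],
    chemical: Chemical,
    dose: float = 1.0,
    age_group: str = "",
    ranks: Sequence[float] = CSS_RANKS,
) -> CssDistribution:
    """Analytic liver Css for every individual at ``dose`` mg/kg/day.

    Solves the stacked linear systems in one batched call; stability is
    checked on the batch (any eigenvalue with nonnegative real part fails
    with the individual's index).
    """
    if len(population) == 0:
        raise PBTKError("population must be nonempty")
    mats = np.empty((len(population), 7, 7))
    rhs = np.empty((len(population), 7))
    liver_volumes = np.empty(len(population))
    for j, ind in enumerate(population):
        params = scale_clearances(ind, chemical, dose)
        A, b = system_matrix(params)
        mats[j], rhs[j] = A, b
        liver_volumes[j] = params.volumes["liver"]
    eigs = np.linalg.eigvals(mats)
    unstable = np.nonzero(eigs.real.max(axis=1) >= 0)[0]
    if unstable.size:
        j = int(unstable[0])
        raise PBTKError(f"individual {j}: unstable system (eigenvalues {eigs[j]})")
    try:
        x = np.linalg.solve(mats, -rhs[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as err:
        raise PBTKError(f"singular system in population solve: {err}") from err
    samples = x[:, _IDX["liver"]] / liver_volumes * 1000.0 / chemical.molecular_weight
    dist = CssDistribution(
        chemical_id=chemical.chemical_id,
        age_group=age_group,
        dose_ref=dose,
        samples=samples,
    )
    dist.percentiles = dist.percentile_summary(ranks)
    return dist
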