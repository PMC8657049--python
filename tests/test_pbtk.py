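"""Toxicokinetic model: clearance scaling, steady state, ODE cross-check."""

import numpy as np
import pytest

from opetk.fixtures import _CHEMICALS
from opetk.pbtk import (
    Chemical,
    PBTKError,
    _check_stable,
    integrate_to_steady_state,
    mass_balance_residual,
    population_css,
    scale_clearances,
    steady_state_css,
    system_matrix,
)
from opetk.population import Individual, apply_chemical, default_spec, sample_population

TPHP = _CHEMICALS["TPHP"]
TDCPP = _CHEMICALS["TDCPP"]


def make_individual(
    bw=70.0, liver=1.8, hep=110.0, co=336.0, gfr=7.5, fub=0.05, clint=10.0,
    f_ha=0.065, f_gut=0.19, f_kid=0.19,
):
    q_ha, q_gut, q_kid = f_ha * co, f_gut * co, f_kid * co
    return Individual(
        body_weight=bw,
        liver_mass=liver,
        hepatocellularity=hep,
        blood_flows={
            "hepatic_artery": q_ha,
            "gut": q_gut,
            "kidney": q_kid,
            "rest": co - q_ha - q_gut - q_kid,
            "lung": co,
        },
        gfr=gfr,
        fub=fub,
        clint=clint,
    )


def test_clearance_scaling_matches_stepwise_hand_calculation():
    # Q_h = (0.065 + 0.19) * 352.94... pick flows so hepatic flow is exactly 90 L/h
    co = 90.0 / 0.255
    ind = make_individual(co=co, fub=0.05, clint=10.0, hep=110.0, liver=1.8)
    params = scale_clearances(ind, TPHP)
    # hand unit conversion: 10 uL/min/1e6 cells x 110e6 cells/g x 1800 g
    clint_ul_min = 10.0 * 110.0 * 1800.0
    clint_l_h = clint_ul_min / 1e6 * 60.0
    assert params.clint_whole_liver == pytest.approx(clint_l_h, rel=1e-12)
    fu_cl = 0.05 * clint_l_h
    expected = 90.0 * fu_cl / (90.0 + fu_cl)
    assert params.cl_hepatic == pytest.approx(expected, rel=1e-12)
    assert params.cl_renal == pytest.approx(7.5 * 0.05, rel=1e-12)


def test_well_stirred_bounds_and_limits():
    ind = make_individual(fub=1e-9)
    p = scale_clearances(ind, TPHP)
    q_h = ind.blood_flows["hepatic_artery"] + ind.blood_flows["gut"]
    assert p.cl_hepatic < ind.fub * p.clint_whole_liver
    assert p.cl_hepatic < q_h
    # nearly fully bound chemical is barely cleared
    assert p.cl_hepatic == pytest.approx(ind.fub * p.clint_whole_liver, rel=1e-3)
    # flow-limited asymptote: enormous intrinsic clearance → CL_h → Q_h
    fast = scale_clearances(make_individual(clint=1e9), TPHP)
    assert fast.cl_hepatic == pytest.approx(q_h, rel=1e-5)


def test_zero_dose_steady_state_is_zero():
    params = scale_clearances(make_individual(), TPHP, dose=0.0)
    res = steady_state_css(params)
    assert res.css_liver == 0.0 and res.css_plasma == 0.0


def test_css_linear_in_dose():
    ind = make_individual()
    c1 = steady_state_css(scale_clearances(ind, TPHP, dose=1.0)).css_liver
    c2 = steady_state_css(scale_clearances(ind, TPHP, dose=2.0)).css_liver
    assert c2 == pytest.approx(2.0 * c1, rel=1e-12)


def test_css_micromolar_consistent_with_mg_per_L():
    # identical chemistry except molecular weight: uM concentration scales as 1/MW
    ind = make_individual()
    heavy = Chemical(
        "X", "x", molecular_weight=2 * TPHP.molecular_weight,
        clint_default=TPHP.clint_default, fub_default=TPHP.fub_default,
        partition_coefficients=TPHP.partition_coefficients,
    )
    c_light = steady_state_css(scale_clearances(ind, TPHP)).css_liver
    c_heavy = steady_state_css(scale_clearances(ind, heavy)).css_liver
    assert c_light == pytest.approx(2.0 * c_heavy, rel=1e-12)


def test_css_monotone_decreasing_in_clearance():
    base = steady_state_css(scale_clearances(make_individual(clint=5.0), TPHP)).css_liver
    faster = steady_state_css(scale_clearances(make_individual(clint=50.0), TPHP)).css_liver
    assert faster < base


def test_analytic_matches_ode_on_fixture_adult():
    params = scale_clearances(make_individual(), TPHP)
    analytic = steady_state_css(params)
    ode = integrate_to_steady_state(params, rel_tol=1e-5)
    assert ode.method == "ode"
    assert ode.css_liver == pytest.approx(analytic.css_liver, rel=1e-3)
    assert ode.css_plasma == pytest.approx(analytic.css_plasma, rel=1e-3)


def test_zero_dose_trajectory_identically_zero():
    params = scale_clearances(make_individual(), TDCPP, dose=0.0)
    res = integrate_to_steady_state(params)
    assert res.css_liver == 0.0 and res.css_plasma == 0.0


def test_mass_balance_residual_small_at_random_states():
    rng = np.random.default_rng(3)
    params = scale_clearances(make_individual(), TDCPP)
    for _ in range(10):
        x = rng.uniform(0.0, 50.0, size=7)
        assert mass_balance_residual(params, x) <= 1e-8


def test_rhs_consistent_with_system_matrix():
    # the explicit balance equations and the assembled matrix are two codings
    # of the same model: A x + b must equal the RHS everywhere
    from opetk.pbtk import _rhs

    params = scale_clearances(make_individual(), TPHP)
    A, b = system_matrix(params)
    f = _rhs(params)
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.uniform(0.0, 10.0, 7)
        assert np.allclose(A @ x + b, f(0.0, x), rtol=1e-12, atol=1e-12)


def test_stability_check_names_offending_eigenvalue():
    with pytest.raises(PBTKError, match="eigenvalue"):
        _check_stable(np.array([[1.0]]))


def test_population_css_degenerate_population_collapses():
    from opetk.population import Distribution, PopulationSpec

    base = default_spec("adults", n=5, seed=0)
    spec = PopulationSpec(
        "adults", 5, 0,
        {k: Distribution("fixed", d.location) for k, d in base.distributions.items()},
    )
    pop = sample_population(apply_chemical(spec, TPHP))
    dist = population_css(pop, TPHP, age_group="adults")
    single = steady_state_css(scale_clearances(pop[0], TPHP)).css_liver
    assert all(v == pytest.approx(single, rel=1e-12) for v in dist.percentiles.values())


def test_population_css_percentiles_monotone():
    pop = sample_population(apply_chemical(default_spec("adults", n=300, seed=2), TPHP))
    dist = population_css(pop, TPHP, age_group="adults")
    ranks = sorted(dist.percentiles)
    values = [dist.percentiles[r] for r in ranks]
    assert values == sorted(values)


def test_population_css_rejects_empty_population():
    with pytest.raises(PBTKError, match="nonempty"):
        population_css([], TPHP)
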