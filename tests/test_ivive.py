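"""Reverse dosimetry: Eq-of-motion from AC50 and Css to HED distributions."""

import numpy as np
import pytest

from opetk.assays import AnimalPOD, AssayRecord
from opetk.ivive import (
    IVIVEError,
    animal_hed,
    hed_from_assay,
    hed_from_css_percentiles,
    merge_assays,
)
from opetk.pbtk import CssDistribution


def css_dist(samples, chemical_id="TDCPP", age_group="adults"):
    return CssDistribution(
        chemical_id=chemical_id, age_group=age_group, dose_ref=1.0,
        samples=np.asarray(samples, float),
    )


def assay(ac50, chemical_id="TDCPP", name="a1"):
    return AssayRecord(name, chemical_id, ac50=ac50, cytotox_limit=1000.0)


@pytest.mark.parametrize(
    "ac50, css_median, expected",
    [
        (5.01, 58.66, 0.085),  # TDCPP, adult population
        (5.01, 25.34, 0.198),  # TDCPP, child population
        (1.26, 8.17, 0.154),  # TPHP, child population
        (5.43, 24.1, 0.225),  # TPHP, adult population
        (0.39, 58.66, 0.007),  # TDCPP, adult population
        (0.36, 25.34, 0.014),  # TDCPP, child population
    ],
)
def test_summary_pathway_reproduces_published_median_heds(ac50, css_median, expected):
    """HED = AC50 x 1 mg/kg/day / Css, at the published median Css values."""
    heds = hed_from_css_percentiles(ac50, {50.0: css_median})
    assert round(heds[50.0], 3) == expected


def test_summary_pathway_reverses_rank_order():
    # upper Css percentile -> lower HED percentile through the reciprocal
    summary = {2.5: 14.6, 50.0: 58.66, 97.5: 481.66}
    heds = hed_from_css_percentiles(5.01, summary)
    assert round(heds[2.5], 2) == 0.01  # 5.01 / 481.66
    assert round(heds[97.5], 3) == 0.343  # 5.01 / 14.6
    with pytest.raises(IVIVEError, match="complementary"):
        hed_from_css_percentiles(5.01, {2.5: 14.6, 50.0: 58.66})


def test_hed_identity_when_ac50_equals_css():
    css = css_dist([3.3] * 11)
    dist = hed_from_assay(assay(3.3), css)
    assert np.allclose(dist.samples, 1.0)


def test_hed_chemical_mismatch_rejected():
    with pytest.raises(IVIVEError, match="mismatch"):
        hed_from_assay(assay(1.0, chemical_id="TPHP"), css_dist([1.0, 2.0]))


def test_hed_median_maps_css_median_for_odd_counts():
    rng = np.random.default_rng(8)
    samples = rng.lognormal(2.0, 0.8, size=501)
    css = css_dist(samples)
    dist = hed_from_assay(assay(5.01), css)
    assert dist.median == pytest.approx(5.01 / np.median(samples), rel=1e-12)


def test_scale_equivariance_of_hed_percentiles():
    rng = np.random.default_rng(4)
    samples = rng.lognormal(3.0, 0.5, size=401)
    a, k = assay(2.0), 7.0
    base = hed_from_assay(a, css_dist(samples))
    scaled = hed_from_assay(a, css_dist(k * samples))
    for rank, value in base.percentiles.items():
        assert scaled.percentiles[rank] == pytest.approx(value / k, rel=1e-9)


def test_merge_single_distribution_is_identity():
    dist = hed_from_assay(assay(5.01), css_dist(np.linspace(10, 100, 101)))
    merged = merge_assays([dist])
    assert merged.assay_name == "overall"
    assert merged.percentiles == dist.percentiles


def test_merge_point_masses_bounds_overall_median():
    lo = hed_from_assay(assay(0.01, name="lo"), css_dist([1.0] * 10))
    hi = hed_from_assay(assay(1.0, name="hi"), css_dist([1.0] * 10))
    merged = merge_assays([lo, hi])
    assert 0.01 <= merged.percentiles[50.0] <= 1.0


def test_merge_rejects_mixed_chemicals_and_unequal_counts():
    a = hed_from_assay(assay(1.0, "TPHP"), css_dist([1.0, 2.0], chemical_id="TPHP"))
    b = hed_from_assay(assay(1.0, "TDCPP"), css_dist([1.0, 2.0], chemical_id="TDCPP"))
    with pytest.raises(IVIVEError, match="across chemicals"):
        merge_assays([a, b])
    c = hed_from_assay(assay(1.0, "TPHP"), css_dist([1.0, 2.0, 3.0], chemical_id="TPHP"))
    with pytest.raises(IVIVEError, match="equal sample counts"):
        merge_assays([a, c])


def test_merge_median_of_ranks_variant():
    rng = np.random.default_rng(1)
    dists = [
        hed_from_assay(assay(ac, name=f"a{i}"), css_dist(rng.lognormal(2, 0.4, 201)))
        for i, ac in enumerate([0.5, 1.0, 2.0])
    ]
    merged = merge_assays(dists, method="median_of_ranks")
    medians = sorted(d.percentiles[50.0] for d in dists)
    assert merged.percentiles[50.0] == pytest.approx(medians[1], rel=1e-9)
    with pytest.raises(IVIVEError, match="unknown merge method"):
        merge_assays(dists, method="bogus")


def test_extreme_tail_warning_below_sample_threshold():
    with pytest.warns(UserWarning, match="estimator-sensitive"):
        hed_from_assay(assay(1.0), css_dist(np.linspace(1, 10, 100)), ranks=(0.1, 50.0, 99.9))


@pytest.mark.parametrize(
    "pod, expected",
    [
        (AnimalPOD("TPHP", 105.0, "NOAEL", 0.24, "systemic"), 25.2),
        (AnimalPOD("TDCPP", 5.0, "LOAEL", 0.26, "renal"), 1.3),
        (AnimalPOD("X", 12.5, "NOAEL", 1.0, ""), 12.5),  # DAF = 1 identity
    ],
)
def test_animal_hed_is_pod_times_daf(pod, expected):
    assert animal_hed(pod) == pytest.approx(expected, rel=1e-12)
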