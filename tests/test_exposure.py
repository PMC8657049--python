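"""EDI tables, margin-of-exposure arithmetic and concern tiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opetk.exposure import (
    EDIRecord,
    ExposureError,
    classify_moe,
    moe_point,
    probabilistic_assessment,
    read_edi_table,
)
from opetk.ivive import HEDDistribution

HEADER = "region,age_group,chemical_id,edi_ng_kg_day,reference\n"


def hed_dist(samples, chemical_id="TDCPP", age_group="children"):
    return HEDDistribution(
        chemical_id=chemical_id, age_group=age_group, assay_name="overall",
        samples=np.asarray(samples, float),
        percentiles={},
    )


def test_read_edi_skips_dash_cells_and_keeps_reported_groups(tmp_path):
    path = tmp_path / "edi.csv"
    path.write_text(
        HEADER
        + "North China,adults,TPHP,0.42,B34\n"
        + "North China,children,TPHP,-,B34\n"
        + "North China,adults,TDCPP,0.33,B34\n"
        + "North China,children,TDCPP,-,B34\n"
    )
    records = read_edi_table(path)
    assert len(records) == 2
    assert {r.age_group for r in records} == {"adults"}


def test_read_edi_latvia_row(tmp_path):
    path = tmp_path / "edi.csv"
    path.write_text(
        HEADER
        + "Latvia,adults,TPHP,24,B11\n"
        + "Latvia,children,TPHP,560,B11\n"
        + "Latvia,adults,TDCPP,67.4,B11\n"
        + "Latvia,children,TDCPP,1570,B11\n"
    )
    records = read_edi_table(path)
    by_key = {(r.age_group, r.chemical_id): r.edi_median for r in records}
    assert by_key == {
        ("adults", "TPHP"): 24.0,
        ("children", "TPHP"): 560.0,
        ("adults", "TDCPP"): 67.4,
        ("children", "TDCPP"): 1570.0,
    }


def test_read_edi_empty_and_duplicate_and_bad_number(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text(HEADER)
    assert read_edi_table(empty) == []
    dup = tmp_path / "dup.csv"
    dup.write_text(HEADER + "A,adults,TPHP,1,x\nA,adults,TPHP,2,x\n")
    with pytest.raises(ExposureError, match="duplicate"):
        read_edi_table(dup)
    bad = tmp_path / "bad.csv"
    bad.write_text(HEADER + "A,adults,TPHP,abc,x\n")
    with pytest.raises(ExposureError, match="non-numeric"):
        read_edi_table(bad)


def test_moe_point_examples():
    # overall median HED for TDCPP children against the Latvian children EDI
    moe = moe_point(0.042, 1570.0)
    assert moe == pytest.approx(26.75, rel=1e-3)
    assert classify_moe(moe) == "moderate"
    # equal doses after unit conversion sit exactly on the high/moderate boundary
    assert moe_point(1e-6 * 1570.0, 1570.0) == pytest.approx(1.0)
    # animal-based TPHP HED against the Latvian adult EDI
    big = moe_point(25.2, 24.0)
    assert big == pytest.approx(1.05e6, rel=1e-9)
    assert classify_moe(big) == "low"
    with pytest.raises(ExposureError):
        moe_point(0.0, 1.0)
    with pytest.raises(ExposureError):
        moe_point(1.0, -2.0)


@pytest.mark.parametrize(
    "moe, tier",
    [(0.5, "high"), (1.0, "high"), (1.0000001, "moderate"), (99.999, "moderate"),
     (100.0, "low"), (1e9, "low")],
)
def test_tier_boundaries_exact(moe, tier):
    assert classify_moe(moe) == tier


@given(st.floats(min_value=1e-12, max_value=1e12))
@settings(deadline=None, derandomize=True)
def test_tier_function_is_a_partition(moe):
    tier = classify_moe(moe)
    assert tier in ("high", "moderate", "low")
    assert (tier == "high") == (moe <= 1.0)
    assert (tier == "low") == (moe >= 100.0)


def test_probabilistic_assessment_point_mass_collapses_intervals():
    hed = hed_dist([0.05] * 10)
    edi = EDIRecord("Latvia", "children", "TDCPP", 1570.0)
    a = probabilistic_assessment(hed, edi)
    moes = set(round(v, 12) for v in a.moe_percentiles.values())
    assert len(moes) == 1
    for lo, hi in a.intervals.values():
        assert lo == pytest.approx(hi)


def test_probabilistic_assessment_scales_inversely_with_edi():
    rng = np.random.default_rng(2)
    hed = hed_dist(rng.lognormal(-2, 0.5, 501))
    a1 = probabilistic_assessment(hed, EDIRecord("X", "children", "TDCPP", 10.0))
    a10 = probabilistic_assessment(hed, EDIRecord("X", "children", "TDCPP", 100.0))
    for rank, moe in a1.moe_percentiles.items():
        assert a10.moe_percentiles[rank] == pytest.approx(moe / 10.0, rel=1e-9)
        # larger EDI never increases any MOE percentile
        assert a10.moe_percentiles[rank] <= moe


def test_probabilistic_assessment_moe_monotone_in_rank():
    rng = np.random.default_rng(6)
    hed = hed_dist(rng.lognormal(-2, 0.8, 1001))
    a = probabilistic_assessment(hed, EDIRecord("X", "children", "TDCPP", 50.0))
    ranks = sorted(a.moe_percentiles)
    values = [a.moe_percentiles[r] for r in ranks]
    assert values == sorted(values)
    assert set(a.intervals) == {"P2.5-P97.5", "P1-P99", "P0.1-P99.9"}


def test_probabilistic_assessment_mismatch_rejected():
    hed = hed_dist([0.1] * 5, age_group="adults")
    with pytest.raises(ExposureError, match="mismatched"):
        probabilistic_assessment(hed, EDIRecord("X", "children", "TDCPP", 1.0))
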