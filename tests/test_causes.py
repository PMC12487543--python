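"""ICD-10 classification and garbage-code redistribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motomort.causes import (CauseMap, assign_period,
                             build_redistribution_probs, classify,
                             classify_table, redistribute)
from motomort.standards import ROAD_USER_GROUPS


@pytest.mark.parametrize("code,expected", [
    ("V23.4", "motorcyclist"),
    ("V234", "motorcyclist"),
    ("V20", "motorcyclist"),
    ("V39", "motorcyclist"),
    ("V03", "pedestrian"),
    ("V13", "bicyclist"),
    ("V43", "car_occupant"),
    ("V78", "other_rt"),
    ("V98", "other_rt"),
    ("V87", "partially_defined_rt"),
    ("V89", "partially_defined_rt"),
    ("V99", "partially_defined_rt"),
    ("X59", "ill_defined_external"),
    ("Y10", "ill_defined_external"),
    ("Y34", "ill_defined_external"),
    ("W10", "non_rt_external"),
    ("W74", "non_rt_external"),
    ("Y35", "non_rt_external"),
    ("v23", "motorcyclist"),          # case-insensitive
])
def test_classify(code, expected):
    assert classify(code) == expected


@pytest.mark.parametrize("bad", ["", "23", "V2", "VXX", "V23.45.6", "A00",
                                 "Z99", "R99"])
def test_classify_rejects_malformed_or_non_external(bad):
    with pytest.raises(ValueError):
        classify(bad)


@settings(deadline=None, derandomize=True)
@given(st.integers(1, 99), st.one_of(st.none(), st.integers(0, 9)))
def test_every_v_code_maps_to_exactly_one_road_traffic_class(num, sub):
    code = f"V{num:02d}" + ("" if sub is None else f".{sub}")
    cls = classify(code)
    assert cls in (*ROAD_USER_GROUPS, "partially_defined_rt")


def test_overlapping_prefix_sets_rejected():
    with pytest.raises(ValueError, match="V23"):
        CauseMap(pedestrian=frozenset({"V01", "V23"}))


def test_period_assignment_three_year_blocks_remainder_joined():
    years = pd.Series(range(2010, 2020))
    periods = assign_period(years, (2010, 2019), 3)
    assert list(periods) == [0, 0, 0, 1, 1, 1, 2, 2, 2, 2]


def _deaths(rows):
    return pd.DataFrame(rows, columns=["city_id", "country_id", "year", "sex",
                                       "age_group", "icd10_code", "n_deaths"])


def test_probs_proportional_to_specific_counts():
    d = _deaths([
        ("c1", "A", 2010, "M", "20-24", "V23", 30),
        ("c1", "A", 2010, "M", "20-24", "V03", 10),
        ("c1", "A", 2010, "M", "20-24", "V78", 10),
    ])
    probs = build_redistribution_probs(classify_table(d), year_range=(2010, 2019))
    p_rt, vec = probs.lookup("A", "M", "20-24", 0)
    assert vec == pytest.approx([0.6, 0.2, 0.0, 0.0, 0.2], abs=1e-12)
    assert vec.sum() == pytest.approx(1.0, abs=1e-12)


def test_backoff_to_coarser_margins_when_stratum_empty():
    d = _deaths([
        ("c1", "A", 2010, "M", "20-24", "V89", 5),    # garbage only here
        ("c1", "A", 2010, "M", "30-34", "V23", 8),    # specific elsewhere
        ("c1", "A", 2010, "M", "30-34", "V03", 2),
    ])
    probs = build_redistribution_probs(classify_table(d), year_range=(2010, 2019))
    _, vec = probs.lookup("A", "M", "20-24", 0)
    # falls back to the (country, sex) margin: 8/10 motorcyclist
    assert vec == pytest.approx([0.8, 0.2, 0, 0, 0], abs=1e-12)
    row = probs.table.loc[("A", "M", "20-24", 0)]
    assert row["backoff_level"] == 2


def test_probs_normalized_on_simulated_study(small_study_inputs):
    _, deaths, *_ = small_study_inputs
    probs = build_redistribution_probs(classify_table(deaths))
    vals = probs.table[list(ROAD_USER_GROUPS)].to_numpy(float)
    defined = ~np.isnan(vals[:, 0])
    assert np.allclose(vals[defined].sum(axis=1), 1.0, atol=1e-12)


def test_redistribute_degenerate_probabilities_deterministic():
    d = _deaths([
        ("c1", "A", 2010, "M", "20-24", "V23", 5),
        ("c1", "A", 2010, "M", "20-24", "V89", 10),
    ])
    cd = classify_table(d)
    probs = build_redistribution_probs(cd, year_range=(2010, 2019))
    counts, summaries = redistribute(cd, probs, n_draws=100, seed=3)
    # only motorcyclist observed -> probability 1, every draw adds exactly 10
    assert (counts.groupby("draw")["n_motorcyclist"].sum() == 15).all()


def test_no_garbage_draws_identical_to_observed():
    d = _deaths([
        ("c1", "A", 2010, "M", "20-24", "V23", 7),
        ("c1", "A", 2011, "F", "25-29", "V03", 3),
    ])
    cd = classify_table(d)
    probs = build_redistribution_probs(cd, year_range=(2010, 2019))
    counts, _ = redistribute(cd, probs, n_draws=5, seed=0)
    moto = counts.groupby("draw")["n_motorcyclist"].sum()
    assert (moto == 7).all()


def test_exact_conservation_every_draw(small_study_inputs):
    _, deaths, *_ = small_study_inputs
    cd = classify_table(deaths)
    probs = build_redistribution_probs(cd)
    counts, summaries = redistribute(cd, probs, n_draws=20, seed=9)
    garbage = int(cd.loc[cd.cause_class.isin(
        ["partially_defined_rt", "ill_defined_external"]), "n_deaths"].sum())
    observed_moto = int(cd.loc[cd.cause_class == "motorcyclist",
                               "n_deaths"].sum())
    for s in summaries:
        assert s["garbage_allocated"] + s["ill_to_non_rt"] == garbage
        assert s["motorcyclist_total"] >= observed_moto
    # redistributed counts never below the observed specific count, stratum-wise
    obs = (cd[cd.cause_class == "motorcyclist"]
           .groupby(["city_id", "sex", "age_group"])["n_deaths"].sum())
    for d_idx, sub in counts.groupby("draw"):
        merged = sub.set_index(["city_id", "sex", "age_group"])[
            "n_motorcyclist"].align(obs, fill_value=0)
        assert (merged[0] >= merged[1]).all()


def test_mean_allocation_converges_to_probability_share():
    # 20 partially-defined deaths, motorcyclist probability 0.6:
    # mean motorcyclist additions over 2000 draws within binomial tolerance
    d = _deaths([
        ("c1", "A", 2010, "M", "20-24", "V23", 30),
        ("c1", "A", 2010, "M", "20-24", "V03", 10),
        ("c1", "A", 2010, "M", "20-24", "V78", 10),
        ("c1", "A", 2010, "M", "20-24", "V89", 20),
    ])
    cd = classify_table(d)
    probs = build_redistribution_probs(cd, year_range=(2010, 2019))
    counts, _ = redistribute(cd, probs, n_draws=2000, seed=5)
    added = counts.groupby("draw")["n_motorcyclist"].sum() - 30
    assert 11.4 <= added.mean() <= 12.6


def test_higher_motorcyclist_share_never_lowers_expected_allocation():
    def expected_moto(moto_count):
        d = _deaths([
            ("c1", "A", 2010, "M", "20-24", "V23", moto_count),
            ("c1", "A", 2010, "M", "20-24", "V03", 10),
            ("c1", "A", 2010, "M", "20-24", "V89", 12),
        ])
        cd = classify_table(d)
        probs = build_redistribution_probs(cd, year_range=(2010, 2019))
        _, vec = probs.lookup("A", "M", "20-24", 0)
        return moto_count + 12 * vec[0]

    values = [expected_moto(m) for m in (0, 5, 10, 30, 100)]
    assert all(b >= a for a, b in zip(values, values[1:]))


def test_draw_reproducible_in_isolation():
    d = _deaths([
        ("c1", "A", 2010, "M", "20-24", "V23", 10),
        ("c1", "A", 2010, "M", "20-24", "V03", 10),
        ("c1", "A", 2010, "M", "20-24", "X59", 25),
        ("c1", "A", 2010, "M", "20-24", "W74", 40),
    ])
    cd = classify_table(d)
    probs = build_redistribution_probs(cd, year_range=(2010, 2019))
    c3, _ = redistribute(cd, probs, n_draws=3, seed=11)
    c5, _ = redistribute(cd, probs, n_draws=5, seed=11)
    pd.testing.assert_frame_equal(c3, c5[c5.draw <= 3].reset_index(drop=True))
    again, _ = redistribute(cd, probs, n_draws=3, seed=11)
    pd.testing.assert_frame_equal(c3, again)


def test_missing_probabilities_raise_hard_error():
    d = _deaths([("c1", "A", 2010, "M", "20-24", "V89", 4)])
    cd = classify_table(d)
    probs = build_redistribution_probs(cd, year_range=(2010, 2019))
    with pytest.raises(ValueError, match="conservation"):
        redistribute(cd, probs, n_draws=1, seed=0)


def test_single_stage_flag_sends_all_ill_defined_to_road_traffic():
    d = _deaths([
        ("c1", "A", 2010, "M", "20-24", "V23", 50),
        ("c1", "A", 2010, "M", "20-24", "X59", 10),
    ])
    cd = classify_table(d)
    probs = build_redistribution_probs(cd, year_range=(2010, 2019))
    counts, _ = redistribute(cd, probs, n_draws=10, seed=2, two_stage=False)
    assert (counts.groupby("draw")["n_motorcyclist"].sum() == 60).all()
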