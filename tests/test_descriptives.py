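"""Quartile tables, correlations, ICC and rate profiles."""

import numpy as np
import pandas as pd
import pytest

import motomort as mm
from motomort.descriptives import (assign_quartiles, correlation_bands,
                                   correlation_matrix, quartile_table,
                                   quartile_wald_p, rate_profiles,
                                   within_country_icc)


def test_quartile_sizes_differ_by_at_most_one():
    rng = np.random.default_rng(0)
    for n in (8, 100, 337, 341):
        q, _ = assign_quartiles(pd.Series(rng.lognormal(1, 0.6, n)))
        sizes = q.value_counts().sort_index().tolist()
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1
        assert sizes == [n // 4] * 3 + [n - 3 * (n // 4)]


def test_quartiles_refuse_fewer_than_eight_cities():
    with pytest.raises(ValueError, match=">= 8"):
        assign_quartiles(pd.Series([1.0] * 7))


def test_quartile_membership_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    rates = pd.Series(rng.lognormal(1, 0.8, 101))
    q1, _ = assign_quartiles(rates)
    q2, _ = assign_quartiles(np.log(rates))
    q3, _ = assign_quartiles(rates.rank())
    assert (q1 == q2).all() and (q1 == q3).all()


def test_identical_exposure_gives_p_one():
    q = np.repeat([1, 2, 3, 4], 25)
    assert quartile_wald_p(np.full(100, 3.7), q) == 1.0


def test_separated_exposure_gives_tiny_p():
    rng = np.random.default_rng(2)
    rates = pd.Series(np.sort(rng.lognormal(1, 0.6, 336)))
    expo = pd.DataFrame({"city_id": [f"c{i}" for i in range(336)],
                         "patch_density": np.linspace(0, 1, 336)
                         + 0.01 * rng.normal(size=336)})
    rates.index = expo["city_id"]
    tab = quartile_table(rates, expo, columns=["patch_density"])
    assert tab["wald_p"].iloc[0] < 0.001


def test_quartile_table_reports_sizes_and_binary_counts(small_study_inputs):
    exposures = small_study_inputs[0]
    rng = np.random.default_rng(3)
    rates = pd.Series(rng.lognormal(1, 0.5, len(exposures)),
                      index=exposures["city_id"])
    tab = quartile_table(rates, exposures)
    assert sum(tab.attrs["quartile_sizes"]) == len(exposures)
    transit = tab[tab.exposure == "transit_presence"].iloc[0]
    assert "%" in transit["q1"]


def test_correlation_of_column_with_itself_is_one(small_study_inputs):
    expo = small_study_inputs[0]
    corr = correlation_matrix(expo)
    assert np.allclose(np.diag(corr), 1.0)
    vals = corr.to_numpy()
    assert np.allclose(vals, vals.T, equal_nan=True)


def test_strong_generated_correlation_banded_strong():
    cfg = mm.SimulationConfig(
        n_countries=6, cities_per_country=50,
        exposure_corr={("patch_density", "intersection_density"): 0.7}, seed=1)
    corr = correlation_matrix(mm.generate_exposures(cfg))
    bands = correlation_bands(corr)
    row = bands[(bands.var1 == "patch_density")
                & (bands.var2 == "intersection_density")].iloc[0]
    assert row["band"] == "strong"


def test_independent_columns_rarely_reach_moderate():
    weak = 0
    total = 0
    for seed in range(10):
        cfg = mm.SimulationConfig(n_countries=6, cities_per_country=50,
                                  exposure_corr={}, seed=seed)
        bands = correlation_bands(correlation_matrix(mm.generate_exposures(cfg)))
        total += len(bands)
        weak += (bands["band"] == "weak").sum()
    assert weak / total >= 0.95


def test_zero_variance_column_reported_absent():
    df = pd.DataFrame({"city_id": list("abcd"),
                       "patch_density": [1.0, 2.0, 3.0, 4.0],
                       "circuity": [1.0, 1.0, 1.0, 1.0]})
    corr = correlation_matrix(df, columns=["patch_density", "circuity"])
    assert corr.loc["circuity"].isna().all()
    assert corr.loc["patch_density", "patch_density"] == 1.0


def test_icc_one_when_all_variation_is_between_countries():
    rates = [1.0, 1.0, 1.0, 5.0, 5.0, 5.0, 2.5, 2.5]
    countries = ["A"] * 3 + ["B"] * 3 + ["C"] * 2
    assert within_country_icc(rates, countries) == pytest.approx(1.0)


def test_icc_matches_hand_computed_anova_components():
    # balanced two-country fixture, natural scale
    y = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
    g = np.array(["A"] * 3 + ["B"] * 3)
    # by hand: group means 2 and 3, grand 2.5; SSB = 3*0.25*2 = 1.5;
    # SSW = 2 + 2 = 4; MSB = 1.5; MSW = 4/4 = 1; n0 = 3
    # s2b = (1.5 - 1)/3 = 1/6; ICC = (1/6)/(1/6 + 1)
    expected = (1 / 6) / (1 / 6 + 1)
    got = within_country_icc(y, g, log_scale=False)
    assert got == pytest.approx(expected, abs=1e-10)


def test_icc_near_zero_under_label_permutation():
    rng = np.random.default_rng(5)
    rates = rng.lognormal(1.0, 0.6, 120)
    countries = np.repeat([f"c{i}" for i in range(6)], 20)
    vals = []
    for _ in range(200):
        vals.append(within_country_icc(rates, rng.permutation(countries)))
    assert 0.0 <= min(vals)
    assert np.mean(vals) < 0.02


def test_icc_requires_multiple_countries():
    with pytest.raises(ValueError):
        within_country_icc([1.0, 2.0, 3.0], ["A", "A", "A"])


def test_icc_bounded_zero_one(small_study_inputs):
    exposures, deaths, population, factors, _ = small_study_inputs
    rng = np.random.default_rng(9)
    rates = rng.lognormal(1, 1.0, len(exposures))
    icc = within_country_icc(rates, exposures["country_id"])
    assert 0.0 <= icc <= 1.0


def test_peak_age_group_detection_and_tie_reporting():
    rows = []
    for sex in ("M", "F"):
        for a in mm.AGE_GROUPS:
            for city in ("x", "y"):
                rate = 10.0 if a == "20-24" else 1.0
                rows.append({"sex": sex, "age_group": a, "rate": rate})
    prof = rate_profiles(pd.DataFrame(rows))
    assert prof["peak_age_group"] == {"M": ["20-24"], "F": ["20-24"]}

    flat = pd.DataFrame([{"sex": "M", "age_group": a, "rate": 2.0}
                         for a in mm.AGE_GROUPS])
    prof2 = rate_profiles(flat)
    assert set(prof2["peak_age_group"]["M"]) == set(mm.AGE_GROUPS)


def test_male_female_ratio_in_configured_range(small_study, small_study_inputs):
    # generator sets an 8x male/female baseline; the pooled ratio of
    # draw-averaged rates should land near it
    _, _, population, factors, _ = small_study_inputs
    counts = mm.average_over_draws(small_study.counts_by_draw)
    py = small_study.person_years
    merged = counts.merge(py, on=["city_id", "country_id", "sex", "age_group"])
    rows = []
    for sex, sub in merged.groupby("sex"):
        rows.append({"sex": sex, "age_group": "all",
                     "rate": 1e5 * sub.n_motorcyclist.sum()
                     / sub.person_years.sum()})
    pooled = {r["sex"]: r["rate"] for r in rows}
    assert 7.0 <= pooled["M"] / pooled["F"] <= 10.0
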