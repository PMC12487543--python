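"""Synthetic study generator: correlations, count distributions, files."""

import numpy as np
import pandas as pd
import pytest

import motomort as mm
from motomort.config import build_correlation_matrix
from motomort.standards import AGE_GROUPS, BINARY_EXPOSURES, EXPOSURE_NAMES
from motomort.synthetic import (city_frame, emit_study_files,
                                generate_exposures, read_study_files)


def _corr_config(targets, n_countries=6, cities_per_country=50, seed=1):
    return mm.SimulationConfig(n_countries=n_countries,
                               cities_per_country=cities_per_country,
                               exposure_corr=targets, seed=seed)


def test_target_correlation_realized_within_band():
    cfg = _corr_config({("patch_density", "intersection_density"): 0.7})
    expo = generate_exposures(cfg)
    r = np.corrcoef(expo["patch_density"], expo["intersection_density"])[0, 1]
    assert 0.55 <= r <= 0.85


def test_identity_correlation_gives_near_independent_columns():
    cfg = _corr_config({})
    expo = generate_exposures(cfg)
    cont = [c for c in EXPOSURE_NAMES if c not in BINARY_EXPOSURES]
    corr = expo[cont].corr().to_numpy()
    off = corr[~np.eye(len(cont), dtype=bool)]
    assert np.abs(off).max() < 0.15


def test_non_psd_correlation_rejected_with_names():
    targets = {("patch_density", "intersection_density"): 0.9,
               ("intersection_density", "circuity"): 0.9,
               ("patch_density", "circuity"): -0.9}
    with pytest.raises(ValueError, match="positive semi-definite"):
        build_correlation_matrix(targets)


def test_single_city_is_a_valid_row():
    cfg = mm.SimulationConfig(n_countries=1, cities_per_country=1, seed=0)
    expo = generate_exposures(cfg)
    assert len(expo) == 1
    assert set(EXPOSURE_NAMES) <= set(expo.columns)


def test_no_corruption_yields_only_specific_codes_and_exact_totals():
    cfg = mm.SimulationConfig(n_countries=2, cities_per_country=4,
                              p_illdefined=0.0, completeness_range=(1.0, 1.0),
                              seed=3)
    expo = generate_exposures(cfg)
    deaths, _, truth = mm.generate_deaths(cfg, expo)
    assert not set(deaths["icd10_code"]) & {"V89", "X59"}
    assert int(deaths["n_deaths"].sum()) == sum(truth.true_totals.values())
    moto = deaths[deaths["icd10_code"] == "V23"]
    assert int(moto["n_deaths"].sum()) == truth.true_totals["motorcyclist"]


def test_garbage_and_thinning_preserve_nothing_but_expectations():
    # conservation before thinning: with completeness 1 the observed total
    # equals the true total even under heavy garbage coding
    cfg = mm.SimulationConfig(n_countries=2, cities_per_country=3,
                              p_illdefined=0.3, completeness_range=(1.0, 1.0),
                              seed=4)
    expo = generate_exposures(cfg)
    deaths, _, truth = mm.generate_deaths(cfg, expo)
    assert int(deaths["n_deaths"].sum()) == sum(truth.true_totals.values())


def _dispersion_ratio(alpha, seed=6):
    """Mean variance/mean ratio of stratum counts at equal expectations."""
    cfg = mm.SimulationConfig(
        n_countries=2, cities_per_country=40, beta={}, sigma_city=0.0,
        sigma_country=0.0, alpha_nb=alpha, p_illdefined=0.0,
        completeness_range=(1.0, 1.0), city_pop_sigma=0.0,
        city_pop_median=500_000, seed=seed)
    expo = generate_exposures(cfg)
    deaths, _, _ = mm.generate_deaths(cfg, expo)
    moto = deaths[deaths["icd10_code"] == "V23"]
    grid = (city_frame(cfg).merge(pd.DataFrame({"year": cfg.year_list}),
                                  how="cross"))
    ratios = []
    for (sex, age) in [("M", "20-24"), ("M", "25-29"), ("M", "30-34"),
                       ("M", "15-19")]:
        sub = moto[(moto.sex == sex) & (moto.age_group == age)]
        counts = (sub.set_index(["city_id", "year"])["n_deaths"]
                  .reindex(pd.MultiIndex.from_frame(grid[["city_id", "year"]]),
                           fill_value=0))
        ratios.append(counts.var(ddof=1) / counts.mean())
    return float(np.mean(ratios))


def test_poisson_limit_dispersion_near_one():
    assert _dispersion_ratio(1e-13) == pytest.approx(1.0, abs=0.12)


def test_dispersion_ratio_nondecreasing_in_alpha():
    r = [_dispersion_ratio(a) for a in (0.05, 0.5, 1.5)]
    assert r[0] < r[1] < r[2]


def test_registration_thinning_matches_completeness():
    cfg = mm.SimulationConfig(
        n_countries=1, cities_per_country=1, city_pop_median=2e6,
        city_pop_sigma=0.0, completeness={"city_01_001": 0.8}, seed=8)
    expo = generate_exposures(cfg)
    deaths, _, truth = mm.generate_deaths(cfg, expo)
    true_total = sum(truth.true_totals.values())
    assert true_total > 1000
    frac = deaths["n_deaths"].sum() / true_total
    assert 0.75 <= frac <= 0.85


def test_emit_and_read_round_trip(tmp_path, small_config, small_study_inputs):
    exposures, deaths, population, factors, truth = small_study_inputs
    emit_study_files(tmp_path, deaths, population, factors, exposures, truth)
    d2, p2, f2, e2, t2 = read_study_files(tmp_path)
    pd.testing.assert_frame_equal(deaths.reset_index(drop=True), d2)
    pd.testing.assert_frame_equal(population.reset_index(drop=True), p2)
    pd.testing.assert_frame_equal(factors.reset_index(drop=True), f2)
    pd.testing.assert_frame_equal(exposures.reset_index(drop=True), e2)
    assert t2.beta == truth.beta
    assert t2.completeness == truth.completeness


def test_empty_death_table_writes_header_only(tmp_path, small_study_inputs):
    exposures, deaths, population, factors, _ = small_study_inputs
    empty = deaths.iloc[0:0]
    emit_study_files(tmp_path, empty, population, factors, exposures)
    text = (tmp_path / "deaths.csv").read_text().strip().splitlines()
    assert len(text) == 1 and text[0].startswith("city_id")


def test_orphan_keys_rejected(tmp_path, small_study_inputs):
    exposures, deaths, population, factors, _ = small_study_inputs
    with pytest.raises(ValueError, match="city_01_001"):
        emit_study_files(tmp_path, deaths, population, factors,
                         exposures[exposures.city_id != "city_01_001"])


def test_population_row_count_is_cities_by_years_by_sex_by_age(small_config,
                                                              small_study_inputs):
    _, _, population, _, _ = small_study_inputs
    expected = small_config.n_cities * 10 * 2 * 17
    assert len(population) == expected
    assert set(population["age_group"]) == set(AGE_GROUPS)


def test_seed_determinism_byte_identical(small_config):
    a = mm.generate_study(small_config)
    b = mm.generate_study(small_config)
    for x, y in zip(a[:4], b[:4]):
        assert x.to_csv(index=False) == y.to_csv(index=False)
    assert a[4].city_intercepts == b[4].city_intercepts


def test_deaths_require_exposures_for_all_cities(small_config,
                                                 small_study_inputs):
    exposures = small_study_inputs[0]
    with pytest.raises(ValueError, match="missing cities"):
        mm.generate_deaths(small_config,
                           exposures[exposures.city_id != "city_01_001"])
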