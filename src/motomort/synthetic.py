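"""Synthetic multi-country city study generator with known ground truth.

Emulates the inputs of an ecological road-safety study: ~300 cities in ~7
countries observed 2010-2019, with (i) city-level built/social-environment
exposures drawn from a Gaussian copula with configurable target correlations
and realistic marginals, (ii) motorcyclist death counts per city x year x
sex x age stratum that are NB2-overdispersed around a log-linear model with
country offsets, per-SD exposure effects and a city random intercept,
(iii) other road-user and non-traffic external deaths, (iv) garbage coding
of a configurable fraction of external-cause deaths to partially- or
ill-defined ICD-10 codes, and (v) under-registration thinning with the true
completeness recorded as the correction factor.

Garbage coding is constructed so that ill-defined miscoding hits every
external death at the same rate regardless of true cause (the identifying
assumption of composition-based redistribution), while partially-defined
miscoding additionally hits road-traffic deaths; the two rates are
calibrated so the overall garbage fraction among external deaths equals
``p_illdefined``.  An optional gradient makes garbage propensity depend on
the city's social-environment score, which breaks complete-case analysis
but not redistribution.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import stats

from .config import GroundTruth, SimulationConfig, build_correlation_matrix
from .standards import (AGE_GROUPS, BINARY_EXPOSURES, EXPOSURE_NAMES,
                        MOTORIZATION_COL, SEXES, WHO_WORLD_STANDARD)

# representative ICD-10 code emitted per cause group
CLASS_CODES = {
    "motorcyclist": "V23", "pedestrian": "V03", "bicyclist": "V13",
    "car_occupant": "V43", "other_rt": "V78",
    "partially_defined_rt": "V89", "ill_defined_external": "X59",
    "non_rt_external": "W74",
}

#: marginal distributions of the exposures: (kind, param1, param2)
EXPOSURE_MARGINALS: dict[str, tuple] = {
    "nearest_neighbor_distance": ("lognormal", np.log(84.0), 0.25),
    "patch_density": ("lognormal", np.log(0.30), 0.60),
    "circuity": ("normal", 1.065, 0.02),
    "street_length_avg": ("lognormal", np.log(140.0), 0.15),
    "intersection_density": ("lognormal", np.log(4.5), 0.70),
    "street_node_avg": ("normal", 3.0, 0.15),
    "population_density": ("lognormal", np.log(6500.0), 0.35),
    "transit_presence": ("bernoulli", 0.16, None),
    "travel_delay_index": ("lognormal", np.log(0.12), 0.50),
    "gdp_per_capita": ("lognormal", np.log(15000.0), 0.45),
    "social_environment_index": ("normal", 0.2, 0.45),
}

_RNG_EXPOSURES, _RNG_POP, _RNG_EFFECTS, _RNG_COUNTS, _RNG_GARBAGE, \
    _RNG_THIN, _RNG_REG = range(101, 108)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def city_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = [(f"city_{i + 1:02d}_{j + 1:03d}", f"country_{i + 1:02d}")
            for i in range(config.n_countries)
            for j in range(config.cities_per_country)]
    return pd.DataFrame(rows, columns=["city_id", "country_id"])


def generate_exposures(config: SimulationConfig) -> pd.DataFrame:
    """One row per city: the 11 exposures plus motorcycle registrations.

    Correlation targets refer to the latent Gaussian copula; monotone
    marginal transforms attenuate realized Pearson correlations slightly
    (well within +-0.15 for the packaged marginals).  Registrations per
    1,000 are missing for a configurable fraction of cities.
    """
    corr = build_correlation_matrix(config.exposure_corr, EXPOSURE_NAMES)
    rng = _rng(config, _RNG_EXPOSURES)
    cities = city_frame(config)
    n = len(cities)
    # eigendecomposition handles the PSD-but-singular case cholesky rejects
    vals, vecs = np.linalg.eigh(corr)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n, len(EXPOSURE_NAMES))) @ root.T

    out = cities.copy()
    for k, name in enumerate(EXPOSURE_NAMES):
        kind, a, b = EXPOSURE_MARGINALS[name]
        if kind == "lognormal":
            out[name] = np.exp(a + b * z[:, k])
        elif kind == "normal":
            out[name] = a + b * z[:, k]
        elif kind == "bernoulli":
            out[name] = (z[:, k] < stats.norm.ppf(a)).astype(int)
        else:  # pragma: no cover
            raise ValueError(kind)
    moto = np.exp(np.log(80.0) + 1.0 * rng.standard_normal(n))
    has_reg = rng.random(n) < config.registration_coverage
    out[MOTORIZATION_COL] = np.where(has_reg, moto, np.nan)
    return out


def _standardize_for_truth(exposures: pd.DataFrame) -> pd.DataFrame:
    """z-scores used to apply the true per-SD effects (transit kept 0/1)."""
    z = {}
    for name in EXPOSURE_NAMES:
        col = exposures[name].astype(float)
        if name in BINARY_EXPOSURES:
            z[name] = col
        else:
            sd = col.std(ddof=1)
            z[name] = (col - col.mean()) / sd if sd > 0 else col * 0.0
    return pd.DataFrame(z, index=exposures.index)


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Population by city x year x sex x age group (true counts)."""
    rng = _rng(config, _RNG_POP)
    cities = city_frame(config)
    base = np.exp(np.log(config.city_pop_median)
                  + config.city_pop_sigma * rng.standard_normal(len(cities)))
    base = np.maximum(base, 1e5)
    pyramid = np.array([WHO_WORLD_STANDARD[a] for a in AGE_GROUPS])
    pyramid = pyramid / pyramid.sum()
    years = config.year_list
    growth = (1.0 + config.annual_pop_growth) ** np.arange(len(years))
    frames = []
    for (city, country), pop0 in zip(cities.itertuples(index=False), base):
        grid = pd.MultiIndex.from_product(
            [years, SEXES, AGE_GROUPS], names=["year", "sex", "age_group"]
        ).to_frame(index=False)
        g = growth[[years.index(y) for y in grid["year"]]]
        w = pyramid[[AGE_GROUPS.index(a) for a in grid["age_group"]]]
        grid["population"] = np.rint(pop0 * g * w * 0.5).astype(int)
        grid.insert(0, "country_id", country)
        grid.insert(0, "city_id", city)
        frames.append(grid)
    return pd.concat(frames, ignore_index=True)


def _baseline_rate(config: SimulationConfig) -> pd.DataFrame:
    """Yearly motorcyclist baseline rate per person by sex and age group."""
    prof = np.asarray(config.age_profile, float)
    male = config.baseline_peak_rate / 1e5 * prof
    rows = []
    for a, rm in zip(AGE_GROUPS, male):
        rows.append(("M", a, rm))
        rows.append(("F", a, rm / config.male_female_ratio))
    return pd.DataFrame(rows, columns=["sex", "age_group", "base_rate"])


def generate_deaths(config: SimulationConfig, exposures: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the observed death table, true population and ground truth.

    Returns ``(deaths, population, truth)`` where ``deaths`` is long-format
    (city_id, country_id, year, sex, age_group, icd10_code, n_deaths) after
    garbage coding and registration thinning, and ``population`` holds true
    (un-thinned) counts; the matching correction factor equals the city's
    completeness.
    """
    cities = city_frame(config)
    if not set(cities["city_id"]) <= set(exposures["city_id"]):
        missing = sorted(set(cities["city_id"]) - set(exposures["city_id"]))
        raise ValueError(f"exposures missing cities: {missing[:5]}")
    exposures = exposures.set_index("city_id").loc[cities["city_id"]].reset_index()

    rng_eff = _rng(config, _RNG_EFFECTS)
    countries = sorted(cities["country_id"].unique())
    country_eff = dict(zip(
        countries, config.sigma_country * rng_eff.standard_normal(len(countries))))
    b_city = dict(zip(
        cities["city_id"],
        config.sigma_city * rng_eff.standard_normal(len(cities))))

    z = _standardize_for_truth(exposures)
    beta = dict(config.beta)
    xb = np.zeros(len(cities))
    for name, b in beta.items():
        xb += b * z[name].to_numpy()
    lp_city = pd.Series(
        np.array([country_eff[c] for c in cities["country_id"]]) + xb
        + np.array([b_city[c] for c in cities["city_id"]]),
        index=cities["city_id"])
    # other road users share the city profile (scaled); defensible because the
    # exposures describe road environment common to all road users
    lp_other = pd.Series(
        np.array([country_eff[c] for c in cities["country_id"]])
        + 1.0 * xb + np.array([b_city[c] for c in cities["city_id"]]),
        index=cities["city_id"])
    lp_nonrt = pd.Series(
        np.array([country_eff[c] for c in cities["country_id"]]),
        index=cities["city_id"])

    population = generate_population(config)
    strata = population.merge(_baseline_rate(config), on=["sex", "age_group"])
    strata = strata.sort_values(["city_id", "year", "sex", "age_group"],
                                ignore_index=True)
    pop = strata["population"].to_numpy(float)
    mu_moto = pop * strata["base_rate"].to_numpy() \
        * np.exp(lp_city.loc[strata["city_id"]].to_numpy())
    if ((pop == 0) & (mu_moto > 0)).any():  # pragma: no cover - structural guard
        raise ValueError("stratum with zero person-years but nonzero rate")

    rng_counts = _rng(config, _RNG_COUNTS)
    if config.alpha_nb > 1e-12:
        shape = 1.0 / config.alpha_nb
        lam = rng_counts.gamma(shape, scale=config.alpha_nb * mu_moto)
        y_moto = rng_counts.poisson(lam)
    else:
        y_moto = rng_counts.poisson(mu_moto)

    other = {}
    e_other = np.exp(lp_other.loc[strata["city_id"]].to_numpy())
    for grp, fac in config.other_rt_factors.items():
        mu_g = pop * strata["base_rate"].to_numpy() * fac * e_other
        other[grp] = rng_counts.poisson(mu_g)
    nonrt_rate = strata["sex"].map(config.non_rt_rate).to_numpy(float) / 1e5
    mu_nr = pop * nonrt_rate * np.exp(lp_nonrt.loc[strata["city_id"]].to_numpy())
    y_nonrt = rng_counts.poisson(mu_nr)

    counts = {"motorcyclist": y_moto, **other, "non_rt_external": y_nonrt}
    rt_groups = ["motorcyclist", *config.other_rt_factors.keys()]
    true_rt = sum(counts[g] for g in rt_groups)
    true_external = true_rt + y_nonrt

    truth = GroundTruth(
        beta={k: float(v) for k, v in beta.items()},
        country_effects={k: float(v) for k, v in country_eff.items()},
        city_intercepts={k: float(v) for k, v in b_city.items()},
        completeness={},
        true_totals={g: int(v.sum()) for g, v in counts.items()},
        true_moto_by_city={
            c: int(t) for c, t in
            pd.Series(y_moto).groupby(strata["city_id"].to_numpy()).sum().items()},
        true_person_years=float(population["population"].sum()),
        sigma_city=config.sigma_city,
        alpha_nb=config.alpha_nb,
    )

    # --- garbage coding -------------------------------------------------
    rng_g = _rng(config, _RNG_GARBAGE)
    p_city = pd.Series(config.p_illdefined, index=cities["city_id"])
    gradient = config.p_illdefined_gradient
    if gradient:
        p_city = np.clip(
            config.p_illdefined
            * np.exp(-gradient * pd.Series(
                z["social_environment_index"].to_numpy(),
                index=cities["city_id"])),
            0.0, 0.5)
    s = config.partial_share
    # expected road-traffic share of external deaths, for calibrating the
    # partial-coding rate so overall garbage fraction ~= p_illdefined
    rho = float(true_rt.sum()) / max(1.0, float(true_external.sum()))
    p_row = p_city.loc[strata["city_id"]].to_numpy()
    q_ill = (1.0 - s) * p_row                      # all external deaths
    q_partial = np.minimum(s * p_row / max(rho, 1e-9), 1.0 - q_ill)  # RT only

    garb_partial = {}
    garb_ill = {}
    kept = {}
    # conditional ill rate among deaths not already partial-coded
    q_ill_cond = np.clip(q_ill / np.maximum(1e-12, 1.0 - q_partial), 0.0, 1.0)
    for grp in rt_groups:
        n = counts[grp]
        to_partial = rng_g.binomial(n, q_partial)
        to_ill = rng_g.binomial(n - to_partial, q_ill_cond)
        garb_partial[grp] = to_partial
        garb_ill[grp] = to_ill
        kept[grp] = n - to_partial - to_ill
    nr_to_ill = rng_g.binomial(y_nonrt, q_ill)
    kept["non_rt_external"] = y_nonrt - nr_to_ill
    kept["partially_defined_rt"] = sum(garb_partial.values())
    kept["ill_defined_external"] = sum(garb_ill.values()) + nr_to_ill

    # --- registration thinning ------------------------------------------
    rng_t = _rng(config, _RNG_THIN)
    if config.completeness is not None:
        comp = pd.Series({c: config.completeness[c] for c in cities["city_id"]})
    else:
        lo, hi = config.completeness_range
        comp = pd.Series(lo + (hi - lo) * rng_t.random(len(cities)),
                         index=cities["city_id"])
    truth.completeness = {k: float(v) for k, v in comp.items()}
    c_row = comp.loc[strata["city_id"]].to_numpy()
    observed = {grp: rng_t.binomial(v, c_row) for grp, v in kept.items()}

    frames = []
    keycols = strata[["city_id", "country_id", "year", "sex", "age_group"]]
    for grp, v in observed.items():
        nz = v > 0
        if not nz.any():
            continue
        f = keycols.loc[nz].copy()
        f["icd10_code"] = CLASS_CODES[grp]
        f["n_deaths"] = v[nz]
        frames.append(f)
    if frames:
        deaths = pd.concat(frames, ignore_index=True)
        deaths = deaths.sort_values(
            ["city_id", "year", "sex", "age_group", "icd10_code"],
            kind="mergesort", ignore_index=True)
    else:
        deaths = pd.DataFrame(columns=[*keycols.columns, "icd10_code", "n_deaths"])
    return deaths, population, truth


def correction_factors_from_truth(config: SimulationConfig,
                                  truth: GroundTruth) -> pd.DataFrame:
    """(city, year) correction factors: the true registration completeness."""
    rows = [(c, y, f) for c, f in truth.completeness.items()
            for y in config.year_list]
    return pd.DataFrame(rows, columns=["city_id", "year", "factor"])


def generate_study(config: SimulationConfig):
    """Convenience: exposures, deaths, population, factors, truth."""
    exposures = generate_exposures(config)
    deaths, population, truth = generate_deaths(config, exposures)
    factors = correction_factors_from_truth(config, truth)
    return exposures, deaths, population, factors, truth


FILES = ("deaths.csv", "population.csv", "correction_factors.csv",
         "exposures.csv", "ground_truth.json")


def emit_study_files(outdir, deaths: pd.DataFrame, population: pd.DataFrame,
                     factors: pd.DataFrame, exposures: pd.DataFrame,
                     truth: GroundTruth | None = None) -> None:
    """Write the five study files; validates key consistency first."""
    pop_cities = set(population["city_id"])
    expo_cities = set(exposures["city_id"])
    death_cities = set(deaths["city_id"]) if len(deaths) else set()
    factor_cities = set(factors["city_id"]) if len(factors) else set()
    orphans = {
        "deaths_not_in_population": sorted(death_cities - pop_cities),
        "population_not_in_exposures": sorted(pop_cities - expo_cities),
        "factors_not_in_population": sorted(factor_cities - pop_cities),
    }
    bad = {k: v for k, v in orphans.items() if v}
    if bad:
        raise ValueError(f"inconsistent city keys across tables: {bad}")
    os.makedirs(outdir, exist_ok=True)
    deaths.to_csv(os.path.join(outdir, "deaths.csv"), index=False)
    population.to_csv(os.path.join(outdir, "population.csv"), index=False)
    factors.to_csv(os.path.join(outdir, "correction_factors.csv"), index=False)
    exposures.to_csv(os.path.join(outdir, "exposures.csv"), index=False)
    if truth is not None:
        truth.to_json(os.path.join(outdir, "ground_truth.json"))


def read_study_files(indir):
    """Read the files written by :func:`emit_study_files`."""
    deaths = pd.read_csv(os.path.join(indir, "deaths.csv"),
                         dtype={"icd10_code": str})
    population = pd.read_csv(os.path.join(indir, "population.csv"))
    factors = pd.read_csv(os.path.join(indir, "correction_factors.csv"))
    exposures = pd.read_csv(os.path.join(indir, "exposures.csv"))
    truth_path = os.path.join(indir, "ground_truth.json")
    truth = GroundTruth.from_json(truth_path) if os.path.exists(truth_path) else None
    return deaths, population, factors, exposures, truth
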